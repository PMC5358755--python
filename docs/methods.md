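# Methods

## Scope and data model

All analyses are transcript-centric: coordinates are 0-based half-open in
transcript space, and the annotation dialect is a transcript-space GTF
(seqname = transcript id, 1-based inclusive spans, CDS feature optional).
Genomic alignments must be projected to transcript space upstream; the
synthetic generator emits transcript-space SAM directly. This avoids
re-implementing splice-aware projection while keeping every UTR-positional
analysis exact. Antisense alignments are excluded from all counting — the
library protocols are sense-stranded. Ensembl biotypes are reduced to eight
values (`protein_coding`, `lincRNA`, `miRNA`, `snoRNA`, `snRNA`, `rRNA`,
`tRNA`, `other`); unknown biotypes map to `other`.

## Cluster calling

Candidates are maximal runs of overlapping sense reads per transcript
(overlap = ≥ 1 shared base on half-open intervals; abutting reads do not
merge; duplicate coordinates all count), discarded below 5 reads. The null
model is reads uniform over the transcript: a candidate of width `w` with
`k` of the transcript's `n` reads scores the binomial tail
`P(X ≥ k), X ~ Binomial(n, w/L)`, computed via the survival function.

Merge-only candidates have a blind spot: on deeply covered transcripts every
read chains into one transcript-wide run whose width-proportional null makes
`p ≈ 1` regardless of local structure. Calling therefore refines wide
candidates: start-count windows of the median read length are scanned at
half-width stride; the densest window's member reads define a subcluster
whose binomial tail is multiplied by the number of scanned windows (union
bound), and the candidate's final p is `min(1, 2·min(p_whole, p_refined))`
(a paired-test Bonferroni factor). Both tails are valid upper bounds under
the null, so BH-FDR control is preserved — on fully null simulations the
fraction of transcripts carrying a reported q < 0.05 cluster is ~10⁻⁴,
far below the nominal 0.05 — while planted windows at ≥ 10-fold local
enrichment are recovered essentially always, including on saturated
transcripts. FDR adjustment (BH step-up) is applied across all candidates of
a library jointly, and reported clusters additionally satisfy the
minimum-of-five-reads rule.

## Chimera detection

A read is *contiguous* when some full-length diagonal against the transcript
index matches all but ≤ 2 positions. Otherwise the read is decomposed into a
prefix arm and a suffix arm by seed-and-extend (exact 12-nt seeds anchored
at the read ends, greedy extension with ≤ 1 mismatch, trailing mismatches
trimmed). Constraints: each arm ≥ 17 nt, read-overlap between arms ≤ 4 nt
(excess is trimmed from an arm that can spare it), read-gap ≤ 4 nt. Ties are
broken by larger total matched length, then intramolecular over
intermolecular, then lexicographic (transcript, start). Arms whose best
score is achieved on more than one gene are treated as multi-mapping and the
read is left unassigned, avoiding spurious intermolecular calls.

The junction position between arms is intrinsically ambiguous by a few
nucleotides whenever bases beyond the true break happen to match the other
reference; the anchored outer ends (arm1 start, arm2 end) are exact. Tests
assert exact anchors, correct class, and ≥ 50% reciprocal arm overlap with
planted truth.

Two hybrids are the same *unique interaction* iff they involve the same
unordered gene pair and corresponding arms reciprocally overlap ≥ 50%.
Hybrid fractions carry exact (Clopper–Pearson) binomial CIs.

## Duplex thermodynamics

Arm-pair energies use an intermolecular-duplex-only nearest-neighbor model
(no intramolecular folding within an arm): dynamic programming over all
non-crossing antiparallel pairings minimizing initiation + stack terms +
affine interior-loop/bulge penalties (init 3.2 kcal/mol + 0.4 per unpaired
nt, loops capped at 15 unpaired nt per gap as a model constraint) + terminal
AU/GU penalties. The 37 °C parameter table
(`src/ripflash/data/rna_stack_dg37_v1.tsv`) contains all 36 stacks over
{AU, UA, CG, GC, GU, UG} with Watson–Crick values following the standard
Xia-style set and wobble stacks from the usual extensions; the table is
mirror-symmetric (`AB/CD = DC/BA`) and swappable without code changes. G·U
wobble is allowed by default and can be disabled. If no pairing reaches
ΔG < 0 the result is the "no-duplex" sentinel ΔG = 0, excluded from
distribution means but counted. Absolute energies are engine-dependent;
only relative comparisons between libraries are asserted anywhere.

The DP is verified exactly against brute-force enumeration of all
non-crossing pairings (same scoring) for arms ≤ 10 nt.

The Wilcoxon rank-sum test uses the exact rank-sum distribution (counting
DP) when both samples have ≤ 12 tie-free observations, otherwise a normal
approximation with tie-corrected variance and continuity correction; a
statistic exactly at its null mean reports p = 1, and the two-sided p is
floored at 10⁻³⁰⁰ to stay in (0, 1]. Calibration: 4–5% rejections at
α = 0.05 over 1000 null datasets of n = 50/50.

## Profiles and motifs

Metagene profiles rescale each coding transcript's 5'UTR/CDS/3'UTR to
20/60/20 bins (configurable). Cluster mass is spread over the fractional
interval it covers; per-bin mass is divided by per-bin nucleotide exposure
(each contributing transcript spreads its region length evenly over that
region's bins) so densities are comparable between regions of different
physical length, then globally normalized to sum to 1. A uniform read rate
yields a flat profile; a 5× 3'UTR rate yields a utr3/cds bin-density ratio
of 5.

The k-mer null preserves the exact dinucleotide multiset of each sequence
via Euler-path shuffling (random last-exit edges forming a tree into the
terminal vertex, then shuffled edge orders), because UTRs are
composition-biased and a mononucleotide null would inflate AT-rich k-mers.
Z = (observed − shuffle mean)/shuffle SD over 100 shuffles by default;
zero-variance k-mers are flagged degenerate and ranked last. Ranking k-mers
on the down-regulated gene subset is available by filtering the input
sequences.

Seed sites follow the canonical grades: the 6mer core is the reverse
complement of miRNA positions 2–7; a match opposite position 8 and/or an A
opposite position 1 upgrade to 7mer-m8 / 7mer-A1 / 8mer, highest grade
reported per locus. Sites of any miRNA within 50 nt (configurable) group
into clusters; ids are assigned only to groups of ≥ 2 sites.

## Integration

Per-gene binding statistics: 3'UTR covered fraction (interval union) for IP
and input, each floored at 1/(UTR length) before the ratio; RPKM ratios
(3'UTR-restricted and whole-transcript) with a symmetric +1-read
pseudocount. The pseudocount policy keeps log-ratios finite for
zero-coverage genes and is applied identically to numerator and denominator.
Joins are audited: every coding gene lands in exactly one of joined /
unmeasured / excluded-no-UTR. Down-vs-unregulated and down-vs-up group
comparisons use the rank-sum test on log₂ ratios; gene identifiers are
case-normalized. ΔΔCt fold changes are `2^(−ΔΔCt)` with replicate series
compared by two-sided Welch t-test (the unequal-variance form, since
replicate variances need not match). Decay fits are ordinary least squares
of ln(expression) on time with ≥ 3 timepoints including t = 0; λ ≤ 0 is
reported as "not decaying" rather than a negative half-life.

## Synthetic data

The generator is the package's study-condition definition, not a test prop.
Defaults: 0.49% chimeric reads (vs 0.03% in control libraries), 52% of
hybrids intramolecular 3'UTR, 5% mRNA–miRNA, bound genes down-regulated
with probability 0.94, mean |log2FC| 1.5 with 0.3 SD noise, ~92%
protein-coding transcripts with lincRNA > miRNA ≈ snoRNA among the rest, and
20-fold 3'UTR binding enrichment in 40-nt windows on 30% of coding genes.
Sequences are uniform-random; region lengths are Gamma-distributed around
means of 150/900/600 nt (5'UTR/CDS/3'UTR); miRNAs are 22 nt; expression is
log-normal (log₁₀ FPKM ~ N(1,1)) for a realistic dynamic range; reads are
50 nt single-end and FLASH arms 25 nt — library read lengths and depths are
not dictated by the emulated study design, so defaults (10⁵–2×10⁵ reads)
are chosen for desk-scale runtime. A single global seed feeds named
per-stage substreams (stage name CRC-hashed into the seed sequence), so any
stage can be re-run independently and all outputs are byte-reproducible.

Stable-mode planting edits transcript 3'UTRs: intramolecular hybrids embed a
reverse-complementary 20-nt window downstream of the first arm, and
mRNA–miRNA hybrids embed the seed match in the mRNA arm; control mode emits
the same read classes from unrelated random windows, so its duplexes are
weak. All planted windows are reserved per transcript (no overlaps), and
contiguous reads are drawn only after all edits, so every emitted read is an
exact substring (or arm-concatenation) of the final transcriptome.

What the generator does *not* emulate — sequencing errors, PCR duplicates,
adapters/barcodes, splice isoforms, composition-biased real sequence,
genome-space mapping ambiguity — bounds what green tests show: they certify
the algorithms' statistical behavior under their stated models, not
performance on raw instrument output.

## Experiment sizes in the test suite

Null FDR: 500 transcripts × 50 seeds at 20 reads/transcript. Sensitivity:
200 genes at 120k reads, 10-fold enrichment (so ≥ 15 planted windows carry
≥ 20 supporting reads). Chimera exactness: 10⁴ constructed chimeras +
10⁵ contiguous reads; fraction recovery at 2×10⁵ reads. Duplex oracle: 1000
random arm pairs ≤ 10 nt. Energy separation: 200 stable vs 200 scrambled
hybrids. Rank-sum calibration: every (n1, n2) ≤ 8 against full enumeration,
plus 1000 null datasets at n = 50/50. Motif recovery: a 7-mer planted once
per sequence in 200 × 300-nt sequences. Association: 500 coding genes, 45%
bound, ≥ 200 genes per compared group, with 100-permutation calibration.
The full suite runs in under a minute on one CPU.

## Known limitations

* The duplex model scores arm–arm hybridization only; it does not predict
  full secondary structures, partition functions, or temperature dependence,
  and its absolute energies should not be compared against other engines.
* The binomial cluster null assumes uniform read starts within a transcript;
  fragmentation and coverage biases of real libraries are not modeled.
* Chimera detection requires an exact 12-nt seed at each read end, so arms
  with errors in their terminal seed are missed; acceptable for the
  error-free generator, conservative on real data.
* The metagene exposure normalization weights each contributing transcript
  equally within a region; depth-weighted variants would need explicit
  per-transcript normalization first.
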