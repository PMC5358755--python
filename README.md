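# ripflash

Transcript-centric analysis of protein–RNA interaction sequencing for a
3'UTR-binding, mRNA-stabilizing RNA-binding protein. The package covers the
computational arc of such a study end to end:

* **Binding-cluster calling** from RIP-seq / single-read FLASH alignments:
  overlapping sense reads are merged into candidate clusters (minimum of five
  reads), tested against a uniform-read binomial null, and reported at
  Benjamini–Hochberg FDR < 0.05.
* **Chimeric-read (hybrid) detection** in FLASH libraries: reads whose two
  segments map to noncontiguous loci are resolved into two-arm hybrids,
  classified intramolecular ("gene-self") vs intermolecular and by
  biotype/region category (e.g. `mRNA_3utr::miRNA`), and deduplicated into
  unique interactions.
* **Duplex energetics**: nearest-neighbor minimum free energy of each arm
  pair (intermolecular duplex only, RNAduplex-style), with a Wilcoxon
  rank-sum comparison of energy distributions between libraries.
* **Profiles and motifs**: metagene density over rescaled 5'UTR/CDS/3'UTR
  bins, k-mer Z-scores against a dinucleotide-preserving shuffle null, and
  canonical miRNA seed-site scanning (6mer/7mer-A1/7mer-m8/8mer).
* **Integration with expression**: per-gene 3'UTR coverage and RPKM ratios
  (IP/input) joined to differential-expression direction, gene-self-hybrid
  tallies per direction, ChIP target-set overlaps, ΔΔCt qPCR fold changes,
  and actinomycin-chase half-life fits.
* **A synthetic-data generator** that emulates the statistical structure of
  the real libraries (a ~0.5% chimeric fraction vs ~0.03% background,
  intramolecular 3'UTR duplexes thermodynamically more stable than scrambled
  controls, bound genes predominantly down-regulated on regulator loss), so
  that every stage is exercisable and testable at desk scale with no
  external data.

## The statistics in brief

A cluster of `k` reads spanning `w` nt on a transcript of length `L`
carrying `n` mapped reads is scored `p = P(X ≥ k)`, `X ~ Binomial(n, w/L)`;
q-values are BH step-up across all candidates of a library. Duplex free
energy is `ΔG = ΔG_init + Σ stacks + Σ loop penalties (+ terminal AU/GU)`,
minimized by dynamic programming over all non-crossing antiparallel pairings
(37 °C nearest-neighbor table shipped as a versioned text file). Half-lives
come from least squares of `ln(expression)` on time, `t½ = ln 2 / λ`; qPCR
fold changes from `2^(−ΔΔCt)`.

## Worked example

The one-command demo generates a complete synthetic study (transcriptome,
RIP + input SAM, stable- and control-mode FLASH FASTQ, DE table, decay
timecourses), runs every stage over the emitted files, and writes a
checksummed manifest:

```bash
ripflash demo --seed 7 --out-dir demo/
```

prints (abridged):

```json
{
  "n_significant_clusters": 24,
  "pct_clusters_protein_coding": 100.0,
  "hybrid_fraction_pct": 0.49,
  "control_hybrid_fraction_pct": 0.03,
  "intramolecular_3utr_share_pct": 52.45,
  "mean_dg_flash": -21.76,
  "mean_dg_control": -5.34,
  "energy_ranksum_p": 1.37e-06,
  "down_vs_unregulated_p_rpkm": 0.0019,
  "n_genes_destabilized": 4
}
```

Reading: 0.49% of FLASH reads are chimeric against 0.03% in the control
library; 52% of hybrids are intramolecular 3'UTR duplexes; their mean
hybridization energy (−21.8 kcal/mol) is far below the scrambled-arm control
(−5.3 kcal/mol, rank-sum p ≈ 10⁻⁶), i.e. the recovered duplexes are real,
stable structures; genes bound by the protein and down-regulated on its loss
have higher IP/input RPKM ratios than unregulated genes (p ≈ 0.002); and all
four decay-timecourse genes show shortened half-lives on knockdown.

Each stage is also exposed as its own subcommand over files
(`simulate`, `clusters`, `hybrids`, `thermo`, `profiles metagene|kmers|mirna`,
`integrate stats|decay`) — see `ripflash --help` — and as plain library
functions (`ripflash.cluster_calling.call_clusters`,
`ripflash.hybrid_analysis.detect_chimeras`,
`ripflash.duplex_thermo.duplex_energy`, ...).

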