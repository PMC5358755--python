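"""Metagene density profiles, k-mer Z-score enrichment and miRNA seed scanning.

The metagene profile rescales each coding transcript's 5'UTR, CDS and 3'UTR
to fixed bin grids (default 20/60/20) and accumulates cluster density; the
k-mer null preserves dinucleotide composition via Euler-path shuffling, which
matters because UTRs are composition-biased; seed-site scanning follows the
canonical 6mer / 7mer-m8 / 7mer-A1 / 8mer grades (complementarity to miRNA
positions 2-8, with or without an A opposite position 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ripflash.io_formats import TranscriptModel, reverse_complement
from ripflash.synthetic_data import stage_rng

CODING_REGIONS = ("utr5", "cds", "utr3")


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Binned cluster density across rescaled transcript regions.

    ``density`` maps region label to a bin vector; the three vectors jointly
    sum to 1 whenever any cluster contributed.
    """

    bins: tuple[int, int, int]
    density: dict[str, np.ndarray]
    n_transcripts: int
    n_skipped_no_region: int

    def as_table(self) -> pd.DataFrame:
        rows = []
        for region in CODING_REGIONS:
            for b, d in enumerate(self.density[region]):
                rows.append((region, b, float(d)))
        return pd.DataFrame(rows, columns=["region", "bin", "density"])


def metagene_profile(
    clusters: Iterable,
    models: Mapping[str, TranscriptModel],
    bins: tuple[int, int, int] = (20, 60, 20),
) -> MetageneProfile:
    """Accumulate cluster spans into rescaled region bins, normalized to sum 1.

    Each cluster contributes total mass 1, split across regions in proportion
    to its overlap and spread uniformly over the fractional interval it covers
    within each region.  Clusters on transcripts lacking a region skip that
    region (counted).
    """
    n_bins = dict(zip(CODING_REGIONS, bins))
    mass = {r: np.zeros(n_bins[r]) for r in CODING_REGIONS}
    exposure = {r: np.zeros(n_bins[r]) for r in CODING_REGIONS}
    seen: set[str] = set()
    skipped = 0
    for c in clusters:
        model = models.get(c.transcript_id)
        if model is None or model.biotype != "protein_coding":
            continue
        width = c.end - c.start
        if width <= 0:
            continue
        contributed = False
        for label, rs, re_ in model.regions:
            if label not in n_bins:
                continue
            ov_s, ov_e = max(c.start, rs), min(c.end, re_)
            if ov_e <= ov_s:
                continue
            frac_lo = (ov_s - rs) / (re_ - rs)
            frac_hi = (ov_e - rs) / (re_ - rs)
            weight = (ov_e - ov_s) / width
            nb = n_bins[label]
            # distribute weight uniformly over [frac_lo, frac_hi) in nb bins
            edges = np.linspace(0.0, 1.0, nb + 1)
            cover = (np.minimum(edges[1:], frac_hi) - np.maximum(edges[:-1], frac_lo)).clip(0)
            span = frac_hi - frac_lo
            if span > 0:
                mass[label] += weight * cover / span
            contributed = True
        if contributed:
            seen.add(c.transcript_id)
        else:
            skipped += 1
    # per-nt exposure: each contributing transcript spreads its region lengths
    # evenly over that region's bins, so densities are comparable between
    # regions of different physical length
    for tx in seen:
        for label, rs, re_ in models[tx].regions:
            if label in n_bins:
                exposure[label] += (re_ - rs) / n_bins[label]
    density = {}
    for r in CODING_REGIONS:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(exposure[r] > 0, mass[r] / np.maximum(exposure[r], 1e-300), 0.0)
        density[r] = d
    total = sum(d.sum() for d in density.values())
    if total > 0:
        density = {r: d / total for r, d in density.items()}
    return MetageneProfile(bins, density, len(seen), skipped)


def end_density(
    clusters: Iterable,
    models: Mapping[str, TranscriptModel],
    end_fraction: float = 0.1,
) -> tuple[float, float, float]:
    """Per-nt cluster coverage in the first/last ``end_fraction`` of each
    transcript versus the remainder, averaged over transcripts with signal.

    Returns (density_5prime, density_3prime, density_body)."""
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        if c.transcript_id in models:
            by_tx.setdefault(c.transcript_id, []).append((c.start, c.end))

    sums = np.zeros(3)
    n = 0
    for tx, spans in by_tx.items():
        length = models[tx].length
        cut5 = int(round(end_fraction * length))
        cut3 = length - cut5
        zones = [(0, cut5), (cut3, length), (cut5, cut3)]
        covered = _interval_union(spans)
        for zi, (zs, ze) in enumerate(zones):
            zlen = ze - zs
            if zlen <= 0:
                continue
            cov = sum(min(e, ze) - max(s, zs) for s, e in covered if s < ze and e > zs)
            sums[zi] += cov / zlen
        n += 1
    if n == 0:
        return 0.0, 0.0, 0.0
    return float(sums[0] / n), float(sums[1] / n), float(sums[2] / n)


def _interval_union(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# k-mer Z-scores against a dinucleotide-preserving shuffle null
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Euler-path method).

    The sequence is viewed as an Eulerian walk on the graph whose edges are
    its dinucleotides; a random walk with the same start/end vertices and the
    same edge multiset is an exact dinucleotide-preserving permutation.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]

    # pick a random "last exit" edge per vertex forming a tree into `last`
    for _ in range(1000):
        last_exit = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        ok = True
        for v in vertices:
            cur, hops = v, 0
            while cur != last:
                if cur not in last_exit:
                    ok = False
                    break
                cur = last_exit[cur]
                hops += 1
                if hops > 8:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabets always converge
        return seq

    remaining: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        remaining[v] = pool

    out = [seq[0]]
    cur = seq[0]
    counters = {v: 0 for v in remaining}
    for _ in range(len(seq) - 1):
        nxt = remaining[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _count_kmers(seq: str, k: int, counts: dict[str, int]) -> None:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1


def kmer_zscores(
    sequences: Sequence[str],
    k: int = 6,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank k-mers by Z-score against a dinucleotide-preserving shuffle null.

    Observed counts are total overlapping occurrences across sequences; the
    null re-counts after per-sequence shuffles, ``n_shuffles`` times.  k-mers
    with zero null variance are flagged degenerate and ranked after all
    finite Z-scores.  Results are invariant to sequence input order.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if k < 2:
        raise ValueError("k must be >= 2 for a dinucleotide-preserving null")
    sequences = sorted(sequences)  # order invariance
    observed: dict[str, int] = {}
    for s in sequences:
        _count_kmers(s.upper(), k, observed)
    kmers = sorted(observed)
    null = np.zeros((n_shuffles, len(kmers)))
    idx = {km: i for i, km in enumerate(kmers)}
    rng = stage_rng(seed, "kmer-shuffle")
    for r in range(n_shuffles):
        counts: dict[str, int] = {}
        for s in sequences:
            _count_kmers(dinucleotide_shuffle(s.upper(), rng), k, counts)
        for km, n in counts.items():
            i = idx.get(km)
            if i is not None:
                null[r, i] = n
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1) if n_shuffles > 1 else np.zeros(len(kmers))
    obs = np.array([observed[km] for km in kmers], dtype=float)
    degenerate = sd == 0
    z = np.full(len(kmers), np.nan)
    z[~degenerate] = (obs[~degenerate] - mean[~degenerate]) / sd[~degenerate]
    df = pd.DataFrame({
        "kmer": kmers, "observed": obs.astype(int),
        "shuffle_mean": mean, "shuffle_sd": sd,
        "z_score": z, "degenerate": degenerate,
    })
    df = df.sort_values(["degenerate", "z_score", "kmer"],
                        ascending=[True, False, True], kind="mergesort",
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# miRNA seed-site scanning
# ---------------------------------------------------------------------------

@dataclass
class MirnaSite:
    utr_id: str
    position: int  # start of the 6mer seed core in the UTR
    site_type: str  # 8mer / 7mer-m8 / 7mer-A1 / 6mer
    mirna_id: str
    cluster_id: int | None = None


def scan_mirna_sites(
    utr_sequences: Mapping[str, str],
    mirna_sequences: Mapping[str, str],
    cluster_window: int = 50,
) -> list[MirnaSite]:
    """Scan UTRs for canonical miRNA seed matches and cluster nearby sites.

    A site's core is the reverse complement of miRNA positions 2-7; a match
    opposite position 8 upgrades it to 7mer-m8, an A opposite position 1 to
    7mer-A1, both to 8mer (the highest-specificity type is reported).  Sites
    of any miRNA within ``cluster_window`` nt are grouped; a cluster_id is
    assigned only to groups of >= 2 sites.
    """
    sites: list[MirnaSite] = []
    for mirna_id in sorted(mirna_sequences):
        mir = mirna_sequences[mirna_id].upper().replace("U", "T")
        if not 19 <= len(mir) <= 24:
            raise ValueError(f"{mirna_id}: miRNAs must be 19-24 nt, got {len(mir)}")
        core = reverse_complement(mir[1:7])
        m8 = reverse_complement(mir[7])
        for utr_id in sorted(utr_sequences):
            utr = utr_sequences[utr_id].upper().replace("U", "T")
            start = utr.find(core)
            while start != -1:
                has_m8 = start > 0 and utr[start - 1] == m8
                has_a1 = start + 6 < len(utr) and utr[start + 6] == "A"
                if has_m8 and has_a1:
                    site_type = "8mer"
                elif has_m8:
                    site_type = "7mer-m8"
                elif has_a1:
                    site_type = "7mer-A1"
                else:
                    site_type = "6mer"
                sites.append(MirnaSite(utr_id, start, site_type, mirna_id))
                start = utr.find(core, start + 1)

    # cluster sites (any miRNA) within cluster_window per UTR
    next_cluster = 1
    by_utr: dict[str, list[MirnaSite]] = {}
    for s in sites:
        by_utr.setdefault(s.utr_id, []).append(s)
    for utr_id in sorted(by_utr):
        group = sorted(by_utr[utr_id], key=lambda s: (s.position, s.mirna_id))
        chain: list[MirnaSite] = []
        for s in group + [None]:  # type: ignore[list-item]
            if chain and (s is None or s.position - chain[-1].position > cluster_window):
                if len(chain) >= 2:
                    for member in chain:
                        member.cluster_id = next_cluster
                    next_cluster += 1
                chain = []
            if s is not None:
                chain.append(s)
    return sites
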