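"""Chimeric-read detection and two-arm hybrid classification for FLASH libraries.

A read is *contiguous* when its best full-length alignment against the
transcript index covers all but at most 2 nt.  Otherwise the read is searched
for a two-arm decomposition -- a prefix arm and a suffix arm, each at least
``min_arm`` nt, overlapping on the read by at most ``max_read_overlap`` nt and
separated by at most ``max_read_gap`` nt -- maximizing total matched length.
Arm search is seed-and-extend: exact seeds of ``seed_length`` (default 12)
with at most ``max_mismatches`` in the extension.  Reads with neither
interpretation, and reads whose best arms map with equal score to more than
one gene (multi-mapping), are left unassigned.

Hybrids with both arms on the same gene are intramolecular ("gene-self"),
otherwise intermolecular; categories combine each arm's biotype and region
(e.g. ``mRNA_3utr::miRNA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from ripflash.io_formats import TranscriptModel


@dataclass
class Arm:
    """One aligned segment of a chimeric read."""

    read_offset: int
    read_length: int
    transcript_id: str
    start: int
    end: int
    matched_sequence: str
    n_mismatches: int = 0


@dataclass
class Hybrid:
    read_id: str
    arm1: Arm  # 5' arm of the read
    arm2: Arm
    hybrid_class: str = ""  # intramolecular / intermolecular
    category: str = ""
    delta_g: float = float("nan")
    genomic_distance: int | None = None  # nt between arms when intramolecular

    def as_row(self) -> dict:
        return {
            "read_id": self.read_id,
            "tx1": self.arm1.transcript_id,
            "start1": self.arm1.start,
            "end1": self.arm1.end,
            "tx2": self.arm2.transcript_id,
            "start2": self.arm2.start,
            "end2": self.arm2.end,
            "hybrid_class": self.hybrid_class,
            "category": self.category,
            "delta_g": self.delta_g,
            "genomic_distance": self.genomic_distance,
        }


class TranscriptIndex:
    """Exact-seed substring index over transcript sequences."""

    def __init__(self, models: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
                 seed_length: int = 12):
        if not isinstance(models, Mapping):
            seen: dict[str, TranscriptModel] = {}
            for m in models:
                if m.transcript_id in seen:
                    raise ValueError(f"duplicate transcript_id {m.transcript_id}")
                seen[m.transcript_id] = m
            models = seen
        self.models = dict(models)
        self.seed_length = seed_length
        self.gene_of = {tx: m.gene_id for tx, m in self.models.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for tx, m in self.models.items():
            seq = m.sequence
            for pos in range(len(seq) - seed_length + 1):
                self._seeds.setdefault(seq[pos : pos + seed_length], []).append((tx, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._seeds.get(kmer, [])


def build_index(models, seed_length: int = 12) -> TranscriptIndex:
    """Build the deterministic exact-seed index used by chimera detection."""
    return TranscriptIndex(models, seed_length)


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------

def _count_matches(ref: str, pos: int, read: str) -> int:
    """Matched positions of the whole read aligned at ref[pos:]; -1 if the
    read does not fit inside the reference at that diagonal."""
    if pos < 0 or pos + len(read) > len(ref):
        return -1
    window = ref[pos : pos + len(read)]
    if window == read:
        return len(read)
    return sum(1 for a, b in zip(window, read) if a == b)


def _extend_match(ref: str, pos: int, read: str, off: int, max_mm: int) -> int:
    """Greedy rightward extension length from read[off:] at ref[pos:], with at
    most max_mm mismatches; trailing mismatches are trimmed."""
    limit = min(len(read) - off, len(ref) - pos)
    i = mm = last_good = 0
    while i < limit:
        if ref[pos + i] == read[off + i]:
            i += 1
            last_good = i
        else:
            mm += 1
            if mm > max_mm:
                break
            i += 1
    return last_good


def _best_prefix_arms(read: str, index: TranscriptIndex, max_mm: int) -> list[tuple[int, str, int]]:
    """All (length, tx, start) prefix-anchored extensions of maximal length."""
    k = index.seed_length
    if len(read) < k:
        return []
    best: list[tuple[int, str, int]] = []
    best_len = 0
    for tx, pos in index.lookup(read[:k]):
        seq = index.models[tx].sequence
        length = k + _extend_match(seq, pos + k, read, k, max_mm)
        if length > best_len:
            best, best_len = [(length, tx, pos)], length
        elif length == best_len:
            best.append((length, tx, pos))
    return best


def _best_suffix_arms(read: str, index: TranscriptIndex, max_mm: int) -> list[tuple[int, str, int]]:
    """All (length, tx, end) suffix-anchored extensions of maximal length.

    Implemented as prefix search on the reversed strings (no complementing:
    arms align sense)."""
    k = index.seed_length
    if len(read) < k:
        return []
    seed = read[-k:]
    rread = read[::-1]
    best: list[tuple[int, str, int]] = []
    best_len = 0
    for tx, pos in index.lookup(seed):
        seq = index.models[tx].sequence
        end = pos + k  # transcript end of the seed
        length = k + _extend_match(seq[:pos][::-1], 0, rread, k, max_mm)
        if length > best_len:
            best, best_len = [(length, tx, end)], length
        elif length == best_len:
            best.append((length, tx, end))
    return best


# ---------------------------------------------------------------------------
# Chimera detection
# ---------------------------------------------------------------------------

@dataclass
class ChimeraResult:
    hybrids: list[Hybrid] = field(default_factory=list)
    contiguous: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.hybrids) + len(self.contiguous) + len(self.unassigned)


def detect_chimeras(
    reads: Iterable[tuple[str, str]],
    index: TranscriptIndex,
    min_arm: int = 17,
    max_read_overlap: int = 4,
    max_read_gap: int = 4,
    max_mismatches: int = 1,
) -> ChimeraResult:
    """Partition raw reads into hybrids, contiguous reads and unassigned reads.

    Detection is per-read, hence invariant to input order.  See module
    docstring for the decomposition rules and tie-breaking.
    """
    out = ChimeraResult()
    k = index.seed_length
    for read_id, seq in reads:
        seq = seq.upper().replace("U", "T") if "U" in seq else seq.upper()
        n = len(seq)
        if n < k:
            out.unassigned.append(read_id)
            continue

        # 1) contiguous test: best full-length diagonal covers >= n - 2
        best_full = -1
        offsets = {0, k, max(0, n - k)}
        for off in offsets:
            if off + k > n:
                continue
            for tx, pos in index.lookup(seq[off : off + k]):
                m = _count_matches(index.models[tx].sequence, pos - off, seq)
                if m > best_full:
                    best_full = m
            if best_full == n:
                break
        if best_full >= n - 2:
            out.contiguous.append(read_id)
            continue

        if n < 2 * min_arm:
            out.unassigned.append(read_id)
            continue

        # 2) two-arm decomposition
        prefixes = _best_prefix_arms(seq, index, max_mismatches)
        suffixes = _best_suffix_arms(seq, index, max_mismatches)
        candidates = []
        for (l1, tx1, s1), (l2, tx2, e2) in product(prefixes, suffixes):
            a, b = l1, l2
            overlap = a + b - n
            if overlap > max_read_overlap:
                trim = overlap - max_read_overlap
                if a - trim >= min_arm:
                    a -= trim
                elif b - trim >= min_arm:
                    b -= trim
                else:
                    continue
            if a < min_arm or b < min_arm:
                continue
            gap = n - b - a
            if gap > max_read_gap:
                continue
            intra = index.gene_of[tx1] == index.gene_of[tx2]
            candidates.append((a + b, intra, tx1, s1, a, tx2, e2, b))
        if not candidates:
            out.unassigned.append(read_id)
            continue
        # tie-break: larger total match, intramolecular first, lexicographic
        candidates.sort(key=lambda c: (-c[0], not c[1], c[2], c[3], c[5], c[6]))
        best_score, best_intra = candidates[0][0], candidates[0][1]
        top = [c for c in candidates if c[0] == best_score and c[1] == best_intra]
        gene_pairs = {
            frozenset((index.gene_of[c[2]], index.gene_of[c[5]])) for c in top
        }
        if len(gene_pairs) > 1:
            out.unassigned.append(read_id)  # multi-mapping arms
            continue
        _, _, tx1, s1, a, tx2, e2, b = candidates[0]
        arm1 = Arm(0, a, tx1, s1, s1 + a, index.models[tx1].sequence[s1 : s1 + a])
        arm2 = Arm(n - b, b, tx2, e2 - b, e2, index.models[tx2].sequence[e2 - b : e2])
        hybrid = Hybrid(read_id, arm1, arm2)
        classify_hybrid(hybrid, index.models)
        out.hybrids.append(hybrid)
    return out


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def _arm_category(arm: Arm, models: Mapping[str, TranscriptModel]) -> str:
    model = models.get(arm.transcript_id)
    if model is None:
        return "body"
    if model.biotype == "protein_coding":
        mid = (arm.start + arm.end) // 2
        for label, rs, re_ in model.regions:
            if rs <= mid < re_:
                return {"utr5": "mRNA_5utr", "cds": "mRNA_cds", "utr3": "mRNA_3utr"}[label]
        return "mRNA"
    return model.biotype if model.biotype != "other" else "body"


def classify_hybrid(hybrid: Hybrid, models: Mapping[str, TranscriptModel]) -> Hybrid:
    """Set hybrid_class, category and genomic distance from arm annotations."""
    m1, m2 = models.get(hybrid.arm1.transcript_id), models.get(hybrid.arm2.transcript_id)
    g1 = m1.gene_id if m1 else hybrid.arm1.transcript_id
    g2 = m2.gene_id if m2 else hybrid.arm2.transcript_id
    c1, c2 = _arm_category(hybrid.arm1, models), _arm_category(hybrid.arm2, models)
    if g1 == g2:
        hybrid.hybrid_class = "intramolecular"
        if c1 == c2 == "mRNA_3utr":
            hybrid.category = "mRNA_3utr::mRNA_3utr_self"
        else:
            hybrid.category = f"{c1}::{c2}"
        if hybrid.arm1.transcript_id == hybrid.arm2.transcript_id:
            first, second = sorted((hybrid.arm1, hybrid.arm2), key=lambda a: a.start)
            hybrid.genomic_distance = max(0, second.start - first.end)
    else:
        hybrid.hybrid_class = "intermolecular"
        hybrid.category = f"{c1}::{c2}"
        hybrid.genomic_distance = None
    return hybrid


def _reciprocal_overlap(a: Arm, b: Arm) -> bool:
    if a.transcript_id != b.transcript_id:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= 0.5 * (a.end - a.start) and ov >= 0.5 * (b.end - b.start)


def unique_interactions(hybrids: Sequence[Hybrid], models: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    """Deduplicate hybrids into unique interactions with support counts.

    Two hybrids are the same interaction iff they involve the same unordered
    gene pair and each pair of corresponding arms reciprocally overlaps by at
    least 50%.  Output is sorted by support descending.
    """

    def gene(tx: str) -> str:
        m = models.get(tx)
        return m.gene_id if m else tx

    def canonical_arms(h: Hybrid) -> tuple[Arm, Arm]:
        key = lambda a: (gene(a.transcript_id), a.transcript_id, a.start)
        return tuple(sorted((h.arm1, h.arm2), key=key))  # type: ignore[return-value]

    groups: dict[frozenset, list[list]] = {}
    for h in hybrids:
        pair = frozenset((gene(h.arm1.transcript_id), gene(h.arm2.transcript_id)))
        a1, a2 = canonical_arms(h)
        merged = False
        for entry in groups.setdefault(pair, []):
            r1, r2 = entry[0]
            if _reciprocal_overlap(a1, r1) and _reciprocal_overlap(a2, r2):
                entry[1].append(h)
                merged = True
                break
        if not merged:
            groups[pair].append([(a1, a2), [h]])

    rows = []
    for pair, entries in groups.items():
        for (a1, a2), members in entries:
            rows.append({
                "gene_pair": "::".join(sorted(pair)),
                "tx1": a1.transcript_id, "start1": a1.start, "end1": a1.end,
                "tx2": a2.transcript_id, "start2": a2.start, "end2": a2.end,
                "hybrid_class": members[0].hybrid_class,
                "category": members[0].category,
                "support": len(members),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["support", "gene_pair", "start1"],
                            ascending=[False, True, True], kind="mergesort",
                            ignore_index=True)
    return df


def hybrids_from_table(df: pd.DataFrame, models: Mapping[str, TranscriptModel]) -> list[Hybrid]:
    """Rebuild Hybrid objects (with arm sequences) from a hyb-like table."""
    out = []
    for r in df.itertuples():
        def arm(tx: str, s: int, e: int, off: int) -> Arm:
            m = models.get(tx)
            seq = m.sequence[s:e] if m else ""
            return Arm(off, e - s, tx, int(s), int(e), seq)

        h = Hybrid(r.read_id, arm(r.tx1, r.start1, r.end1, 0),
                   arm(r.tx2, r.start2, r.end2, int(r.end1 - r.start1)))
        classify_hybrid(h, models)
        out.append(h)
    return out


def hybrid_fraction(n_hybrids: int, total_reads: int, confidence: float = 0.95) -> tuple[float, float, float]:
    """Hybrid percentage with exact binomial (Clopper-Pearson) CI, in percent."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    k, n = n_hybrids, total_reads
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * k / n, 100.0 * lo, 100.0 * hi


def class_composition(hybrids: Sequence[Hybrid]) -> pd.DataFrame:
    """Share of hybrids per category; shares sum to 100%."""
    counts: dict[str, int] = {}
    for h in hybrids:
        counts[h.category] = counts.get(h.category, 0) + 1
    total = sum(counts.values())
    rows = [
        (cat, n, 100.0 * n / total)
        for cat, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "share_pct"])
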