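"""Nearest-neighbor free energies for intermolecular RNA duplexes.

The engine scores only the duplex formed *between* two arms (no folding
within an arm), in the style of RNAduplex/RNAhybrid: a dynamic program finds
the non-crossing, antiparallel pairing minimizing

    dG = duplex initiation
       + sum of nearest-neighbor stack energies over adjacent pairs
       + affine interior-loop/bulge penalties (init + per-unpaired-nt)
       + terminal AU/GU penalties at both helix ends.

Parameters are 37 degC free energies shipped as a versioned plain-text table
(``data/rna_stack_dg37_v1.tsv``); swapping tables requires no code change.
Interior loops/bulges larger than the table's ``max_loop`` unpaired nt are
disallowed by the model.  If no pairing achieves dG < 0, the result is the
"no-duplex" sentinel with dG = 0.

Absolute energies are model-dependent; analyses downstream assert relative
comparisons between libraries (e.g. by Wilcoxon rank-sum), which is also what
this module's statistics support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WATSON_CRICK = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}
_AU_GU_ENDS = WATSON_CRICK - {("C", "G"), ("G", "C")} | WOBBLE

NO_DUPLEX = 0.0


class EnergyModel:
    """Nearest-neighbor parameter set loaded from a tab-separated table."""

    def __init__(self, stacks: Mapping[str, float], scalars: Mapping[str, float]):
        self.stacks = dict(stacks)
        self.duplex_init = scalars["duplex_init"]
        self.terminal_au_gu = scalars["terminal_au_gu"]
        self.loop_init = scalars["loop_init"]
        self.loop_per_nt = scalars["loop_per_nt"]
        self.max_loop = int(scalars["max_loop"])

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyModel":
        stacks: dict[str, float] = {}
        scalars: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                kind, key, value = line.rstrip("\n").split("\t")
                if kind == "stack":
                    stacks[key] = float(value)
                elif kind == "scalar":
                    scalars[key] = float(value)
                else:
                    raise ValueError(f"unknown parameter kind {kind!r}")
        return cls(stacks, scalars)

    @classmethod
    def default(cls) -> "EnergyModel":
        ref = resources.files("ripflash.data") / "rna_stack_dg37_v1.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def stack(self, a1: str, a2: str, b1: str, b2: str) -> float:
        """Stack of pairs (a1-b1) then (a2-b2): key 5'a1a2/3'b1b2."""
        return self.stacks[f"{a1}{a2}/{b1}{b2}"]

    def terminal(self, a: str, b: str) -> float:
        return self.terminal_au_gu if (a, b) in _AU_GU_ENDS else 0.0


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.default()
    return _DEFAULT_MODEL


@dataclass
class DuplexResult:
    """Minimum-energy pairing of two arms."""

    delta_g: float
    pairing: list[tuple[int, int]]  # (i in seq1, j in seq2), antiparallel
    allows_gu: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def is_duplex(self) -> bool:
        return bool(self.pairing)


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(c not in "ACGU" for c in s):
        bad = sorted({c for c in s if c not in "ACGU"})
        raise ValueError(f"non-nucleotide characters {bad} in sequence")
    return s


def _pair_ok(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in WATSON_CRICK or (allow_gu and (a, b) in WOBBLE)


def duplex_energy(
    seq1: str,
    seq2: str,
    allow_gu: bool = True,
    model: EnergyModel | None = None,
) -> DuplexResult:
    """Minimum free energy of the intermolecular duplex between two arms.

    Both sequences are given 5'->3' (T is read as U); pairing is antiparallel,
    so pair (i, j) followed by pair (i', j') requires i' > i and j' < j.
    Returns the optimal pairing, or the no-duplex sentinel (dG = 0, empty
    pairing) when no pairing with negative energy exists.
    """
    em = model or default_model()
    s1, s2 = _normalize(seq1), _normalize(seq2)
    if not (1 <= len(s1) <= 100 and 1 <= len(s2) <= 100):
        raise ValueError("sequences must be 1-100 nt")
    n, m = len(s1), len(s2)
    INF = math.inf
    # E[i][j]: best energy of a duplex whose rightmost-in-s1 pair is (i, j),
    # including initiation and the terminal penalty of the starting end.
    E = [[INF] * m for _ in range(n)]
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    max_loop = em.max_loop
    for i in range(n):
        a = s1[i]
        for j in range(m - 1, -1, -1):
            b = s2[j]
            if not _pair_ok(a, b, allow_gu):
                continue
            best = em.duplex_init + em.terminal(a, b)  # open the helix here
            best_prev: tuple[int, int] | None = None
            # predecessors (i', j') with gap a_gap unpaired in s1, b_gap in s2
            for a_gap in range(0, min(max_loop, i) + 1):
                ip = i - 1 - a_gap
                if ip < 0:
                    break
                for b_gap in range(0, min(max_loop - a_gap, m - 1 - j) + 1):
                    jp = j + 1 + b_gap
                    if jp >= m:
                        break
                    e_prev = E[ip][jp]
                    if e_prev == INF:
                        continue
                    if a_gap == 0 and b_gap == 0:
                        cand = e_prev + em.stack(s1[ip], a, s2[jp], b)
                    else:
                        cand = e_prev + em.loop_init + em.loop_per_nt * (a_gap + b_gap)
                    if cand < best:
                        best = cand
                        best_prev = (ip, jp)
            E[i][j] = best
            back[i][j] = best_prev

    best_g, best_end = NO_DUPLEX, None
    for i in range(n):
        for j in range(m):
            if E[i][j] == INF:
                continue
            g = E[i][j] + em.terminal(s1[i], s2[j])  # close the helix here
            if g < best_g - 1e-12:
                best_g, best_end = g, (i, j)

    if best_end is None:
        return DuplexResult(NO_DUPLEX, [], allow_gu)
    pairing: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = best_end
    while cur is not None:
        pairing.append(cur)
        cur = back[cur[0]][cur[1]]
    pairing.reverse()
    return DuplexResult(round(best_g, 10), pairing, allow_gu)


def annotate_hybrid_energies(
    hybrids: Iterable,
    models: Mapping,
    allow_gu: bool = True,
    energy_model: EnergyModel | None = None,
) -> list:
    """Fill ``delta_g`` on each hybrid from its arm matched sequences.

    Hybrids whose arm sequence cannot be retrieved are flagged
    (``delta_g = nan``) and excluded from distribution summaries.
    """
    out = []
    for h in hybrids:
        try:
            s1 = models[h.arm1.transcript_id].sequence[h.arm1.start : h.arm1.end]
            s2 = models[h.arm2.transcript_id].sequence[h.arm2.start : h.arm2.end]
            h.delta_g = duplex_energy(s1, s2, allow_gu, energy_model).delta_g
        except (KeyError, ValueError):
            h.delta_g = float("nan")
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float  # rank sum W of sample x in the pooled ranking
    p_value: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int
    mean_x: float
    mean_y: float


def _exact_ranksum_distribution(n1: int, n: int) -> np.ndarray:
    """Counts over rank sums of an n1-subset of ranks 1..n (DP, exact)."""
    max_sum = n1 * n
    # ways[k][s]: subsets of size k with rank-sum s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    ways[0][0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    return ways[n1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration of the rank-sum distribution when both samples
    have <= 12 observations and the pooled sample is tie-free; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction.  A statistic exactly at its null mean yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    mu = n1 * (n + 1) / 2.0

    if n1 <= 12 and n2 <= 12 and not has_ties:
        dist = _exact_ranksum_distribution(n1, n)
        total = dist.sum()
        dev = abs(w - mu)
        sums = np.arange(len(dist))
        p = float(dist[np.abs(sums - mu) >= dev - 1e-9].sum() / total)
        method = "exact"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float((counts**3 - counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0 or abs(w - mu) < 1e-12:
            return RankSumResult(w, 1.0, "normal_approx", n1, n2,
                                 float(x.mean()), float(y.mean()))
        z = (abs(w - mu) - 0.5) / math.sqrt(var)  # continuity correction
        # floor keeps p in (0, 1] even when the tail underflows
        p = float(min(1.0, max(2.0 * stats.norm.sf(z), 1e-300)))
        method = "normal_approx"
    return RankSumResult(w, min(1.0, p), method, n1, n2, float(x.mean()), float(y.mean()))


def energy_map(
    delta_g: Sequence[float],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-category energy distribution summaries for plotting.

    The no-duplex sentinel (dG = 0) and flagged hybrids (NaN) are excluded
    from the summaries but counted.  A pooled "all" row is always included.
    Returns columns: category, n, n_no_duplex, mean, median, decile_1..9.
    """
    dg = np.asarray(delta_g, dtype=float)
    pooled_only = categories is None
    if pooled_only:
        categories = ["all"] * len(dg)
    df = pd.DataFrame({"category": list(categories), "delta_g": dg})
    groups = [("all", df)]
    if not pooled_only:
        groups += [(c, g) for c, g in df.groupby("category", sort=True)]
    rows = []
    for name, g in groups:
        vals = g["delta_g"].to_numpy()
        excluded = np.isnan(vals) | (vals >= NO_DUPLEX)
        kept = vals[~excluded]
        row = {"category": name, "n": len(kept), "n_no_duplex": int(excluded.sum())}
        if len(kept):
            row["mean"] = float(kept.mean())
            row["median"] = float(np.median(kept))
            for d in range(1, 10):
                row[f"decile_{d}"] = float(np.quantile(kept, d / 10.0))
        rows.append(row)
    return pd.DataFrame(rows)
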