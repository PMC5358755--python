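"""Joining binding evidence to expression outcome.

Per-gene 3'UTR coverage and RPKM ratios (IP over input) are compared between
regulation directions with the Wilcoxon rank-sum test; gene-self hybrids are
tallied per direction; set overlaps against transcription-factor ChIP target
lists quantify how much of the post-transcriptional signal is explainable by
transcription; ddCt fold changes and actinomycin-chase half-life fits close
the loop on stability.

Ratios are kept finite with a symmetric pseudocount policy: coverage
fractions are floored at 1/(3'UTR length) and RPKM counts at +1 read, applied
to numerator and denominator alike.  Joins are audited: every input gene
lands in exactly one of joined / unmeasured / excluded-no-UTR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ripflash.cluster_calling import rpkm
from ripflash.duplex_thermo import RankSumResult, wilcoxon_rank_sum
from ripflash.io_formats import ReadAlignment, TranscriptModel

__all__ = [
    "rpkm",
    "utr3_coverage_ratio",
    "compute_gene_stats",
    "binding_regulation_association",
    "hybrid_regulation_table",
    "overlap_report",
    "ddct_fold_change",
    "fit_decay",
    "DecayFit",
]


# ---------------------------------------------------------------------------
# Coverage / RPKM ratios
# ---------------------------------------------------------------------------

def _covered_nt(spans: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in spans if s < hi and e > lo
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def utr3_coverage_ratio(
    rip_spans: Sequence[tuple[int, int]],
    input_spans: Sequence[tuple[int, int]],
    model: TranscriptModel,
) -> tuple[float, float, float]:
    """(ratio, covered_fraction_rip, covered_fraction_input) over the 3'UTR.

    Covered fraction is the interval-union coverage of the 3'UTR; both
    fractions are floored at 1/(UTR length) before the ratio."""
    region = model.region_of("utr3")
    if region is None:
        raise ValueError(f"{model.transcript_id} has no annotated 3'UTR")
    _, lo, hi = region
    length = hi - lo
    f_rip = _covered_nt(rip_spans, lo, hi) / length
    f_inp = _covered_nt(input_spans, lo, hi) / length
    eps = 1.0 / length
    return max(f_rip, eps) / max(f_inp, eps), f_rip, f_inp


def compute_gene_stats(
    rip_alignments: Iterable[ReadAlignment],
    input_alignments: Iterable[ReadAlignment],
    models: Mapping[str, TranscriptModel],
    de_table: pd.DataFrame | None = None,
    hybrids: Sequence | None = None,
    chip_targets: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene binding statistics joined to DE outcome.

    Returns the stats frame plus an audit of the join: every coding gene in
    the transcriptome lands in exactly one of joined / unmeasured (no DE row)
    / excluded_no_utr.
    """
    rip_by_tx: dict[str, list[tuple[int, int]]] = {}
    n_rip = 0
    for a in rip_alignments:
        if a.strand == "+" and a.transcript_id in models:
            rip_by_tx.setdefault(a.transcript_id, []).append((a.start, a.end))
            n_rip += 1
    inp_by_tx: dict[str, list[tuple[int, int]]] = {}
    n_inp = 0
    for a in input_alignments:
        if a.strand == "+" and a.transcript_id in models:
            inp_by_tx.setdefault(a.transcript_id, []).append((a.start, a.end))
            n_inp += 1

    directions: dict[str, str] = {}
    if de_table is not None:
        directions = {
            str(g).lower(): d for g, d in zip(de_table["gene_id"], de_table["direction"])
        }
    self_hybrids: dict[str, int] = {}
    if hybrids is not None:
        for h in hybrids:
            if h.hybrid_class == "intramolecular":
                m = models.get(h.arm1.transcript_id)
                g = m.gene_id if m else h.arm1.transcript_id
                self_hybrids[g] = self_hybrids.get(g, 0) + 1
    chip = {g.lower() for g in chip_targets} if chip_targets else set()

    rows = []
    audit = {"joined": 0, "unmeasured": 0, "excluded_no_utr": 0}
    for tx, model in models.items():
        if model.biotype != "protein_coding":
            continue
        region = model.region_of("utr3")
        if region is None:
            audit["excluded_no_utr"] += 1
            continue
        _, lo, hi = region
        utr_len = hi - lo
        rip_spans = rip_by_tx.get(tx, [])
        inp_spans = inp_by_tx.get(tx, [])
        cov_ratio, _, _ = utr3_coverage_ratio(rip_spans, inp_spans, model)
        # RPKM ratios with a symmetric +1 read pseudocount
        k_rip_utr = sum(1 for s, e in rip_spans if s < hi and e > lo)
        k_inp_utr = sum(1 for s, e in inp_spans if s < hi and e > lo)
        n_rip_eff, n_inp_eff = max(n_rip, 1), max(n_inp, 1)
        ratio_utr = (rpkm(k_rip_utr + 1, utr_len, n_rip_eff)
                     / rpkm(k_inp_utr + 1, utr_len, n_inp_eff))
        ratio_tx = (rpkm(len(rip_spans) + 1, model.length, n_rip_eff)
                    / rpkm(len(inp_spans) + 1, model.length, n_inp_eff))
        direction = directions.get(model.gene_id.lower())
        if direction is None:
            audit["unmeasured"] += 1
            direction = "unmeasured"
        else:
            audit["joined"] += 1
        rows.append({
            "gene_id": model.gene_id,
            "utr3_coverage_ratio": cov_ratio,
            "rpkm_ratio_utr3": ratio_utr,
            "rpkm_ratio_tx": ratio_tx,
            "n_hybrids": self_hybrids.get(model.gene_id, 0),
            "de_direction": direction,
            "chip_target": model.gene_id.lower() in chip,
        })
    return pd.DataFrame(rows), audit


# ---------------------------------------------------------------------------
# Binding vs regulation
# ---------------------------------------------------------------------------

def binding_regulation_association(gene_stats: pd.DataFrame) -> dict:
    """Compare log binding ratios between regulation directions.

    Down-regulated genes are tested against unregulated and against
    up-regulated genes (Wilcoxon rank-sum on log coverage ratio and log RPKM
    ratio).  Returns group medians/sizes, test results, and a scatter-ready
    table (gene_id, log_cov_ratio, log_rpkm_ratio, direction).  Comparisons
    with an empty group are skipped with a notice.
    """
    df = gene_stats.copy()
    df["log_cov_ratio"] = np.log2(df["utr3_coverage_ratio"])
    df["log_rpkm_ratio"] = np.log2(df["rpkm_ratio_utr3"])
    scatter = df[["gene_id", "log_cov_ratio", "log_rpkm_ratio", "de_direction"]].rename(
        columns={"de_direction": "direction"}
    )
    report: dict = {"scatter": scatter, "groups": {}, "tests": {}, "skipped": []}
    grouped = {d: g for d, g in df.groupby("de_direction")}
    for d, g in grouped.items():
        report["groups"][d] = {
            "n": len(g),
            "median_log_cov_ratio": float(g["log_cov_ratio"].median()),
            "median_log_rpkm_ratio": float(g["log_rpkm_ratio"].median()),
        }
    for other in ("unregulated", "up"):
        for metric in ("log_cov_ratio", "log_rpkm_ratio"):
            name = f"down_vs_{other}_{metric}"
            down = grouped.get("down")
            comp = grouped.get(other)
            if down is None or comp is None or len(down) < 2 or len(comp) < 2:
                report["skipped"].append(name)
                continue
            report["tests"][name] = wilcoxon_rank_sum(
                down[metric].to_numpy(), comp[metric].to_numpy()
            )
    return report


def hybrid_regulation_table(
    hybrids: Sequence,
    de_table: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Counts of gene-self hybrids per DE direction.

    One row per direction (plus "unmeasured" for genes absent from the DE
    table): number of genes with >= 1 gene-self hybrid, total gene-self
    hybrid count, and the share of interacting genes that are up-regulated
    is derivable from the gene counts.
    """
    directions = {
        str(g).lower(): d for g, d in zip(de_table["gene_id"], de_table["direction"])
    }
    per_gene: dict[str, int] = {}
    for h in hybrids:
        if h.hybrid_class != "intramolecular":
            continue
        m = models.get(h.arm1.transcript_id)
        g = m.gene_id if m else h.arm1.transcript_id
        per_gene[g] = per_gene.get(g, 0) + 1
    tallies: dict[str, list[int]] = {}
    for gene, n in per_gene.items():
        d = directions.get(gene.lower(), "unmeasured")
        t = tallies.setdefault(d, [0, 0])
        t[0] += 1
        t[1] += n
    rows = [
        {"direction": d, "n_genes": t[0], "n_self_hybrids": t[1]}
        for d, t in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["direction", "n_genes", "n_self_hybrids"])


def overlap_report(sets: Mapping[str, Iterable[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise intersections and a k-way membership table.

    Identifiers are case-normalized before comparison.  Returns
    (pairwise, membership): pairwise has |A|, |B|, |A & B| and Jaccard per
    unordered pair; membership flags every gene's presence in each set.
    """
    norm = {name: {str(g).lower() for g in genes} for name, genes in sets.items()}
    names = sorted(norm)
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(norm[a] & norm[b])
            union = len(norm[a] | norm[b])
            pair_rows.append({
                "set_a": a, "set_b": b,
                "size_a": len(norm[a]), "size_b": len(norm[b]),
                "intersection": inter,
                "jaccard": inter / union if union else 0.0,
            })
    universe = sorted(set().union(*norm.values())) if norm else []
    member_rows = [
        {"gene_id": g, **{name: g in norm[name] for name in names}} for g in universe
    ]
    return pd.DataFrame(pair_rows), pd.DataFrame(member_rows)


# ---------------------------------------------------------------------------
# qPCR ddCt
# ---------------------------------------------------------------------------

def _check_ct(values: np.ndarray, label: str) -> np.ndarray:
    if values.size == 0:
        raise ValueError(f"missing Ct values for {label}")
    if np.any((values < 0) | (values > 45)):
        raise ValueError(f"{label}: Ct values outside the plausible 0-45 range")
    return values


def ddct_fold_change(
    ct_target_cond: float | Sequence[float],
    ct_reference_cond: float | Sequence[float],
    ct_target_ctrl: float | Sequence[float],
    ct_reference_ctrl: float | Sequence[float],
) -> dict:
    """Relative expression by the ddCt method: fold = 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference)_condition - (Ct_target - Ct_reference)_control.
    With replicate series, dCt is computed per replicate and the fold change
    reported as mean with SD, plus a two-sided Welch t-test of the dCt values
    condition vs control.
    """
    tc = _check_ct(np.atleast_1d(np.asarray(ct_target_cond, dtype=float)), "target/condition")
    rc = _check_ct(np.atleast_1d(np.asarray(ct_reference_cond, dtype=float)), "reference/condition")
    tk = _check_ct(np.atleast_1d(np.asarray(ct_target_ctrl, dtype=float)), "target/control")
    rk = _check_ct(np.atleast_1d(np.asarray(ct_reference_ctrl, dtype=float)), "reference/control")
    if len(tc) != len(rc) or len(tk) != len(rk):
        raise ValueError("target and reference Ct series must have equal length")
    dct_cond = tc - rc
    dct_ctrl = tk - rk
    ddct = float(dct_cond.mean() - dct_ctrl.mean())
    folds = 2.0 ** (-(dct_cond - dct_ctrl.mean()))
    result = {
        "ddct": ddct,
        "fold_change": float(2.0 ** (-ddct)),
        "fold_mean": float(folds.mean()),
        "fold_sd": float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
        "n_replicates": len(dct_cond),
    }
    if len(dct_cond) > 1 and len(dct_ctrl) > 1:
        t, p = stats.ttest_ind(dct_cond, dct_ctrl, equal_var=False)
        result["t_statistic"], result["p_value"] = float(t), float(p)
    return result


# ---------------------------------------------------------------------------
# Actinomycin decay
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """First-order decay fit on an actinomycin-chase timecourse."""

    gene_id: str
    decay_rate: float  # per hour; lambda in N(t) = N0 * exp(-lambda t)
    half_life: float  # hours; inf when not decaying
    r_squared: float
    n_points: int

    @property
    def decaying(self) -> bool:
        return self.decay_rate > 0


def fit_decay(
    timepoints_h: Sequence[float],
    relative_expression_pct: Sequence[float],
    gene_id: str = ".",
) -> DecayFit:
    """Least squares of ln(expression) on time; half-life = ln2 / lambda.

    Requires >= 3 timepoints including t = 0 and strictly positive expression.
    A non-positive decay rate is reported as not decaying (infinite
    half-life)."""
    t = np.asarray(timepoints_h, dtype=float)
    y = np.asarray(relative_expression_pct, dtype=float)
    if len(t) != len(y) or len(t) < 3:
        raise ValueError("need >= 3 matched timepoints")
    if not np.any(t == 0):
        raise ValueError("timepoints must include 0")
    if np.any(y <= 0):
        raise ValueError("expression must be positive (log-linear fit)")
    fit = stats.linregress(t, np.log(y))
    lam = -float(fit.slope)
    half_life = math.log(2) / lam if lam > 0 else float("inf")
    return DecayFit(gene_id, lam, half_life, float(fit.rvalue**2), len(t))


def fit_decay_table(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Fit every gene of a tidy timecourse (gene_id, time_h, relative_expression).

    Replicate rows at the same timepoint all enter the regression."""
    rows = []
    for gene, g in timecourse.groupby("gene_id"):
        fit = fit_decay(g["time_h"].to_numpy(), g["relative_expression"].to_numpy(), gene)
        rows.append({
            "gene_id": gene, "decay_rate": fit.decay_rate,
            "half_life_h": fit.half_life, "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        })
    return pd.DataFrame(rows)


def compare_half_lives(control: pd.DataFrame, knockdown: pd.DataFrame) -> pd.DataFrame:
    """Paired per-gene half-life report, control vs regulator loss.

    ``destabilized`` marks genes whose half-life shortens on knockdown, the
    signature of a stabilizing regulator."""
    merged = control.merge(knockdown, on="gene_id", suffixes=("_control", "_knockdown"))
    merged["destabilized"] = merged["half_life_h_knockdown"] < merged["half_life_h_control"]
    return merged[["gene_id", "half_life_h_control", "half_life_h_knockdown", "destabilized"]]
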