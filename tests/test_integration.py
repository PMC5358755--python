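"""Coverage/RPKM ratios, association tests, set overlaps, ddCt, decay fits."""

import numpy as np
import pandas as pd
import pytest

from ripflash.hybrid_analysis import Arm, Hybrid, classify_hybrid
from ripflash.integration import (
    binding_regulation_association,
    compute_gene_stats,
    ddct_fold_change,
    fit_decay,
    fit_decay_table,
    compare_half_lives,
    hybrid_regulation_table,
    overlap_report,
    rpkm,
    utr3_coverage_ratio,
)
from ripflash.io_formats import ReadAlignment
from ripflash import synthetic_data as sd


class TestCoverageRatio:
    def test_arithmetic_example(self, tiny_models):
        model = tiny_models["txA"]  # utr3 = [400, 600), 200 nt
        rip = [(400, 500)]  # covers 100/200
        inp = [(400, 450)]  # covers 50/200
        ratio, f_rip, f_inp = utr3_coverage_ratio(rip, inp, model)
        assert (f_rip, f_inp) == (0.5, 0.25)
        assert ratio == pytest.approx(2.0)

    def test_identical_coverage_gives_unity(self, tiny_models):
        spans = [(420, 470), (480, 530)]
        ratio, _, _ = utr3_coverage_ratio(spans, spans, tiny_models["txA"])
        assert ratio == pytest.approx(1.0)

    def test_zero_coverage_floored_by_pseudofraction(self, tiny_models):
        ratio, _, _ = utr3_coverage_ratio([(400, 600)], [], tiny_models["txA"])
        assert ratio == pytest.approx(1.0 / (1.0 / 200))  # 1 / eps

    def test_no_utr_rejected(self, tiny_models):
        with pytest.raises(ValueError, match="no annotated"):
            utr3_coverage_ratio([], [], tiny_models["mirX"])

    def test_interval_union_matches_per_base_marking(self, rng, tiny_models):
        model = tiny_models["txA"]
        for _ in range(300):
            n = int(rng.integers(1, 15))
            spans = []
            for _ in range(n):
                s = int(rng.integers(350, 590))
                spans.append((s, s + int(rng.integers(1, 60))))
            mask = np.zeros(600, bool)
            for s, e in spans:
                mask[s:e] = True
            expected = mask[400:600].sum() / 200
            _, f_rip, _ = utr3_coverage_ratio(spans, [], model)
            assert f_rip == pytest.approx(expected)


class TestGeneStats:
    def test_join_audit_is_lossless(self, tiny_models):
        rip = [ReadAlignment("r1", "txA", 420, 470)]
        de = pd.DataFrame({"gene_id": ["gA"], "direction": ["down"]})
        stats, audit = compute_gene_stats(rip, [], tiny_models, de)
        assert audit == {"joined": 1, "unmeasured": 0, "excluded_no_utr": 0}
        assert stats.iloc[0]["de_direction"] == "down"

    def test_unmeasured_gene_counted(self, tiny_models):
        de = pd.DataFrame({"gene_id": ["other"], "direction": ["up"]})
        stats, audit = compute_gene_stats([], [], tiny_models, de)
        assert audit["unmeasured"] == 1
        assert stats.iloc[0]["de_direction"] == "unmeasured"


class TestAssociation:
    def test_identical_ratios_give_p_one(self):
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "utr3_coverage_ratio": [1.0] * 20,
            "rpkm_ratio_utr3": [1.0] * 20,
            "rpkm_ratio_tx": [1.0] * 20,
            "n_hybrids": [0] * 20,
            "de_direction": ["down"] * 10 + ["unregulated"] * 10,
            "chip_target": [False] * 20,
        })
        report = binding_regulation_association(df)
        test = report["tests"]["down_vs_unregulated_log_cov_ratio"]
        assert test.p_value == pytest.approx(1.0)
        g = report["groups"]
        assert g["down"]["median_log_cov_ratio"] == g["unregulated"]["median_log_cov_ratio"]

    def test_planted_coupling_detected(self, rng):
        n = 120
        ratios_down = 2.0 ** rng.normal(1.5, 0.5, size=n)
        ratios_unreg = 2.0 ** rng.normal(0.0, 0.5, size=n)
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(2 * n)],
            "utr3_coverage_ratio": np.concatenate([ratios_down, ratios_unreg]),
            "rpkm_ratio_utr3": np.concatenate([ratios_down, ratios_unreg]),
            "rpkm_ratio_tx": np.ones(2 * n),
            "n_hybrids": np.zeros(2 * n, int),
            "de_direction": ["down"] * n + ["unregulated"] * n,
            "chip_target": [False] * 2 * n,
        })
        report = binding_regulation_association(df)
        test = report["tests"]["down_vs_unregulated_log_cov_ratio"]
        assert test.p_value < 0.01
        assert (report["groups"]["down"]["median_log_cov_ratio"]
                > report["groups"]["unregulated"]["median_log_cov_ratio"])

    def test_missing_group_skipped_with_notice(self):
        df = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "utr3_coverage_ratio": [1.0, 2.0],
            "rpkm_ratio_utr3": [1.0, 2.0],
            "rpkm_ratio_tx": [1.0, 1.0],
            "n_hybrids": [0, 0],
            "de_direction": ["down", "down"],
            "chip_target": [False, False],
        })
        report = binding_regulation_association(df)
        assert "down_vs_unregulated_log_cov_ratio" in report["skipped"]


class TestHybridRegulationTable:
    def test_arithmetic_fixture_totals(self, tiny_models, small_study):
        """3 down genes with 100+100+52 self-hybrids and 1 up gene with 15:
        down total 252 of 267."""
        models = small_study["models"]
        coding = [m for m in models.values() if m.biotype == "protein_coding"][:4]
        counts = [100, 100, 52, 15]
        directions = ["down", "down", "down", "up"]
        hybrids = []
        for m, k in zip(coding, counts):
            _, us, ue = m.region_of("utr3")
            for i in range(k):
                h = Hybrid(f"{m.transcript_id}_{i}",
                           Arm(0, 25, m.transcript_id, us, us + 25, ""),
                           Arm(25, 25, m.transcript_id, ue - 25, ue, ""))
                classify_hybrid(h, models)
                hybrids.append(h)
        de = pd.DataFrame({"gene_id": [m.gene_id for m in coding],
                           "direction": directions})
        table = hybrid_regulation_table(hybrids, de, models).set_index("direction")
        assert table.loc["down", "n_self_hybrids"] == 252
        assert table.loc["down", "n_genes"] == 3
        assert int(table["n_self_hybrids"].sum()) == 267

    def test_no_hybrids_gives_empty_table(self, tiny_models):
        de = pd.DataFrame({"gene_id": ["gA"], "direction": ["down"]})
        assert len(hybrid_regulation_table([], de, tiny_models)) == 0

    def test_unmeasured_gene_bucketed(self, tiny_models):
        h = Hybrid("r", Arm(0, 25, "txA", 420, 445, ""), Arm(25, 25, "txA", 500, 525, ""))
        classify_hybrid(h, tiny_models)
        de = pd.DataFrame({"gene_id": ["somebody_else"], "direction": ["down"]})
        table = hybrid_regulation_table([h], de, tiny_models)
        assert list(table["direction"]) == ["unmeasured"]


class TestOverlapReport:
    def test_published_style_intersection_counts(self):
        a = {f"de{i}" for i in range(156)}
        b = {f"de{i}" for i in range(22)} | {f"chip{i}" for i in range(1749)}
        pairwise, _ = overlap_report({"de": a, "chip": b})
        row = pairwise.iloc[0]
        sizes = {row["set_a"]: row["size_a"], row["set_b"]: row["size_b"]}
        assert sizes == {"de": 156, "chip": 1771}
        assert row["intersection"] == 22

    def test_disjoint_sets(self):
        pairwise, member = overlap_report({"a": {"x"}, "b": {"y"}})
        assert pairwise.iloc[0]["intersection"] == 0
        assert pairwise.iloc[0]["jaccard"] == 0.0
        assert len(member) == 2

    def test_subset_jaccard(self):
        pairwise, _ = overlap_report({"a": {"x", "y"}, "b": {"x", "y", "z", "w"}})
        row = pairwise.iloc[0]
        assert row["intersection"] == 2
        assert row["jaccard"] == pytest.approx(0.5)

    def test_case_normalization(self):
        pairwise, _ = overlap_report({"a": {"Igfbp5"}, "b": {"IGFBP5"}})
        assert pairwise.iloc[0]["intersection"] == 1


class TestDdct:
    def test_identity_when_all_ct_equal(self):
        assert ddct_fold_change(20, 20, 20, 20)["fold_change"] == pytest.approx(1.0)

    def test_one_cycle_higher_halves_expression(self):
        res = ddct_fold_change(21, 20, 20, 20)
        assert res["fold_change"] == pytest.approx(0.5)

    def test_thirty_fold_knockdown_recovered_with_replicates(self, rng):
        ddct_true = np.log2(30)  # ~4.91 cycles
        tc = 20 + ddct_true + rng.normal(0, 0.08, size=6)
        rc = np.full(6, 15.0) + rng.normal(0, 0.08, size=6)
        tk = np.full(6, 20.0) + rng.normal(0, 0.08, size=6)
        rk = np.full(6, 15.0) + rng.normal(0, 0.08, size=6)
        res = ddct_fold_change(tc, rc, tk, rk)
        assert res["fold_change"] == pytest.approx(1 / 30, rel=0.25)
        assert res["p_value"] < 1e-6

    def test_implausible_ct_rejected(self):
        with pytest.raises(ValueError, match="0-45"):
            ddct_fold_change(99, 20, 20, 20)


class TestFitDecay:
    def test_exact_halving_series(self):
        fit = fit_decay([0, 1, 2], [100, 50, 25])
        assert fit.half_life == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_not_decaying(self):
        fit = fit_decay([0, 1, 2], [100, 100, 100])
        assert not fit.decaying
        assert fit.half_life == float("inf")

    def test_nonpositive_expression_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_decay([0, 1, 2], [100, 0, 25])

    def test_simulated_half_lives_recovered_within_ten_percent(self):
        truths = {"a": 0.5, "b": 1.0, "c": 2.0, "d": 4.0}
        tc = sd.simulate_decay_series(truths, [0, 0.5, 1, 2, 4, 8], 0.05,
                                      seed=5, n_replicates=3)
        fits = fit_decay_table(tc).set_index("gene_id")
        for gene, t_half in truths.items():
            assert fits.loc[gene, "half_life_h"] == pytest.approx(t_half, rel=0.10)

    def test_knockdown_destabilization_flagged(self):
        ctrl = sd.simulate_decay_series({"g": 4.0}, [0, 1, 2, 4], 0.0, seed=1)
        kd = sd.simulate_decay_series({"g": 1.0}, [0, 1, 2, 4], 0.0, seed=1)
        paired = compare_half_lives(fit_decay_table(ctrl), fit_decay_table(kd))
        assert bool(paired.iloc[0]["destabilized"])


class TestRpkmReexport:
    def test_same_function_as_cluster_calling(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)
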