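"""Chimera detection correctness, interaction dedup, composition summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from ripflash.hybrid_analysis import (
    Arm,
    Hybrid,
    build_index,
    class_composition,
    classify_hybrid,
    detect_chimeras,
    hybrid_fraction,
    unique_interactions,
)


class TestIndex:
    def test_unique_20mer_found_at_planted_coordinate(self, tiny_models):
        seq = tiny_models["txA"].sequence
        index = build_index(tiny_models)
        hits = index.lookup(seq[100:112])
        assert ("txA", 100) in hits

    def test_absent_query_has_no_hits(self, tiny_models):
        index = build_index(tiny_models)
        assert index.lookup("N" * 12) == []

    def test_duplicate_transcript_ids_rejected(self, tiny_models):
        models = list(tiny_models.values())
        with pytest.raises(ValueError, match="duplicate"):
            build_index(models + [models[0]])

    def test_planted_queries_all_recovered(self, rng, tiny_models):
        index = build_index(tiny_models)
        seq = tiny_models["txA"].sequence
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - 20))
            hits = index.lookup(seq[pos : pos + 12])
            assert ("txA", pos) in hits


class TestDetectChimeras:
    def test_mrna_mirna_chimera_detected_with_class(self, tiny_models):
        utr = tiny_models["txA"].sequence[450:475]
        mir = tiny_models["mirX"].sequence
        index = build_index(tiny_models)
        res = detect_chimeras([("c1", utr + mir)], index)
        assert len(res.hybrids) == 1
        h = res.hybrids[0]
        assert h.hybrid_class == "intermolecular"
        assert h.category == "mRNA_3utr::miRNA"
        assert (h.arm1.transcript_id, h.arm1.start) == ("txA", 450)
        assert (h.arm2.transcript_id, h.arm2.start, h.arm2.end) == ("mirX", 0, 22)

    def test_contiguous_read_not_a_hybrid(self, tiny_models):
        seq = tiny_models["txA"].sequence[100:150]
        index = build_index(tiny_models)
        res = detect_chimeras([("r1", seq)], index)
        assert res.contiguous == ["r1"] and not res.hybrids

    def test_intramolecular_distance(self, tiny_models):
        seq = tiny_models["txA"].sequence
        read = seq[410:435] + seq[500:525]
        index = build_index(tiny_models)
        res = detect_chimeras([("r1", read)], index)
        assert len(res.hybrids) == 1
        h = res.hybrids[0]
        assert h.hybrid_class == "intramolecular"
        assert h.category == "mRNA_3utr::mRNA_3utr_self"
        # the junction is ambiguous by up to max_read_overlap nt when bases
        # beyond the break happen to match the reference
        assert 500 - 435 - 4 <= h.genomic_distance <= 500 - 435

    def test_short_read_cannot_be_chimeric(self, tiny_models):
        index = build_index(tiny_models)
        res = detect_chimeras([("r1", "ACGTACGTACGTACGTACGTACG")], index, min_arm=17)
        assert not res.hybrids

    def test_detection_invariant_to_read_order(self, small_study):
        models, reads = small_study["models"], small_study["flash_reads"]
        index = build_index(models)
        fwd = detect_chimeras(reads, index)
        rev = detect_chimeras(list(reversed(reads)), index)
        key = lambda h: (h.read_id, h.arm1.start, h.arm2.start)
        assert sorted(map(key, fwd.hybrids)) == sorted(map(key, rev.hybrids))

    def test_planted_hybrids_all_recovered(self, small_study):
        models = small_study["models"]
        index = build_index(models)
        res = detect_chimeras(small_study["flash_reads"], index)
        detected = {h.read_id: h for h in res.hybrids}
        truth = small_study["flash_truth"].planted_hybrids
        assert truth
        for t in truth:
            h = detected[t["read_id"]]
            assert h.hybrid_class == t["hybrid_class"]
            assert h.arm1.start == t["start1"]
            assert h.arm2.end == t["end2"]

    def test_arm_sequences_realign_to_reference(self, small_study):
        models = small_study["models"]
        index = build_index(models)
        res = detect_chimeras(small_study["flash_reads"], index)
        for h in res.hybrids:
            for arm in (h.arm1, h.arm2):
                ref = models[arm.transcript_id].sequence
                assert ref[arm.start : arm.end] == arm.matched_sequence


class TestClassify:
    def _arm(self, tx, start, end):
        return Arm(0, end - start, tx, start, end, "")

    def test_gene_self_3utr(self, tiny_models):
        h = Hybrid("r", self._arm("txA", 420, 445), self._arm("txA", 500, 525))
        classify_hybrid(h, tiny_models)
        assert (h.hybrid_class, h.category) == ("intramolecular", "mRNA_3utr::mRNA_3utr_self")

    def test_cds_mirna(self, tiny_models):
        h = Hybrid("r", self._arm("txA", 150, 175), self._arm("mirX", 0, 22))
        classify_hybrid(h, tiny_models)
        assert (h.hybrid_class, h.category) == ("intermolecular", "mRNA_cds::miRNA")

    def test_unannotated_arm_uses_body(self, tiny_models):
        h = Hybrid("r", self._arm("txA", 450, 475), self._arm("ghost", 0, 25))
        classify_hybrid(h, tiny_models)
        assert h.category == "mRNA_3utr::body"


class TestUniqueInteractions:
    def _hybrid(self, rid, tx1, s1, tx2, s2, length=25):
        h = Hybrid(rid, Arm(0, length, tx1, s1, s1 + length, ""),
                   Arm(length, length, tx2, s2, s2 + length, ""))
        return h

    def test_identical_arms_collapse_with_support(self, tiny_models):
        hybrids = [self._hybrid("a", "txA", 420, "txA", 500),
                   self._hybrid("b", "txA", 420, "txA", 500)]
        for h in hybrids:
            classify_hybrid(h, tiny_models)
        df = unique_interactions(hybrids, tiny_models)
        assert len(df) == 1 and df.iloc[0]["support"] == 2

    def test_distant_arms_stay_separate(self, tiny_models):
        hybrids = [self._hybrid("a", "txA", 100, "lincB", 10),
                   self._hybrid("b", "txA", 300, "lincB", 310)]
        for h in hybrids:
            classify_hybrid(h, tiny_models)
        df = unique_interactions(hybrids, tiny_models)
        assert len(df) == 2

    def test_planted_interactions_counted_exactly(self, rng, small_study):
        """Each planted locus pair sequenced 1-10x yields one interaction."""
        models = small_study["models"]
        coding = [m for m in models.values()
                  if m.biotype == "protein_coding" and m.length > 300]
        hybrids = []
        n_planted = 100
        for i in range(n_planted):
            m1, m2 = rng.choice(coding, size=2, replace=False)
            s1 = int(rng.integers(0, m1.length - 25))
            s2 = int(rng.integers(0, m2.length - 25))
            for c in range(int(rng.integers(1, 11))):
                h = self._hybrid(f"i{i}c{c}", m1.transcript_id, s1,
                                 m2.transcript_id, s2)
                classify_hybrid(h, models)
                hybrids.append(h)
        df = unique_interactions(hybrids, models)
        assert len(df) == n_planted
        assert df["support"].is_monotonic_decreasing


class TestHybridFraction:
    def test_percentage_arithmetic(self):
        frac, lo, hi = hybrid_fraction(49, 10_000)
        assert frac == pytest.approx(0.49)
        assert lo < 0.49 < hi

    def test_zero_hybrids(self):
        frac, lo, hi = hybrid_fraction(0, 1000)
        assert frac == 0.0 and lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 1000)), rel=1e-6)

    def test_clopper_pearson_matches_beta_quantiles(self):
        frac, lo, hi = hybrid_fraction(5, 100)
        assert lo == pytest.approx(100 * sps.beta.ppf(0.025, 5, 96))
        assert hi == pytest.approx(100 * sps.beta.ppf(0.975, 6, 95))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hybrid_fraction(0, 0)


class TestClassComposition:
    def test_shares_sum_to_hundred(self, tiny_models):
        hybrids = []
        for i, (tx2, s2) in enumerate([("txA", 500)] * 52 + [("mirX", 0)] * 5
                                      + [("lincB", 10)] * 43):
            h = Hybrid(f"r{i}", Arm(0, 25, "txA", 420, 445, ""),
                       Arm(25, 22, tx2, s2, s2 + 22, ""))
            classify_hybrid(h, tiny_models)
            hybrids.append(h)
        df = class_composition(hybrids)
        assert df["share_pct"].sum() == pytest.approx(100.0)
        shares = dict(zip(df["category"], df["share_pct"]))
        assert shares["mRNA_3utr::mRNA_3utr_self"] == pytest.approx(52.0)
        assert shares["mRNA_3utr::miRNA"] == pytest.approx(5.0)

    def test_single_category_is_total(self, tiny_models):
        h = Hybrid("r", Arm(0, 25, "txA", 420, 445, ""), Arm(25, 22, "mirX", 0, 22, ""))
        classify_hybrid(h, tiny_models)
        df = class_composition([h])
        assert df.iloc[0]["share_pct"] == pytest.approx(100.0)
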