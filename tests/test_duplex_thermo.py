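"""Duplex energy DP vs brute-force enumeration; rank-sum exactness."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ripflash.duplex_thermo import (
    DuplexResult,
    EnergyModel,
    default_model,
    duplex_energy,
    energy_map,
    wilcoxon_rank_sum,
    WATSON_CRICK,
    WOBBLE,
)


def _pair_ok(a, b, allow_gu=True):
    return (a, b) in WATSON_CRICK or (allow_gu and (a, b) in WOBBLE)


def brute_force_duplex(s1, s2, allow_gu=True, em=None):
    """Minimum dG over an exhaustive enumeration of all non-crossing,
    antiparallel pairings under the same scoring model (loop cap included).

    Independent of the DP: plain recursion over ordered pair choices."""
    em = em or default_model()
    s1 = s1.upper().replace("T", "U")
    s2 = s2.upper().replace("T", "U")
    n, m = len(s1), len(s2)
    best = [0.0]

    def rec(last_i, last_j, g):
        cand = g + em.terminal(s1[last_i], s2[last_j])
        if cand < best[0]:
            best[0] = cand
        for i in range(last_i + 1, n):
            a_gap = i - last_i - 1
            if a_gap > em.max_loop:
                break
            for j in range(last_j - 1, -1, -1):
                b_gap = last_j - j - 1
                if a_gap + b_gap > em.max_loop:
                    break
                if _pair_ok(s1[i], s2[j], allow_gu):
                    if a_gap == 0 and b_gap == 0:
                        add = em.stack(s1[last_i], s1[i], s2[last_j], s2[j])
                    else:
                        add = em.loop_init + em.loop_per_nt * (a_gap + b_gap)
                    rec(i, j, g + add)

    for i in range(n):
        for j in range(m):
            if _pair_ok(s1[i], s2[j], allow_gu):
                rec(i, j, em.duplex_init + em.terminal(s1[i], s2[j]))
    return best[0]


class TestDuplexEnergy:
    def test_no_complementary_pairs_is_no_duplex(self):
        r = duplex_energy("AAAA", "AAAA")
        assert r.delta_g == 0.0 and not r.is_duplex

    def test_perfect_gc_helix_hand_summed_from_table(self):
        em = default_model()
        r = duplex_energy("GGGGG", "CCCCC", model=em)
        expected = em.duplex_init + 4 * em.stacks["GG/CC"]
        assert r.delta_g == pytest.approx(expected)
        assert r.pairing == [(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)]

    def test_terminal_au_penalty_applied_at_both_ends(self):
        em = default_model()
        r = duplex_energy("AGGGA", "UCCCU", model=em)
        expected = (em.duplex_init + 2 * em.terminal_au_gu
                    + em.stacks["AG/UC"] + 2 * em.stacks["GG/CC"]
                    + em.stacks["GA/CU"])
        assert r.delta_g == pytest.approx(expected)

    def test_determinism(self):
        a = duplex_energy("GCAUGCCA", "UGGCAUGC")
        b = duplex_energy("GCAUGCCA", "UGGCAUGC")
        assert a.delta_g == b.delta_g and a.pairing == b.pairing

    def test_strand_swap_symmetry(self, rng):
        for _ in range(30):
            s1 = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 12))))
            s2 = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 12))))
            assert duplex_energy(s1, s2).delta_g == pytest.approx(
                duplex_energy(s2, s1).delta_g)

    def test_appending_wc_pair_never_raises_energy(self, rng):
        # extend a terminal stack by one Watson-Crick pair
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(30):
            core = "".join(rng.choice(list("ACGU"), size=8))
            rc = "".join(comp[c] for c in reversed(core))
            base = duplex_energy(core, rc).delta_g
            extra = str(rng.choice(list("ACGU")))
            extended = duplex_energy(core + extra, comp[extra] + rc).delta_g
            assert extended <= base + 1e-9

    def test_gu_flag_excludes_wobble_pairs(self):
        with_gu = duplex_energy("GGGGG", "UUUUU", allow_gu=True)
        without = duplex_energy("GGGGG", "UUUUU", allow_gu=False)
        assert with_gu.delta_g < 0.0 or with_gu.n_pairs == 0
        assert without.delta_g == 0.0 and not without.is_duplex

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            duplex_energy("ACGX", "ACGU")

    def test_dp_matches_brute_force_on_short_arms(self, rng):
        for _ in range(250):
            n1 = int(rng.integers(2, 11))
            n2 = int(rng.integers(2, 11))
            s1 = "".join(rng.choice(list("ACGU"), size=n1))
            s2 = "".join(rng.choice(list("ACGU"), size=n2))
            dp = duplex_energy(s1, s2).delta_g
            bf = brute_force_duplex(s1, s2)
            assert dp == pytest.approx(min(bf, 0.0), abs=1e-9), (s1, s2)


class TestEnergyModelFile:
    def test_table_is_mirror_symmetric(self):
        em = default_model()
        for key, value in em.stacks.items():
            ab, cd = key.split("/")
            mirror = f"{cd[1]}{cd[0]}/{ab[1]}{ab[0]}"
            assert em.stacks[mirror] == pytest.approx(value)

    def test_swappable_table_changes_energies(self, tmp_path):
        path = tmp_path / "alt.tsv"
        lines = ["stack\tGG/CC\t-1.00\n", "scalar\tduplex_init\t0.0\n",
                 "scalar\tterminal_au_gu\t0.0\n", "scalar\tloop_init\t3.0\n",
                 "scalar\tloop_per_nt\t0.5\n", "scalar\tmax_loop\t15\n"]
        path.write_text("".join(lines))
        em = EnergyModel.from_file(path)
        r = duplex_energy("GGG", "CCC", model=em)
        assert r.delta_g == pytest.approx(-2.0)


def ranksum_enumeration_oracle(x, y):
    """Two-sided p by full enumeration of all C(n, n1) rank assignments."""
    n1, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2
    dev = abs(w - mu)
    hits = total = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_textbook_separation_case(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.10)

    def test_identical_samples_give_p_one(self):
        r = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (8, 7)])
    def test_exact_matches_full_enumeration(self, n1, n2, rng):
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            r = wilcoxon_rank_sum(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(ranksum_enumeration_oracle(x, y))

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=8)
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_used_for_large_or_tied(self):
        x = list(range(20))
        y = list(range(5, 25))
        assert wilcoxon_rank_sum(x, y).method == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestEnergyMap:
    def test_single_value(self):
        df = energy_map([-15.1]).set_index("category")
        assert df.loc["all", "mean"] == pytest.approx(-15.1)

    def test_two_group_means_and_sentinel_exclusion(self):
        dg = [-15.1] * 10 + [-7.3] * 10 + [0.0]
        cats = ["flash"] * 10 + ["control"] * 10 + ["flash"]
        df = energy_map(dg, cats).set_index("category")
        assert df.loc["flash", "mean"] == pytest.approx(-15.1)
        assert df.loc["control", "mean"] == pytest.approx(-7.3)
        assert df.loc["flash", "n_no_duplex"] == 1

    def test_deciles_of_uniform_grid(self):
        vals = list(np.linspace(-10.0, -1.0, 101))
        df = energy_map(vals).set_index("category")
        for d in range(1, 10):
            assert df.loc["all", f"decile_{d}"] == pytest.approx(
                np.quantile(vals, d / 10))
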