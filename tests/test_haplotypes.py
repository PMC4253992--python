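import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halfsib import (
    UndefinedStatisticError,
    build_block,
    d_prime,
    em_haplotype_frequencies,
    find_blocks,
    haplotype_dosage_design,
    pool_rare_haplotypes,
)
from halfsib.haplotypes import _interval_ok
from halfsib.validation import enumeration_haplotype_frequencies

from conftest import genotypes_from_haplotypes, make_genotypes


class TestEm:
    def test_unambiguous_data_equals_gamete_counting(self):
        # every individual homozygous at >= 1 of the 2 loci: phase known
        calls = [[0, 0], [0, 2], [2, 2], [1, 0], [0, 1], [2, 1]]
        res = em_haplotype_frequencies(make_genotypes(calls), ["snp0", "snp1"])
        # direct gamete count over 12 chromosomes
        # gametes: AA,AA | AB,AB | BB,BB | BA,AA | AA,AB | BB,BA
        expected = {"AA": 4 / 12, "AB": 3 / 12, "BA": 2 / 12, "BB": 3 / 12}
        got = dict(zip(res.haplotype_strings, res.frequencies))
        for h, f in expected.items():
            assert got.get(h, 0.0) == pytest.approx(f, abs=1e-9)

    def test_double_heterozygote_matches_grid_search_oracle(self):
        # background of known haplotypes plus one ambiguous individual
        calls = [[0, 0]] * 4 + [[2, 2]] * 3 + [[1, 0]] * 2 + [[1, 1]]
        calls = np.array(calls)
        res = em_haplotype_frequencies(make_genotypes(calls), ["snp0", "snp1"])
        oracle = enumeration_haplotype_frequencies(calls)
        got = np.zeros(4)
        for h, f in zip(res.haplotypes, res.frequencies):
            got[((h & 1) << 1) | ((h >> 1) & 1)] = f
        assert np.abs(got - oracle).max() < 1e-3

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        g, _ = genotypes_from_haplotypes(
            ["000", "011", "110", "101"], [0.4, 0.3, 0.2, 0.1], 120, rng
        )
        res = em_haplotype_frequencies(g, g.snp_ids)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_missing_calls_exclude_individual_from_window(self):
        calls = [[0, 0], [1, -1], [2, 2]]
        res = em_haplotype_frequencies(make_genotypes(calls), ["snp0", "snp1"])
        assert res.kept_ids == ["I0", "I2"]

    def test_recovers_simulated_frequencies_within_binomial_error(self):
        """EM frequency error vs truth stays within 3 binomial s.e. for
        >= 95% of seeds on iid-gamete data at the study sample size."""
        haps = ["111100", "000010", "011101", "011100", "011110"]
        freqs = np.array([0.342, 0.250, 0.167, 0.095, 0.092])
        freqs = freqs / freqs.sum()
        n = 638
        se = np.sqrt(freqs * (1 - freqs) / (2 * n))
        ok = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            g, _ = genotypes_from_haplotypes(haps, freqs, n, rng)
            res = em_haplotype_frequencies(g, g.snp_ids)
            got = dict(zip(res.haplotype_strings, res.frequencies))
            bin_strings = ["".join("B" if c == "1" else "A" for c in h) for h in haps]
            errs = np.array([abs(got.get(h, 0.0) - f) for h, f in zip(bin_strings, freqs)])
            ok += bool((errs <= 3 * se).all())
        assert ok / n_seeds >= 0.95


class TestDprime:
    def test_complete_ld_gives_one(self):
        pair = d_prime([0.7, 0.0, 0.0, 0.3])
        assert pair.Dprime == pytest.approx(1.0)

    def test_equilibrium_gives_zero(self):
        # pAB = pA * pB exactly
        pair = d_prime([0.35, 0.35, 0.15, 0.15])
        assert pair.Dprime == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # D = 0.5 - 0.6*0.6 = 0.14; Dmax = min(0.6*0.4, 0.4*0.6) = 0.24
        pair = d_prime([0.5, 0.1, 0.1, 0.3])
        assert pair.D == pytest.approx(0.14)
        assert pair.Dprime == pytest.approx(0.14 / 0.24)

    def test_monomorphic_locus_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            d_prime([0.6, 0.4, 0.0, 0.0])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4).map(
            lambda v: [x / sum(v) for x in v]
        )
    )
    @settings(max_examples=100)
    def test_symmetry_and_relabel_invariance(self, f):
        pAB, pAb, paB, pab = f
        base = d_prime(f).Dprime
        swapped_loci = d_prime([pAB, paB, pAb, pab]).Dprime
        relabeled_a = d_prime([paB, pab, pAB, pAb]).Dprime
        assert swapped_loci == pytest.approx(base, abs=1e-12)
        assert relabeled_a == pytest.approx(base, abs=1e-12)


def _brute_force_blocks(dp, informative, thr, frac):
    """Exhaustive longest-first greedy over all contiguous intervals."""
    m = dp.shape[0]
    ok = {}
    for i in range(m):
        for j in range(i + 1, m):
            pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            inf = [(a, b) for a, b in pairs if informative[a, b]]
            if inf:
                strong = sum(dp[a, b] > thr for a, b in inf)
                ok[(i, j)] = strong / len(inf) >= frac
    taken = [False] * m
    blocks = []
    for length in range(m, 1, -1):
        for i in range(0, m - length + 1):
            j = i + length - 1
            if ok.get((i, j)) and not any(taken[i : j + 1]):
                for t in range(i, j + 1):
                    taken[t] = True
                blocks.append((i, j))
    return sorted(blocks)


class TestBlocks:
    def test_perfect_ld_run_is_one_block(self):
        rng = np.random.default_rng(1)
        g, _ = genotypes_from_haplotypes(["00000", "11111"], [0.6, 0.4], 200, rng)
        assert find_blocks(g) == [g.snp_ids]

    def test_two_independent_clusters_give_two_blocks(self):
        rng = np.random.default_rng(2)
        left, _ = genotypes_from_haplotypes(["000", "111"], [0.5, 0.5], 300, rng)
        right, _ = genotypes_from_haplotypes(["000", "111"], [0.5, 0.5], 300, rng)
        calls = np.hstack([left.calls, right.calls])
        g = make_genotypes(calls)
        assert find_blocks(g) == [["snp0", "snp1", "snp2"], ["snp3", "snp4", "snp5"]]

    def test_boundary_fraction_accepted_by_ge_rule(self):
        """An interval with exactly 9/10 strong informative pairs meets
        the 0.9 fraction threshold (>= rule), per enumeration oracle."""
        m = 5
        dp = np.ones((m, m))
        informative = ~np.eye(m, dtype=bool)
        dp[1, 3] = dp[3, 1] = 0.2  # 1 weak pair of the 10
        assert _interval_ok(dp, informative, 0, 4, 0.75, 0.9)
        assert _brute_force_blocks(dp, informative, 0.75, 0.9) == [(0, 4)]
        dp[0, 2] = dp[2, 0] = 0.2  # 8/10 fails the fraction
        assert not _interval_ok(dp, informative, 0, 4, 0.75, 0.9)

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_enumeration_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = 8
        dp = np.zeros((m, m))
        informative = np.zeros((m, m), dtype=bool)
        for i in range(m):
            for j in range(i + 1, m):
                informative[i, j] = informative[j, i] = rng.random() > 0.1
                dp[i, j] = dp[j, i] = rng.random()
        expected = _brute_force_blocks(dp, informative, 0.75, 0.9)

        got = []
        candidates = [
            (i, j)
            for length in range(m, 1, -1)
            for i in range(0, m - length + 1)
            for j in [i + length - 1]
            if _interval_ok(dp, informative, i, j, 0.75, 0.9)
        ]
        taken = np.zeros(m, dtype=bool)
        for i, j in candidates:
            if not taken[i : j + 1].any():
                taken[i : j + 1] = True
                got.append((i, j))
        assert sorted(got) == expected

    def test_single_snp_panel_has_no_blocks(self):
        g = make_genotypes([[0], [1], [2]])
        assert find_blocks(g) == []


class TestPooling:
    def test_nine_frequencies_pool_to_five_plus_one(self):
        """The published block-1 spectrum: 5 distinguishable haplotypes,
        rare ones pooled into a class of frequency 0.0548."""
        freqs = [0.339, 0.248, 0.166, 0.094, 0.091, 0.030, 0.024, 0.0007, 0.0001]
        freqs = list(np.array(freqs) / sum(freqs))
        haps = [f"h{i}" for i in range(9)]
        block = pool_rare_haplotypes(haps, freqs)
        assert block.k == 6  # 5 kept + pooled
        assert int(block.pooled_mask.sum()) == 4
        assert block.class_labels[-1] == "POOLED"

    def test_three_common_haplotypes_no_pooled_class(self):
        block = pool_rare_haplotypes(["a", "b", "c"], [0.388, 0.308, 0.304])
        assert block.k == 3
        assert not block.pooled_mask.any()

    def test_all_rare_is_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            pool_rare_haplotypes([f"h{i}" for i in range(30)], [1 / 30] * 30)

    def test_threshold_is_strict_greater_than(self):
        block = pool_rare_haplotypes(["a", "b", "c"], [0.90, 0.05, 0.05])
        assert block.class_labels == ["a", "POOLED"]
        assert block.class_frequencies[-1] == pytest.approx(0.10)


class TestDosage:
    def test_homozygote_and_unambiguous_heterozygote(self):
        rng = np.random.default_rng(0)
        g, picks = genotypes_from_haplotypes(["00", "11"], [0.5, 0.5], 100, rng)
        block = build_block(g, g.snp_ids, pool_threshold=0.05)
        hom = np.flatnonzero((picks[:, 0] == 0) & (picks[:, 1] == 0))[0]
        het = np.flatnonzero(picks[:, 0] != picks[:, 1])[0]
        col_aa = block.class_labels.index("AA")
        col_bb = block.class_labels.index("BB")
        assert block.dosage[hom, col_aa] == pytest.approx(2.0)
        assert block.dosage[hom, col_bb] == pytest.approx(0.0)
        assert block.dosage[het, col_aa] == pytest.approx(1.0)
        assert block.dosage[het, col_bb] == pytest.approx(1.0)

    def test_rows_sum_to_two(self):
        rng = np.random.default_rng(5)
        g, _ = genotypes_from_haplotypes(
            ["0000", "1100", "0011", "1111", "1010"], [0.3, 0.25, 0.2, 0.15, 0.1], 300, rng
        )
        block = build_block(g, g.snp_ids)
        assert np.abs(block.dosage.sum(axis=1) - 2.0).max() < 1e-9

    def test_ambiguous_individual_gets_posterior_fractions(self):
        """A double heterozygote's dosage equals the brute-force posterior
        over its two consistent phase pairs."""
        calls = np.array([[0, 0]] * 6 + [[2, 2]] * 2 + [[1, 1]])
        g = make_genotypes(calls)
        em = em_haplotype_frequencies(g, g.snp_ids)
        block = pool_rare_haplotypes(em.haplotype_strings, em.frequencies, 0.01, g.snp_ids)
        block = haplotype_dosage_design(block, em)
        f = dict(zip(em.haplotype_strings, em.frequencies))
        # posterior of AA/BB vs AB/BA resolution for the last individual
        w_cis = 2 * f["AA"] * f["BB"]
        w_trans = 2 * f.get("AB", 0.0) * f.get("BA", 0.0)
        post = w_cis / (w_cis + w_trans)
        got = block.dosage[-1, block.class_labels.index("AA")]
        assert got == pytest.approx(post, abs=1e-9)
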