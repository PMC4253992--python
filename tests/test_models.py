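import numpy as np
import pytest

from halfsib import (
    MixedModelContext,
    MonomorphicSnpError,
    Pedigree,
    PhenotypeTable,
    VarianceComponents,
    build_A,
    build_A_inverse,
    build_block,
    fdr_adjust,
    fit_weighted_animal_model,
    relative_expression_ddct,
    reml_variance_components,
)
from halfsib import test_haplotype_block as block_test
from halfsib import test_snp as snp_test
import pandas as pd

from conftest import genotypes_from_haplotypes, make_genotypes, random_pedigree_triples
from halfsib.validation import StudyDesign, gls_fit


def _random_instance(seed, n=80):
    rng = np.random.default_rng(seed)
    ped = Pedigree.from_tuples(random_pedigree_triples(n, rng))
    A = build_A(ped)
    Ainv = build_A_inverse(ped, A)
    ids = list(rng.choice(ped.ids, size=n // 2, replace=False))
    rel = rng.uniform(0.2, 1.0, len(ids))
    y = rng.normal(size=len(ids))
    x = rng.integers(0, 3, len(ids)).astype(float)
    return ped, A, Ainv, ids, rel, y, x


class TestMixedModel:
    def test_degenerates_to_ols_without_polygenic_term(self):
        """Reliabilities of 1 and sigma2_a -> 0 reduce to ordinary least
        squares."""
        rng = np.random.default_rng(0)
        ped = Pedigree.from_tuples([(f"I{i}", None, None) for i in range(50)])
        Ainv = build_A_inverse(ped)
        y = rng.normal(size=50)
        x = rng.integers(0, 3, 50).astype(float)
        vc = VarianceComponents(0.0, 1.0)
        ctx = MixedModelContext(ped.ids, y, np.ones(50), Ainv, vc)
        fit = ctx.fit(x[:, None])
        slope = np.polyfit(x, y, 1)[0]
        assert fit.beta_hat[0] == pytest.approx(slope, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_mme_equals_direct_gls(self, seed):
        """Henderson-equation solution and direct GLS agree to 1e-8 in
        both estimates and sampling covariance."""
        ped, A, Ainv, ids, rel, y, x = _random_instance(seed)
        vc = VarianceComponents(0.7, 1.1)
        ctx = MixedModelContext(ids, y, rel, Ainv, vc)
        fit = ctx.fit(x[:, None])
        X = np.column_stack([np.ones(len(ids)), x])
        beta_o, cov_o = gls_fit(y, X, A.submatrix(ids), rel, vc)
        assert np.abs(np.r_[fit.mu_hat, fit.beta_hat] - beta_o).max() < 1e-8
        assert np.abs(fit.cov_fixed - cov_o).max() < 1e-8

    def test_scale_invariance_of_variance_ratio(self):
        """Doubling both variance components leaves estimates and Wald
        statistics unchanged (only the ratio enters the fit)."""
        ped, A, Ainv, ids, rel, y, x = _random_instance(11)
        g = make_genotypes(x.reshape(-1, 1).astype(int), ids=ids)
        r1 = snp_test(MixedModelContext(ids, y, rel, Ainv, VarianceComponents(0.5, 1.0)), g, "snp0")
        r2 = snp_test(MixedModelContext(ids, y, rel, Ainv, VarianceComponents(1.0, 2.0)), g, "snp0")
        assert r1.estimate[0] == pytest.approx(r2.estimate[0], rel=1e-10)
        assert r1.wald_chi2 == pytest.approx(r2.wald_chi2, rel=1e-10)

    def test_constant_reliabilities_match_unweighted_model(self):
        """Any constant reliability gives the same p-value as W = I."""
        ped, A, Ainv, ids, rel, y, x = _random_instance(12)
        g = make_genotypes(x.reshape(-1, 1).astype(int), ids=ids)
        vc = VarianceComponents(0.8, 1.0)
        r_w = snp_test(
            MixedModelContext(ids, y, np.full(len(ids), 0.25), Ainv, vc), g, "snp0"
        )
        # W = (1/0.25) I is absorbed by rescaling sigma2_e: lambda' = 4*lambda
        vc_eq = VarianceComponents(0.8, 4.0)
        r_i = snp_test(MixedModelContext(ids, y, np.ones(len(ids)), Ainv, vc_eq), g, "snp0")
        assert r_w.p_raw == pytest.approx(r_i.p_raw, rel=1e-10)

    def test_rank_deficient_design_names_aliased_column(self):
        ped, A, Ainv, ids, rel, y, x = _random_instance(13)
        F = np.column_stack([x, x])
        ctx = MixedModelContext(ids, y, rel, Ainv, VarianceComponents(1.0, 1.0))
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            ctx.fit(F, fixed_names=["x1", "x2"])


class TestReml:
    def test_recovers_components_on_large_balanced_design(self):
        """REML on data simulated from the analysis model recovers the
        generating variance components."""
        design = StudyDesign(21, sigma2_a=1.0, sigma2_e=0.5)
        rng = np.random.default_rng(0)
        ests = np.array([
            [design.reml(design.draw_null_y(rng)).sigma2_a,
             design.reml(design.draw_null_y(rng)).sigma2_e]
            for _ in range(10)
        ])
        assert ests[:, 0].mean() == pytest.approx(1.0, abs=0.35)
        assert ests[:, 1].mean() == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_hits_zero_boundary(self):
        rng = np.random.default_rng(4)
        ped = Pedigree.from_tuples(random_pedigree_triples(200, rng, n_founders=20))
        A = build_A(ped)
        ids = ped.ids
        y = rng.normal(size=len(ids))  # no genetic signal
        vc = reml_variance_components(y, np.ones(len(ids)), A.submatrix(ids))
        assert vc.sigma2_a < 0.2


class TestSnpTest:
    def test_orthogonal_effect_gives_wald_zero(self):
        ids = [f"I{i}" for i in range(4)]
        ped = Pedigree.from_tuples([(i, None, None) for i in ids])
        Ainv = build_A_inverse(ped)
        # symmetric y around x: OLS slope exactly 0
        y = np.array([1.0, -1.0, 1.0, -1.0])
        g = make_genotypes([[0], [0], [2], [2]], ids=ids)
        ctx = MixedModelContext(ids, y, np.ones(4), Ainv, VarianceComponents(0.0, 1.0))
        r = snp_test(ctx, g, "snp0")
        assert r.wald_chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0)

    def test_allele_swap_negates_estimate_same_p(self):
        ped, A, Ainv, ids, rel, y, x = _random_instance(30)
        g1 = make_genotypes(x.reshape(-1, 1).astype(int), ids=ids)
        g2 = make_genotypes((2 - x).reshape(-1, 1).astype(int), ids=ids)
        vc = VarianceComponents(0.6, 1.0)
        r1 = snp_test(MixedModelContext(ids, y, rel, Ainv, vc), g1, "snp0")
        r2 = snp_test(MixedModelContext(ids, y, rel, Ainv, vc), g2, "snp0")
        assert r1.estimate[0] == pytest.approx(-r2.estimate[0], rel=1e-10)
        assert r1.p_raw == pytest.approx(r2.p_raw, rel=1e-10)

    def test_monomorphic_snp_raises(self):
        ped, A, Ainv, ids, rel, y, x = _random_instance(31)
        g = make_genotypes(np.zeros((len(ids), 1), dtype=int), ids=ids)
        ctx = MixedModelContext(ids, y, rel, Ainv, VarianceComponents(1.0, 1.0))
        with pytest.raises(MonomorphicSnpError):
            snp_test(ctx, g, "snp0")

    def test_missing_calls_reduce_n_used(self):
        ped, A, Ainv, ids, rel, y, x = _random_instance(32)
        calls = x.reshape(-1, 1).astype(int)
        calls[:5] = -1
        g = make_genotypes(calls, ids=ids)
        ctx = MixedModelContext(ids, y, rel, Ainv, VarianceComponents(1.0, 1.0))
        r = snp_test(ctx, g, "snp0")
        assert r.n_used == len(ids) - 5

    def test_power_against_injected_effect(self):
        """An effect of 0.4 trait s.d. at the study size is detected with
        very small p in the typical replicate."""
        design = StudyDesign(40)
        rng_y = np.random.default_rng(1)
        rng_g = np.random.default_rng(2)
        snp = design.cfg.block_spec.snp_ids[0]
        ps = []
        for _ in range(100):
            g = design.draw_genotypes(rng_g)
            y = design.draw_null_y(rng_y) + 0.5 * g.column(snp)
            ctx = design.context(y, design.reml(y))
            ps.append(snp_test(ctx, g, snp).p_raw)
        assert np.median(ps) < 1e-3


class TestHaplotypeTest:
    def test_two_haplotype_block_equals_snp_test(self):
        """With k = 2 the haplotype design is collinear with the SNP
        dosage, so the joint test reduces to the df = 1 SNP test."""
        rng = np.random.default_rng(7)
        g, _ = genotypes_from_haplotypes(["00", "11"], [0.6, 0.4], 150, rng)
        ids = g.ids
        ped = Pedigree.from_tuples([(i, None, None) for i in ids])
        Ainv = build_A_inverse(ped)
        y = rng.normal(size=len(ids)) + 0.3 * g.column("snp0")
        ctx = MixedModelContext(ids, y, np.ones(len(ids)), Ainv, VarianceComponents(0.3, 1.0))
        block = build_block(g, g.snp_ids)
        r_block = block_test(ctx, block)
        r_snp = snp_test(ctx, g, "snp0")
        assert r_block.df == 1
        assert r_block.p_raw == pytest.approx(r_snp.p_raw, rel=1e-8)

    def test_wald_invariant_to_reference_class(self):
        rng = np.random.default_rng(9)
        g, _ = genotypes_from_haplotypes(
            ["000", "110", "011"], [0.5, 0.3, 0.2], 200, rng
        )
        ids = g.ids
        ped = Pedigree.from_tuples([(i, None, None) for i in ids])
        Ainv = build_A_inverse(ped)
        y = rng.normal(size=len(ids))
        ctx = MixedModelContext(ids, y, np.ones(len(ids)), Ainv, VarianceComponents(0.3, 1.0))
        block = build_block(g, g.snp_ids)
        r1 = block_test(ctx, block)
        # rotate class order so a different class is dropped
        rotated = build_block(g, g.snp_ids)
        order = [1, 2, 0]
        rotated.class_labels = [block.class_labels[j] for j in order]
        rotated.class_frequencies = block.class_frequencies[order]
        rotated.dosage = block.dosage[:, order]
        r2 = block_test(ctx, rotated)
        assert r1.wald_chi2 == pytest.approx(r2.wald_chi2, rel=1e-8)

    def test_haplotype_power_when_untagged_by_single_snps(self):
        """A causal haplotype that no single SNP tags well: the joint
        block test rejects more often than any individual SNP test."""
        haps = ["110", "101", "011", "000"]
        freqs = [0.3, 0.25, 0.25, 0.2]
        rng = np.random.default_rng(77)
        hit_block = 0
        hit_snp = np.zeros(3)
        n_rep = 60
        for _ in range(n_rep):
            g, picks = genotypes_from_haplotypes(haps, freqs, 400, rng)
            ids = g.ids
            ped = Pedigree.from_tuples([(i, None, None) for i in ids])
            Ainv = build_A_inverse(ped)
            dose = (picks == 0).sum(axis=1).astype(float)  # copies of "110"
            y = rng.normal(size=len(ids)) + 0.18 * dose
            ctx = MixedModelContext(ids, y, np.ones(len(ids)), Ainv, VarianceComponents(0.0, 1.0))
            block = build_block(g, g.snp_ids, pool_threshold=0.05)
            hit_block += block_test(ctx, block).p_raw < 0.05
            for j, s in enumerate(g.snp_ids):
                hit_snp[j] += snp_test(ctx, g, s).p_raw < 0.05
        assert hit_block > hit_snp.max()


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.032]) == [pytest.approx(0.032)]

    def test_hand_computed_uniform_ladder(self):
        # p_(i) * m / i = 0.05 for every i -> all adjusted to 0.05
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05]) == pytest.approx([0.05] * 5)

    def test_hand_computed_two_values(self):
        assert fdr_adjust([0.001, 0.5]) == pytest.approx([0.002, 0.5])

    def test_empty_list(self):
        assert fdr_adjust([]) == []

    def test_matches_manual_step_up_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            m = len(p)
            order = np.argsort(p)
            manual = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                manual[i] = running
            assert np.allclose(fdr_adjust(list(p)), manual)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        adj = np.array(fdr_adjust(list(p)))
        assert (adj >= p - 1e-15).all()
        assert (np.argsort(np.argsort(p)) == np.argsort(np.argsort(adj, kind="stable"))).all() or (
            np.diff(adj[np.argsort(p)]) >= -1e-15
        ).all()


class TestDdct:
    @pytest.mark.parametrize(
        "target,ref,cal,expected",
        [
            (20.0, 20.0, 0.0, 1.0),
            (19.0, 20.0, 0.0, 2.0),
            (23.32, 20.0, 0.0, 2.0 ** -3.32),
        ],
    )
    def test_fold_change_arithmetic(self, target, ref, cal, expected):
        assert relative_expression_ddct(target, ref, cal) == pytest.approx(expected)

    def test_calibrator_shifts_delta(self):
        assert relative_expression_ddct(25.0, 20.0, 5.0) == pytest.approx(1.0)


class TestPhenotypeTable:
    def test_rejects_invalid_reliability(self):
        df = pd.DataFrame({"id": ["a"], "trait": ["MY"], "ebv": [1.0], "reliability": [0.0]})
        with pytest.raises(ValueError, match="reliabilities"):
            PhenotypeTable(df)

    def test_rejects_duplicate_record(self):
        df = pd.DataFrame(
            {"id": ["a", "a"], "trait": ["MY", "MY"], "ebv": [1.0, 2.0], "reliability": [0.5, 0.5]}
        )
        with pytest.raises(ValueError, match="one record"):
            PhenotypeTable(df)
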