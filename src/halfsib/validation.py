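"""Simulation-based validation studies of the association machinery.

These routines measure the statistical operating characteristics that a
candidate-gene analysis of this design should have — Wald type-I error,
effect recovery, agreement between the mixed-model-equation solver and
a direct GLS computation, and EM-vs-enumeration haplotype frequencies.
They are shared between the test suite and the reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix, SnpInfo
from .haplotypes import build_block, em_haplotype_frequencies
from .models import (
    MixedModelContext,
    MonomorphicSnpError,
    VarianceComponents,
    reml_variance_components,
    test_haplotype_block,
    test_snp,
    weighted_kinship_eig,
)
from .pedigree import Pedigree, build_A, build_A_inverse
from .refpanel import block1_spec, default_sim_config
from .simulate import simulate_population


# ---------------------------------------------------------------------------
# Direct GLS oracle (kept deliberately independent of the MME path)
# ---------------------------------------------------------------------------

def gls_fit(y, X, A_pheno, rel, vc: VarianceComponents):
    """Direct GLS on V = A*sigma2_a + W*sigma2_e with W = diag(1/rel).

    Returns (beta_hat, cov_beta) with the residual variance profiled at
    the variance ratio, matching the mixed-model parameterisation.
    """
    n = len(y)
    lam = vc.lambda_
    V0 = (A_pheno / lam if np.isfinite(lam) else 0.0) + np.diag(1.0 / np.asarray(rel))
    Vinv = np.linalg.inv(V0)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    s2e = float(r @ Vinv @ r) / (n - X.shape[1])
    return beta, s2e * np.linalg.inv(XtVX)


def random_pedigree(n: int, rng: np.random.Generator) -> Pedigree:
    """Random valid pedigree: founders first, then offspring of earlier ids."""
    n_founders = max(2, n // 3)
    triples = [(f"I{i}", None, None) for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        triples.append((f"I{i}", f"I{s}", f"I{d}"))
    return Pedigree.from_tuples(triples)


def mme_gls_max_deviation(seed: int, n_instances: int = 20, n_max: int = 200) -> float:
    """Max |MME - GLS| over random weighted-animal-model instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(20, n_max + 1))
        ped = random_pedigree(n, rng)
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A)
        ids = list(rng.choice(ped.ids, size=max(10, n // 2), replace=False))
        A_pheno = A.submatrix(ids)
        rel = rng.uniform(0.2, 1.0, len(ids))
        y = rng.normal(size=len(ids))
        x = rng.integers(0, 3, len(ids)).astype(float)
        vc = VarianceComponents(float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.2, 2.0)))
        ctx = MixedModelContext(ids, y, rel, Ainv, vc)
        fit = ctx.fit(x[:, None])
        X = np.column_stack([np.ones(len(ids)), x])
        beta_o, cov_o = gls_fit(y, X, A_pheno, rel, vc)
        dev = max(
            float(np.max(np.abs(np.r_[fit.mu_hat, fit.beta_hat] - beta_o))),
            float(np.max(np.abs(fit.cov_fixed - cov_o))),
        )
        worst = max(worst, dev)
    return worst


# ---------------------------------------------------------------------------
# Null calibration and power of the Wald tests (study design)
# ---------------------------------------------------------------------------

class StudyDesign:
    """One fixed realisation of the half-sib design for repeated draws.

    Pedigree, reliabilities and kinship stay fixed; phenotypes (and
    optionally genotypes) are redrawn per replicate under the analysis
    model: a ~ N(0, A*sigma2_a), e_i ~ N(0, sigma2_e / r_i).
    """

    def __init__(self, seed: int, sigma2_a: float = 1.0, sigma2_e: float = 1.0):
        cfg = default_sim_config(seed, sigma2_e=sigma2_e, sigma2_a=sigma2_a)
        self.cfg = cfg
        self.sim = simulate_population(cfg)
        self.ped = self.sim.pedigree
        self.A = build_A(self.ped)
        self.Ainv = build_A_inverse(self.ped, self.A)
        ids, y, rel = self.sim.phenotypes.for_trait("MY")
        self.ids, self.rel = ids, rel
        self.A_pheno = self.A.submatrix(ids)
        self.L = np.linalg.cholesky(self.A_pheno + 1e-10 * np.eye(len(ids)))
        self.sigma2_a, self.sigma2_e = sigma2_a, sigma2_e
        # lambda-independent precomputations shared across replicates
        self.eig = weighted_kinship_eig(rel, self.A_pheno)
        self.solver = MixedModelContext(
            ids, np.zeros(len(ids)), rel, self.Ainv, VarianceComponents(1.0, 1.0)
        ).make_solver()

    def reml(self, y: np.ndarray) -> VarianceComponents:
        return reml_variance_components(y, self.rel, eig=self.eig)

    def context(self, y: np.ndarray, vc: VarianceComponents) -> MixedModelContext:
        return MixedModelContext(self.ids, y, self.rel, self.Ainv, vc, solver=self.solver)

    def draw_null_y(self, rng: np.random.Generator) -> np.ndarray:
        a = self.L @ rng.normal(size=len(self.ids)) * np.sqrt(self.sigma2_a)
        e = rng.normal(size=len(self.ids)) * np.sqrt(self.sigma2_e / self.rel)
        return a + e

    def draw_genotypes(self, rng: np.random.Generator) -> GenotypeMatrix:
        from dataclasses import replace

        sub = simulate_population(
            replace(
                self.cfg,
                seed=int(rng.integers(2**31 - 1)),
                family_sizes=list(self.sim.truth["family_sizes"]),
            )
        )
        return GenotypeMatrix(self.ids, sub.genotypes.snps, sub.genotypes.calls)


def wald_type1_rates(
    seed: int, n_reps: int = 2000, alpha: float = 0.05
) -> tuple[float, float]:
    """Empirical type-I error of the SNP and haplotype-block Wald tests.

    Null phenotypes are drawn from the analysis model on the fixed
    13-sire design; each replicate gets its own REML variance-component
    estimate (as the pipeline estimates them per trait on the data it
    analyses) which is then held fixed for that replicate's tests.
    Returns (snp rejection rate, block rejection rate) at ``alpha``.
    """
    design = StudyDesign(seed)
    root = np.random.SeedSequence(seed)
    rng_y, rng_g = (np.random.default_rng(s) for s in root.spawn(2))

    snp_id = design.cfg.block_spec.snp_ids[0]
    block_snps = design.cfg.block_spec.snp_ids

    rej_snp = rej_blk = n_snp = n_blk = 0
    for _ in range(n_reps):
        y = design.draw_null_y(rng_y)
        g = design.draw_genotypes(rng_g)
        ctx = design.context(y, design.reml(y))
        try:
            r = test_snp(ctx, g, snp_id)
            n_snp += 1
            rej_snp += r.p_raw < alpha
        except MonomorphicSnpError:
            pass
        block = build_block(g, block_snps)
        r = test_haplotype_block(ctx, block)
        n_blk += 1
        rej_blk += r.p_raw < alpha
    return rej_snp / n_snp, rej_blk / n_blk


def slope_recovery(
    seed: int, b: float = 0.4, n_reps: int = 500
) -> tuple[float, float, float]:
    """Recovery of an injected per-allele SNP effect.

    Returns (mean b-hat, Monte-Carlo s.e. of the mean, coverage of the
    nominal 95% Wald interval) over ``n_reps`` replicates of the default
    design with effect ``b`` on the first block SNP.
    """
    design = StudyDesign(seed)
    root = np.random.SeedSequence(seed + 1)
    rng_y, rng_g = (np.random.default_rng(s) for s in root.spawn(2))
    snp_id = design.cfg.block_spec.snp_ids[0]

    est, cover = [], 0
    n_ok = 0
    for _ in range(n_reps):
        g = design.draw_genotypes(rng_g)
        x = g.column(snp_id).astype(float)
        y = design.draw_null_y(rng_y) + b * x
        ctx = design.context(y, design.reml(y))
        try:
            fit = ctx.fit(x[:, None])
        except np.linalg.LinAlgError:
            continue
        n_ok += 1
        bh = float(fit.beta_hat[0])
        se = float(np.sqrt(fit.cov_fixed[1, 1]))
        est.append(bh)
        cover += abs(bh - b) <= 1.959963984540054 * se
    est = np.array(est)
    return float(est.mean()), float(est.std(ddof=1) / np.sqrt(n_ok)), cover / n_ok


# ---------------------------------------------------------------------------
# EM vs exhaustive phase enumeration
# ---------------------------------------------------------------------------

def enumeration_haplotype_frequencies(calls: np.ndarray, grid: int = 2001) -> np.ndarray:
    """Brute-force ML haplotype frequencies for a two-SNP window.

    Maximises the multinomial phase likelihood over the single free
    parameter (the frequency of one double-heterozygote resolution) on a
    dense grid — an oracle for the EM, feasible because a two-locus
    system has one ambiguous genotype class.
    """
    # gamete counts from unambiguous individuals; double hets counted apart
    counts = np.zeros(4)  # haplotypes 00, 01, 10, 11
    n_dh = 0
    for row in calls:
        a, b = int(row[0]), int(row[1])
        if a == 1 and b == 1:
            n_dh += 1
            continue
        # decompose genotype into its two (known-phase) gametes
        g1 = (1 if a >= 1 else 0, 1 if b >= 1 else 0)
        g2 = (1 if a == 2 else 0, 1 if b == 2 else 0)
        counts[g1[0] * 2 + g1[1]] += 1
        counts[g2[0] * 2 + g2[1]] += 1
    n_chrom = counts.sum() + 2 * n_dh

    def loglik(t: float) -> float:
        c = counts.copy()
        c[0] += n_dh * t       # 00/11 resolution
        c[3] += n_dh * t
        c[1] += n_dh * (1 - t)  # 01/10 resolution
        c[2] += n_dh * (1 - t)
        f = c / n_chrom
        ll = counts @ np.log(np.clip(f, 1e-300, None))
        if n_dh:
            ll += n_dh * np.log(max(2 * f[0] * f[3] + 2 * f[1] * f[2], 1e-300))
        return float(ll)

    ts = np.linspace(0.0, 1.0, grid)
    best = ts[int(np.argmax([loglik(t) for t in ts]))]
    c = counts.copy()
    c[[0, 3]] += n_dh * best
    c[[1, 2]] += n_dh * (1 - best)
    return c / n_chrom
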