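"""Weighted polygenic mixed models for EBV phenotypes.

Two association models on estimated breeding values (EBVs) of half-sib
daughters:

* single-SNP regression  y = 1*mu + b*x + Z a + e
* haplotype trend regression  y = 1*mu + X h + Z a + e

with a ~ N(0, A*sigma2_a) (A the pedigree additive relationship matrix)
and e ~ N(0, W*sigma2_e), W diagonal with entries 1/REL_i (the
reciprocal of each EBV's reliability).  Estimates come from Henderson's
mixed model equations; the fixed-effect sampling covariance is the
inverted-coefficient-matrix block scaled by the residual variance
profiled at the fixed variance ratio, so tests depend on the variance
components only through lambda = sigma2_e / sigma2_a.  Wald chi-square
statistics (df = 1 for a SNP, df = k-1 for a k-class haplotype block)
give the p-values; Benjamini-Hochberg controls the FDR across the
declared test family.

Variance components are estimated by REML on the intercept-only model
(per trait) and then held fixed for every test (P3D-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .genostats import UndefinedStatisticError, genotype_counts
from .genotypes import MISSING, GenotypeMatrix
from .haplotypes import POOLED_LABEL, HaplotypeBlock
from .pedigree import KinshipMatrix

log = logging.getLogger(__name__)


class MonomorphicSnpError(UndefinedStatisticError):
    """SNP is monomorphic in the phenotyped subset; no test possible."""


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Long-format EBV phenotypes: one row per individual per trait."""

    data: pd.DataFrame  # columns: id, trait, ebv, reliability

    def __post_init__(self) -> None:
        required = {"id", "trait", "ebv", "reliability"}
        if not required <= set(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        self.data = self.data.astype({"id": str, "trait": str})
        if (self.data["reliability"] <= 0).any() or (self.data["reliability"] > 1).any():
            raise ValueError("reliabilities must lie in (0, 1]")
        if self.data.duplicated(["id", "trait"]).any():
            raise ValueError("one record per individual per trait required")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait"]))

    def for_trait(self, trait: str) -> tuple[list[str], np.ndarray, np.ndarray]:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no phenotypes for trait {trait!r}")
        return (
            sub["id"].tolist(),
            sub["ebv"].to_numpy(float),
            sub["reliability"].to_numpy(float),
        )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    ph.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    converged: bool = True
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be non-negative (sigma2_e > 0)")

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_a if self.sigma2_a > 0 else np.inf


def weighted_kinship_eig(
    reliabilities: np.ndarray, A_pheno: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral decomposition of K = W^{-1/2} A_pheno W^{-1/2}.

    Reusable across REML calls that share the phenotyped set and
    reliabilities (e.g. simulation replicates).
    """
    w = np.sqrt(np.asarray(reliabilities, float))
    d, U = np.linalg.eigh(w[:, None] * A_pheno * w[None, :])
    return np.clip(d, 0.0, None), U


def reml_variance_components(
    y: np.ndarray,
    reliabilities: np.ndarray,
    A_pheno: np.ndarray | None = None,
    X: np.ndarray | None = None,
    log_gamma_bounds: tuple[float, float] = (-12.0, 12.0),
    tol: float = 1e-10,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML estimates of (sigma2_a, sigma2_e) for the weighted animal model.

    Exact 1-D profiling: with W^{-1/2} = sqrt(REL), the spectral
    decomposition of K = W^{-1/2} A_pheno W^{-1/2} reduces the restricted
    likelihood to a function of the single ratio gamma = sigma2_a /
    sigma2_e, optimised on the log scale; sigma2_e is profiled in closed
    form.  A ratio at the lower search bound is reported as a boundary
    fit (sigma2_a ~ 0) rather than an error.
    """
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.asarray(X, float)
    p = X.shape[1]
    w = np.sqrt(np.asarray(reliabilities, float))
    if eig is None:
        if A_pheno is None:
            raise ValueError("provide A_pheno or a precomputed eig decomposition")
        d, U = weighted_kinship_eig(reliabilities, A_pheno)
    else:
        d, U = eig
    yt = U.T @ (w * y)
    Xt = U.T @ (w[:, None] * X)

    def neg_restricted_ll(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        v = gamma * d + 1.0
        Xv = Xt / v[:, None]
        XtVX = Xt.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / v))
        s2e = rss / (n - p)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * np.log(s2e) + np.sum(np.log(v)) + logdet_xvx)

    lo, hi = log_gamma_bounds
    grid = np.linspace(lo, hi, 41)
    vals = [neg_restricted_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(max(lo, g0 - 1.5), min(hi, g0 + 1.5)),
        method="bounded",
        options={"xatol": tol},
    )
    gamma = float(np.exp(res.x))
    v = gamma * d + 1.0
    Xv = Xt / v[:, None]
    beta = np.linalg.solve(Xt.T @ Xv, Xv.T @ yt)
    r = yt - Xt @ beta
    s2e = float(np.sum(r * r / v) / (n - p))
    boundary = res.x <= lo + 1e-6
    if boundary:
        log.warning("REML additive variance at the zero boundary; polygenic term vanishes")
        return VarianceComponents(0.0, s2e, converged=res.success, boundary=True)
    return VarianceComponents(gamma * s2e, s2e, converged=bool(res.success))


# ---------------------------------------------------------------------------
# Henderson mixed model equations
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    mu_hat: float
    beta_hat: np.ndarray            # fixed effects beyond the intercept
    cov_fixed: np.ndarray           # sampling covariance of [mu, beta]
    a_hat: np.ndarray               # polygenic solutions, pedigree order
    sigma2_e_hat: float             # residual variance profiled at lambda
    vc: VarianceComponents
    n_used: int
    pheno_ids: list[str]
    fixed_names: list[str] = field(default_factory=list)


class PolygenicSolver:
    """Solves (Z'W^{-1}Z + lambda A^{-1}) x = b for any lambda.

    Writing A^{-1} = C C' (Cholesky) and M = C^{-1} D C^{-T} with
    D = Z'W^{-1}Z (diagonal for one record per individual), a single
    eigendecomposition M = Q diag(mu) Q' turns every subsequent solve
    into matrix-vector products: the inverse is
    C^{-T} Q diag(1/(mu + lambda)) Q' C^{-1}.  Useful when the variance
    ratio changes between fits (e.g. per-replicate REML) over a fixed
    design; one-off fits use a plain Cholesky instead.
    """

    def __init__(self, Ainv_values: np.ndarray, diag_weights: np.ndarray) -> None:
        from scipy.linalg import cholesky, solve_triangular

        self._C = cholesky(Ainv_values, lower=True)
        CinvD = solve_triangular(self._C, np.diag(diag_weights), lower=True)
        M = solve_triangular(self._C, CinvD.T, lower=True).T
        mu, Q = np.linalg.eigh(0.5 * (M + M.T))
        self._mu = np.clip(mu, 0.0, None)
        self._Q = Q
        self.diag_weights = diag_weights

    def solve(self, lam: float, B: np.ndarray) -> np.ndarray:
        from scipy.linalg import solve_triangular

        one_d = B.ndim == 1
        B2 = B[:, None] if one_d else B
        Y = self._Q.T @ solve_triangular(self._C, B2, lower=True)
        Y /= (self._mu + lam)[:, None]
        X = solve_triangular(self._C, self._Q @ Y, lower=True, trans="T")
        return X[:, 0] if one_d else X


class MixedModelContext:
    """Reusable pieces of the mixed model equations for one trait.

    Caches the Cholesky factor of the random-effect block
    C_zz = Z'W^{-1}Z + lambda * A^{-1}, which only depends on the
    phenotyped set, the reliabilities and lambda — not on the fixed
    design — so that per-SNP and per-block tests reduce to a handful of
    triangular solves (Schur complement on the fixed block).
    """

    def __init__(
        self,
        pheno_ids: Sequence[str],
        y: np.ndarray,
        reliabilities: np.ndarray,
        kinship_inverse: KinshipMatrix,
        vc: VarianceComponents,
        solver: PolygenicSolver | None = None,
    ) -> None:
        self.pheno_ids = list(pheno_ids)
        self.y = np.asarray(y, float)
        self.rel = np.asarray(reliabilities, float)
        self.Ainv = kinship_inverse
        self.vc = vc
        self.q = len(kinship_inverse.ids)
        self.z_index = kinship_inverse.indices(self.pheno_ids)  # row -> pedigree column
        self._solver = solver
        self._factor_cache: dict[bytes, tuple] = {}
        self._all_rows_key = np.arange(len(self.pheno_ids)).tobytes()

    def make_solver(self) -> PolygenicSolver:
        """Precompute the lambda-independent spectral solver (full rows)."""
        D = np.zeros(self.q)
        np.add.at(D, self.z_index, self.rel)
        return PolygenicSolver(self.Ainv.values, D)

    def _czz_solve(self, rows: np.ndarray):
        """Return a solve(B) callable for C_zz, or None when sigma2_a = 0."""
        lam = self.vc.lambda_
        if not np.isfinite(lam):
            return None
        key = rows.tobytes()
        if self._solver is not None and key == self._all_rows_key:
            return lambda B: self._solver.solve(lam, B)
        if key not in self._factor_cache:
            Czz = lam * self.Ainv.values.copy()
            zi = self.z_index[rows]
            np.add.at(Czz, (zi, zi), self.rel[rows])
            self._factor_cache[key] = cho_factor(Czz, lower=True)
        factor = self._factor_cache[key]
        return lambda B: cho_solve(factor, B)

    def fit(
        self,
        F: np.ndarray | None = None,
        rows: np.ndarray | None = None,
        fixed_names: Sequence[str] | None = None,
        y: np.ndarray | None = None,
    ) -> MixedModelFit:
        """Solve the mixed model equations for y = 1*mu + F*beta + Za + e.

        ``rows`` restricts to a complete-case subset of the phenotype
        records (polygenic structure always spans the full pedigree).
        Raises on a rank-deficient fixed design, naming the aliased
        column.
        """
        rows = np.arange(len(self.pheno_ids)) if rows is None else np.asarray(rows)
        y = self.y if y is None else np.asarray(y, float)
        y = y[rows]
        r = self.rel[rows]
        n = len(rows)
        X = np.ones((n, 1)) if F is None else np.column_stack([np.ones(n), np.asarray(F, float)[rows]])
        p = X.shape[1]
        names = ["mu"] + (list(fixed_names) if fixed_names else [f"b{j}" for j in range(1, p)])

        if np.linalg.matrix_rank(X) < p:
            diag = np.abs(np.diag(np.linalg.qr(X)[1]))
            aliased = names[int(np.argmin(diag))]
            raise np.linalg.LinAlgError(f"fixed design is rank deficient (aliased: {aliased})")

        Rw = r  # W^{-1} diagonal
        XtR = X.T * Rw
        Cxx = XtR @ X
        rx = XtR @ y

        solve_czz = self._czz_solve(rows)
        if solve_czz is None:  # sigma2_a = 0: no polygenic term, weighted LS
            S = Cxx
            sol = np.linalg.solve(S, rx)
            a_hat = np.zeros(self.q)
            resid_q = float(y @ (Rw * y)) - float(sol @ rx)
        else:
            zi = self.z_index[rows]
            Cxz = np.zeros((p, self.q))
            np.add.at(Cxz.T, zi, (X * Rw[:, None]))
            rz = np.zeros(self.q)
            np.add.at(rz, zi, Rw * y)
            CzzInv_Czx = solve_czz(Cxz.T)
            CzzInv_rz = solve_czz(rz)
            S = Cxx - Cxz @ CzzInv_Czx
            sol = np.linalg.solve(S, rx - Cxz @ CzzInv_rz)
            a_hat = CzzInv_rz - CzzInv_Czx @ sol
            resid_q = float(y @ (Rw * y)) - float(sol @ rx) - float(a_hat @ rz)
        # residual variance profiled at fixed lambda (REML-style denominator)
        sigma2_e_hat = max(resid_q / (n - p), 1e-300)
        cov_fixed = sigma2_e_hat * np.linalg.inv(S)
        cov_fixed = 0.5 * (cov_fixed + cov_fixed.T)
        return MixedModelFit(
            mu_hat=float(sol[0]),
            beta_hat=sol[1:],
            cov_fixed=cov_fixed,
            a_hat=a_hat,
            sigma2_e_hat=sigma2_e_hat,
            vc=self.vc,
            n_used=n,
            pheno_ids=[self.pheno_ids[i] for i in rows],
            fixed_names=names,
        )


def fit_weighted_animal_model(
    phenotypes: PhenotypeTable,
    trait: str,
    kinship_inverse: KinshipMatrix,
    fixed_design: np.ndarray | None = None,
    vc: VarianceComponents | str = "estimate",
    A_pheno: np.ndarray | None = None,
    fixed_names: Sequence[str] | None = None,
) -> tuple[MixedModelFit, MixedModelContext]:
    """Fit the weighted polygenic regression for one trait.

    With ``vc="estimate"`` the variance components are first obtained by
    REML on the intercept-only model (requires ``A_pheno``, the additive
    relationship submatrix over the phenotyped ids) and then held fixed.
    Returns the fit and the reusable context for further tests.
    """
    ids, y, rel = phenotypes.for_trait(trait)
    missing = [i for i in ids if i not in kinship_inverse._index]
    if missing:
        raise KeyError(f"phenotyped ids absent from pedigree: {missing[:5]}")
    if vc == "estimate":
        if A_pheno is None:
            raise ValueError("vc='estimate' requires A_pheno (relationships of phenotyped ids)")
        vc = reml_variance_components(y, rel, A_pheno)
    ctx = MixedModelContext(ids, y, rel, kinship_inverse, vc)
    fit = ctx.fit(fixed_design, fixed_names=fixed_names)
    return fit, ctx


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    test_id: str
    trait: str
    kind: str                     # "snp" | "block"
    estimate: tuple[float, ...]   # b-hat, or haplotype contrasts vs reference
    wald_chi2: float
    df: int
    p_raw: float
    n_used: int
    p_fdr: float | None = None
    note: str = ""


def test_snp(
    ctx: MixedModelContext, g: GenotypeMatrix, snp_id: str, trait: str = ""
) -> AssociationResult:
    """Single-SNP Wald test b^2 / Var(b), df = 1.

    Genotype codes count the minor allele; individuals with a missing
    call at this SNP are dropped (complete case per test).  Monomorphic
    in the phenotyped subset raises :class:`MonomorphicSnpError`.
    """
    col = g.column(snp_id)
    geno_of = dict(zip(g.ids, col))
    codes = np.array([geno_of.get(i, MISSING) for i in ctx.pheno_ids], dtype=float)
    rows = np.flatnonzero(codes != MISSING)
    x = codes[rows]
    if len(rows) == 0 or np.all(x == x[0]):
        raise MonomorphicSnpError(f"{snp_id}: monomorphic/absent in phenotyped subset")
    full = np.zeros(len(ctx.pheno_ids))
    full[rows] = x
    fit = ctx.fit(full[:, None], rows=rows, fixed_names=[snp_id])
    b = float(fit.beta_hat[0])
    var_b = float(fit.cov_fixed[1, 1])
    wald = b * b / var_b
    p = float(stats.chi2.sf(wald, df=1))
    return AssociationResult(snp_id, trait, "snp", (b,), wald, 1, p, fit.n_used)


def test_haplotype_block(
    ctx: MixedModelContext,
    block: HaplotypeBlock,
    trait: str = "",
    test_id: str | None = None,
) -> AssociationResult:
    """Joint Wald test of a haplotype block, df = k - 1.

    The dosage design rows sum to 2, so one class (the pooled class when
    present, else the last) is dropped to break confounding with the
    intercept; the reported effects are contrasts against that reference
    and the Wald value is invariant to the choice.  Aliased haplotype
    columns are dropped with a reduced df and a log entry.
    """
    if block.dosage is None:
        raise ValueError("block has no dosage design; run haplotype_dosage_design first")
    if block.k < 2:
        raise UndefinedStatisticError("haplotype test needs k >= 2 classes")
    ref = block.k - 1  # pooled class is last by construction, else last kept
    keep_cols = [j for j in range(block.k) if j != ref]
    labels = [block.class_labels[j] for j in keep_cols]
    dos = {i: block.dosage[r, :] for r, i in enumerate(block.ids)}
    rows = np.flatnonzero(np.array([i in dos for i in ctx.pheno_ids]))
    if len(rows) == 0:
        raise UndefinedStatisticError("no phenotyped individuals in block design")
    X = np.zeros((len(ctx.pheno_ids), len(keep_cols)))
    for r in rows:
        X[r] = dos[ctx.pheno_ids[r]][keep_cols]
    note = ""
    sub = X[rows]
    # drop aliased columns (e.g. a class absent from the phenotyped subset)
    while len(keep_cols) > 0 and np.linalg.matrix_rank(np.column_stack([np.ones(len(rows)), sub])) < sub.shape[1] + 1:
        qr_diag = np.abs(np.diag(np.linalg.qr(np.column_stack([np.ones(len(rows)), sub]))[1]))
        drop = int(np.argmin(qr_diag[1:]))
        log.warning("dropping aliased haplotype column %s", labels[drop])
        note = f"aliased column dropped: {labels[drop]}"
        del keep_cols[drop], labels[drop]
        X = np.delete(X, drop, axis=1)
        sub = X[rows]
    if len(keep_cols) == 0:
        raise UndefinedStatisticError("all haplotype columns aliased")
    fit = ctx.fit(X, rows=rows, fixed_names=labels)
    h = fit.beta_hat
    cov = fit.cov_fixed[1:, 1:]
    wald = float(h @ np.linalg.solve(cov, h))
    df = len(h)
    p = float(stats.chi2.sf(wald, df=df))
    tid = test_id or "+".join(block.snp_ids) or "block"
    return AssociationResult(tid, trait, "block", tuple(h), wald, df, p, fit.n_used, note=note)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = list(p_values)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def attach_fdr(
    results: Sequence[AssociationResult], family: str = "global"
) -> list[AssociationResult]:
    """Attach BH-adjusted p-values; family = "global" or "per-trait"."""
    results = list(results)
    if family == "global":
        groups: dict[str, list[int]] = {"": list(range(len(results)))}
    elif family == "per-trait":
        groups = {}
        for i, r in enumerate(results):
            groups.setdefault(r.trait, []).append(i)
    else:
        raise ValueError("family must be 'global' or 'per-trait'")
    out = list(results)
    for idxs in groups.values():
        adj = fdr_adjust([results[i].p_raw for i in idxs])
        for i, a in zip(idxs, adj):
            r = results[i]
            out[i] = AssociationResult(
                r.test_id, r.trait, r.kind, r.estimate, r.wald_chi2, r.df,
                r.p_raw, r.n_used, p_fdr=float(a), note=r.note,
            )
    return out


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test_id": [r.test_id for r in results],
            "trait": [r.trait for r in results],
            "kind": [r.kind for r in results],
            "n_used": [r.n_used for r in results],
            "estimate": [";".join(f"{e:.6g}" for e in r.estimate) for r in results],
            "wald_chi2": [r.wald_chi2 for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "note": [r.note for r in results],
        }
    )


def relative_expression_ddct(
    ct_target: float, ct_reference: float, calibrator_delta: float = 0.0
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - calibrator_delta; returns
    2 ** (-ddCt), the fold change relative to the calibrator sample.
    """
    ddct = (ct_target - ct_reference) - calibrator_delta
    return float(2.0 ** (-ddct))
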