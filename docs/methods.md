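# Methods

## The design and the phenotype

The package targets paternal half-sib daughter designs: a small number
of unrelated sires (default 13), each with a family of daughters
(default 638 in total, family sizes 5–136, mean ≈ 49) out of unrelated,
ungenotyped dams. The phenotype is each daughter's estimated breeding
value (EBV) for a milk production trait, accompanied by its reliability
REL ∈ (0, 1] (squared accuracy). EBVs are treated as weighted
observations: the residual variance of daughter *i* is modelled as
σ²ₑ/RELᵢ, i.e. `W = diag(1/RELᵢ)`.

## Pedigree kinship

`build_A` implements the tabular method: processing individuals in
topological order, `a_ii = 1 + a_{sd}/2` and `a_ij = (a_{js} + a_{jd})/2`,
unknown parents contributing zero. `build_A_inverse` uses Henderson's
direct rules with inbreeding: the Mendelian-sampling variance is
`0.5 − 0.25(F_s + F_d)` (both parents known), `0.75 − 0.25 F_p` (one),
or 1 (none), with F taken from the tabular diagonal; the result matches
the dense inverse exactly, and tests assert `A·A⁻¹ = I` to 1e-8 on
random pedigrees up to 500 individuals. A is stored dense — the
intended scale (≲ a few thousand ids) does not justify sparse
machinery. Individuals present in genotype/phenotype files but missing
from the pedigree are auto-added as unrelated founders with a warning;
by default the pipeline keeps every id it sees (sires, dams,
daughters) in the polygenic structure.

## Per-SNP statistics

Genotype codes count copies of allele 2 (after orientation, the
within-sample minor allele; orientation flips are recorded because they
change the sign of b̂ but not the p-value). Missing calls are dropped
per SNP, never imputed. The HWE test is the plain Pearson
goodness-of-fit chi-square against expected counts (np², 2npq, nq²)
from the sample allele frequencies on 1 df (3 classes − 1 − 1 estimated
frequency), with no continuity correction; monomorphic SNPs raise an
error rather than reporting a vacuous p = 1. Under exact-HWE sampling
at n = 638 the test rejects 5% ± 1% at α = 0.05 (checked over 10,000
simulated SNPs).

## Haplotypes, D′ and blocks

`em_haplotype_frequencies` maximises the multinomial phase likelihood
over the enumerable haplotype space of a SNP window (intended ≤ ~12
SNPs): each genotype with H heterozygous sites has 2^(H−1) compatible
unordered phase pairs; E-steps weight pairs by `(2−δ)·f₁f₂`, M-steps
re-estimate frequencies from expected gamete counts. Initialisation is
the linkage-equilibrium product of allele frequencies; convergence when
the largest frequency change drops below 1e-6 (max 1000 iterations,
non-convergence flagged, never raised); the log-likelihood is monotone
by construction and asserted in tests. Individuals with any missing
call inside a window are excluded from that window only.

D′ uses the standard normalisation `|D|/Dmax` with
`Dmax = min(p_A p_b, p_a p_B)` for D > 0 and `min(p_A p_B, p_a p_b)`
for D < 0; monomorphic loci make it undefined. A pair of SNPs is an
*informative comparison* when both have MAF ≥ 0.05 and the two-locus EM
converged — the term is not otherwise pinned down, and this mirrors how
LD-block software excludes uninformative pairs. Blocks are maximal
contiguous runs (≥ 2 SNPs, position order) in which at least a fraction
0.9 (≥ rule) of informative pairs have D′ > 0.75; the search is greedy
longest-first, leftmost among equals, non-overlapping. The
confidence-interval machinery of Haploview-style algorithms is
deliberately not reproduced: only the two published parameters define
the rule here.

Haplotypes with frequency > 5% are distinguishable classes; all others
merge into a single pooled class whose frequency is their sum (a design
with no class above the threshold is an error). The trend-regression
design holds expected dosages: row *i*, column *j* is the posterior
expected number of copies of class *j*, so every row sums to 2; a
hard-assignment (most probable phase) variant exists behind a flag but
posterior weighting is the default because it avoids arbitrary
tie-breaking.

## Mixed models and tests

Both association models share the machinery: `y = 1μ + Fβ + Za + e`
with `Var(a) = Aσ²ₐ`, `Var(e) = Wσ²ₑ`. The solver assembles Henderson's
mixed model equations and eliminates the random-effect block by a Schur
complement on its Cholesky factor — the factor depends only on the
phenotyped set, the weights and λ = σ²ₑ/σ²ₐ, so per-SNP and per-block
tests reuse it. For repeated fits at *changing* λ over a fixed design
(simulation studies), a spectral solver diagonalises
`C⁻¹(Z′W⁻¹Z)C⁻ᵀ` (with `A⁻¹ = CC′`) once, after which any λ costs only
matrix-vector work; the two paths agree to machine precision.

The sampling covariance of the fixed effects is the inverted
coefficient-matrix block scaled by the residual variance *profiled at
the fixed ratio*: σ̂²ₑ = (y′W⁻¹y − β̂′X′W⁻¹y − â′Z′W⁻¹y)/(n − p). This
makes the fit depend on the variance components only through λ —
doubling both components changes nothing, which is asserted as an
invariant — and reduces to OLS when REL ≡ 1 and σ²ₐ → 0.

Variance components are estimated per trait by REML on the
intercept-only model and then held fixed for all of that trait's tests
(per-test re-estimation would add runtime without changing single-gene
panels materially). The REML implementation profiles the likelihood
down to the single ratio γ = σ²ₐ/σ²ₑ via the spectral decomposition of
`W^{-1/2} A_pheno W^{-1/2}` (grid scan then bounded refinement on
log γ); this is exact rather than iterative AI/EM updating, and a ratio
at the lower search bound is reported as a boundary fit (σ²ₐ ≈ 0) with
a warning.

Single-SNP tests use the Wald chi-square b̂²/Var(b̂) on 1 df, minor
allele coded 1, complete-case per SNP (the polygenic structure always
spans the full pedigree); monomorphic SNPs are skipped with the reason
recorded. Haplotype tests drop the pooled (else last) class to break
the confounding of `1μ` with a design whose rows sum to 2; reported
effects are contrasts against that reference, the joint Wald value is
invariant to the choice (asserted), and df = k − 1. Columns aliased in
the phenotyped subset are dropped with a log entry and a df reduction.
P-values are asymptotic chi-square; no small-sample t/F correction is
applied, matching the Wald form the models specify. BH adjustment (via
statsmodels) runs over the declared family — by default all tests in a
run, optionally per trait; the run log records the choice because the
family definition is otherwise ambiguous.

## Synthetic data

`simulate_population` draws sire and dam gametes either from a block
haplotype spectrum (the built-in reference block: five common
haplotypes plus rare ones, frequencies renormalised from their
published percentages) or independently per SNP from target MAFs; each
daughter gets one recombination-free sire gamete and one dam gamete.
True breeding values follow the gametic recursion — parents are always
non-inbred founders in these two-generation pedigrees, so the
Mendelian-sampling variance is exactly σ²ₐ/2 and `Cov(a) = Aσ²ₐ`
without materialising A (which keeps n = 10,000 runs cheap).
Reliabilities are uniform on (0.3, 0.9) by default, a realistic range
for daughter EBVs. The EBV noise model is `EBV = TBV + e*` with
`Var(e*) = ((1−r)/r)σ²ₐ`, the standard approximation under which
r = σ²ₐ/(σ²ₐ + Var(e*)); passing an explicit σ²ₑ switches to
`Var(e*) = σ²ₑ/r`, exactly the residual law the analysis model assumes.
Family sizes come from a truncated negative-binomial (dispersion 2)
matched to the (5, 136, mean ≈ 49) profile and adjusted to the exact
total. One seed drives three deterministically derived sub-streams
(structure, genotypes, phenotypes); identical configs reproduce
byte-identical datasets.

What the generator does *not* emulate: recombination within the panel,
selection or drift, genotyping error, related dams, and the national
evaluation model behind real EBVs. Passing tests therefore demonstrate
the estimators' correctness and calibration under the stated design,
not robustness to those realities.

## Validation studies

The calibration and recovery studies (shared between the test suite and
`scripts/acceptance.py`) fix one realisation of the design (pedigree,
reliabilities, kinship) and redraw phenotypes and genotypes per
replicate from the analysis model (`a ~ N(0, Aσ²ₐ)`,
`e_i ~ N(0, σ²ₑ/rᵢ)`). Each replicate is analysed as the pipeline would
analyse it: REML on that replicate's phenotypes, then Wald tests at the
estimated ratio. Problem sizes: 2000 replicates for type-I error (SNP
and 5-haplotype block), 500 for effect recovery and interval coverage,
20 random instances (n ≤ 200) for the MME-vs-GLS oracle, 200 seeds for
EM frequency recovery on iid-gamete data. The EM oracle for two-locus
windows maximises the observed-data likelihood along the
completed-count curve on a 2001-point grid — independent of the EM
iteration it checks.

## Known limitations

- Wald p-values are asymptotic; with very rare haplotype classes the
  block test's small-sample behaviour degrades (the pooling rule is the
  main guard).
- The block detector's greedy longest-first rule is a deliberate
  simplification of confidence-interval-based algorithms; on panels
  with borderline LD the block boundaries may differ from Haploview's.
- EBVs as phenotypes inherit whatever bias the upstream genetic
  evaluation had; the package treats them as given observations.
- The EM phase space grows as 2^(H−1) per individual; windows beyond
  ~12 heterozygous sites are not supported by design.
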