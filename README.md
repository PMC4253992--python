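# halfsib

Candidate-gene association analysis for **half-sib daughter designs** in
dairy cattle: single-SNP and haplotype-based mixed-model regression on
estimated breeding values (EBVs), with the pedigree relationship matrix
as the polygenic covariance structure.

The motivating setting is a panel of SNPs in one candidate gene (the
bovine *HAL* gene on BTA5 is the built-in reference panel) genotyped in
daughters of a handful of sires — here 13 sires and 638 daughters, with
family sizes from 5 to 136 (mean ≈ 49). Because individual-level data
for that population were never deposited, the package ships a seeded
synthetic-population generator that reproduces the design's statistical
structure, so every stage is testable end to end.

## Models

**Single-SNP weighted polygenic regression.** For each SNP,

```
y = 1μ + b·x + Z a + e,   a ~ N(0, A σ²ₐ),   e ~ N(0, W σ²ₑ)
```

where `y` are the daughters' EBVs, `x` counts copies of the minor
allele (0/1/2), `A` is the additive relationship matrix from the
pedigree, and `W = diag(1/RELᵢ)` down-weights EBVs with low
reliability. Estimates come from Henderson's mixed model equations; the
test is the Wald chi-square `b̂²/Var(b̂)` on 1 df.

**Haplotype trend regression with polygenic random effects.**

```
y = 1μ + X h + Z a + e
```

with `X` the n × k matrix of expected haplotype-class dosages (EM phase
posteriors; rows sum to 2). Blocks are contiguous SNP runs with ≥ 90%
of informative pairwise comparisons at D′ > 0.75; haplotypes with
frequency ≤ 5% are pooled into one class. The joint Wald statistic
`ĥ′[Var(ĥ)]⁻¹ĥ` over the identifiable contrasts is referred to
chi-square with k − 1 df.

Variance components are estimated per trait by REML on the
intercept-only model and held fixed across tests; Benjamini–Hochberg
FDR is applied over the declared test family. Per-SNP descriptives
(genotype counts, MAF, Hardy–Weinberg chi-square goodness-of-fit) and a
`2^-ΔΔCt` expression helper round out the toolkit.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/02_snp_summaries_and_hwe.py` reconstructs the
reference panel's genotype counts from its published frequencies at
n = 638 and prints

```
snp           region    counts             MAF     HWE p
ss974768524   intron2   (375, 206, 57)   0.251    0.0004
ss974768525   exon5     (413, 200, 25)   0.196    0.8981
ss974768529   intron11  (50, 241, 347)   0.267    0.3699
ss974768531   intron17  (276, 307, 55)   0.327    0.0181
...
```

— the MAF column is the minor-allele frequency implied by the counts,
and the HWE p-value flags loci whose genotype proportions depart from
p², 2pq, q² (the intron-2 SNP clearly does; most loci do not).
`examples/04_association_pipeline.py` injects a known allele effect
into a simulated population, runs the full workflow and shows the
causal SNP ranked first with an FDR-adjusted p ≈ 0.03.

There is also a thin CLI: `halfsib simulate|summarize|assoc-snp|blocks|assoc-hap|run-all`.

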