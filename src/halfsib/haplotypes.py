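"""Haplotype frequency estimation, linkage disequilibrium and blocks.

Unphased multi-locus genotypes are phased probabilistically with an EM
algorithm over the enumerable haplotype space of a small SNP window
(candidate-gene scale, up to ~12 SNPs).  Two-locus EM frequencies feed
the D' statistic; contiguous runs of SNPs whose pairwise D' values are
strong form haplotype blocks; rare block haplotypes are pooled into a
single class; and per-individual expected haplotype dosages (the trend
regression design) are taken from the EM phase posteriors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genostats import UndefinedStatisticError
from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_DPRIME_THRESHOLD = 0.75
DEFAULT_STRONG_FRACTION = 0.9
DEFAULT_POOL_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------

def _compatible_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype pairs (as bitmasks) consistent with a genotype.

    Bit l of a mask is 1 when the haplotype carries allele2 at locus l.
    A genotype heterozygous at H loci has 2^(H-1) compatible pairs (one
    free phase choice per heterozygous locus beyond the first).
    """
    het = [l for l, c in enumerate(genotype) if c == 1]
    base = sum(1 << l for l, c in enumerate(genotype) if c == 2)
    if not het:
        return [(base, base)]
    pairs = []
    first, rest = het[0], het[1:]
    for assignment in itertools.product((0, 1), repeat=len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for l, a in zip(rest, assignment):
            if a:
                h1 |= 1 << l
            else:
                h2 |= 1 << l
        pairs.append((h1, h2) if h1 <= h2 else (h2, h1))
    return pairs


@dataclass
class HaplotypeFreqResult:
    """EM output for one SNP window.

    ``posteriors`` holds, per retained individual, the posterior
    probability of each compatible (h1, h2) phase pair.
    """

    snp_ids: list[str]
    haplotypes: list[int]  # bitmasks, allele2 = set bit
    frequencies: np.ndarray
    kept_ids: list[str]
    posteriors: list[list[tuple[int, int, float]]]
    log_likelihood: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    alleles: list[tuple[str, str]]

    def haplotype_string(self, mask: int) -> str:
        return "".join(
            a2 if (mask >> l) & 1 else a1 for l, (a1, a2) in enumerate(self.alleles)
        )

    @property
    def haplotype_strings(self) -> list[str]:
        return [self.haplotype_string(h) for h in self.haplotypes]


def em_haplotype_frequencies(
    g: GenotypeMatrix,
    snp_ids: Sequence[str],
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> HaplotypeFreqResult:
    """Maximum-likelihood haplotype frequencies for a SNP window via EM.

    Individuals with any missing call inside the window are excluded.
    Initialisation is the linkage-equilibrium product of sample allele
    frequencies (deterministic, no restarts); convergence when the max
    absolute frequency change drops below ``tol``.  Non-convergence at
    ``max_iter`` is flagged on the result, not raised.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) < 2:
        raise ValueError("need at least two SNPs for haplotype estimation")
    sub = g.subset_snps(snp_ids)
    keep = ~(sub.calls == MISSING).any(axis=1)
    if not keep.any():
        raise UndefinedStatisticError("no individuals without missing calls in window")
    calls = sub.calls[keep]
    kept_ids = [i for i, k in zip(g.ids, keep) if k]
    L = len(snp_ids)

    genos, inverse, counts = np.unique(calls, axis=0, return_inverse=True, return_counts=True)
    pair_lists = [_compatible_pairs(tuple(row)) for row in genos]

    hap_set = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    hap_index = {h: k for k, h in enumerate(hap_set)}

    # linkage-equilibrium initialisation from sample allele frequencies
    p2 = calls.mean(axis=0) / 2.0
    p2 = np.clip(p2, 1e-6, 1 - 1e-6)
    freqs = np.array(
        [np.prod([p2[l] if (h >> l) & 1 else 1 - p2[l] for l in range(L)]) for h in hap_set]
    )
    freqs /= freqs.sum()

    n_chrom = 2 * counts.sum()
    pair_idx = [
        (np.array([hap_index[a] for a, _ in pairs]),
         np.array([hap_index[b] for _, b in pairs]),
         np.array([1.0 if a == b else 2.0 for a, b in pairs]))
        for pairs in pair_lists
    ]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros_like(freqs)
        ll = 0.0
        for gi, (ia, ib, mult) in enumerate(pair_idx):
            w = mult * freqs[ia] * freqs[ib]
            tot = w.sum()
            if tot <= 0:
                continue
            ll += counts[gi] * np.log(tot)
            w = w / tot * counts[gi]
            np.add.at(new, ia, w)
            np.add.at(new, ib, w)
        new /= n_chrom
        trace.append(float(ll))
        delta = np.max(np.abs(new - freqs))
        freqs = new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("EM did not converge in %d iterations (window %s)", max_iter, snp_ids)

    # final posteriors per individual
    posts_by_geno: list[list[tuple[int, int, float]]] = []
    for gi, pairs in enumerate(pair_lists):
        ia, ib, mult = pair_idx[gi]
        w = mult * freqs[ia] * freqs[ib]
        tot = w.sum()
        w = w / tot if tot > 0 else np.full_like(w, 1.0 / len(w))
        posts_by_geno.append([(a, b, float(wi)) for (a, b), wi in zip(pairs, w)])
    posteriors = [posts_by_geno[inverse[i]] for i in range(len(kept_ids))]

    alleles = [(s.allele1, s.allele2) for s in sub.snps]
    return HaplotypeFreqResult(
        snp_ids=snp_ids,
        haplotypes=hap_set,
        frequencies=freqs,
        kept_ids=kept_ids,
        posteriors=posteriors,
        log_likelihood=trace[-1] if trace else float("nan"),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# D'
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    hap_freqs: tuple[float, float, float, float]  # pAB, pAb, paB, pab
    D: float
    Dprime: float


def d_prime(
    hap_freqs: Sequence[float], snp_a: str = "a", snp_b: str = "b"
) -> LdPair:
    """D' from two-locus haplotype frequencies (pAB, pAb, paB, pab).

    D = pAB - pA*pB; Dmax = min(pA*pb, pa*pB) for D > 0 and
    min(pA*pB, pa*pb) for D < 0; D' = |D|/Dmax.  Either locus being
    monomorphic makes the statistic undefined.
    """
    pAB, pAb, paB, pab = (float(x) for x in hap_freqs)
    total = pAB + pAb + paB + pab
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("haplotype frequencies must sum to 1")
    pA, pB = pAB + pAb, pAB + paB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa) <= 1e-12 or min(pB, pb) <= 1e-12:
        raise UndefinedStatisticError("D' undefined when a locus is monomorphic")
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        return LdPair(snp_a, snp_b, (pAB, pAb, paB, pab), 0.0, 0.0)
    return LdPair(snp_a, snp_b, (pAB, pAb, paB, pab), D, abs(D) / dmax)


def pairwise_dprime(
    g: GenotypeMatrix,
    snp_ids: Sequence[str] | None = None,
    maf_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs D' and informativeness flags for a SNP panel.

    A pair is informative when both SNPs have MAF >= ``maf_threshold``
    and the two-locus EM converged (mirrors the exclusion of
    uninformative comparisons in standard LD-block software).
    Returns (dprime, informative) as m x m arrays (NaN / False on the
    diagonal and uninformative pairs).
    """
    from .genostats import genotype_counts, minor_allele_frequency

    snp_ids = list(snp_ids) if snp_ids is not None else g.snp_ids
    m = len(snp_ids)
    maf_ok = []
    for s in snp_ids:
        counts = genotype_counts(g, s)
        try:
            maf_ok.append(minor_allele_frequency(counts) >= maf_threshold)
        except UndefinedStatisticError:
            maf_ok.append(False)
    dp = np.full((m, m), np.nan)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            if not (maf_ok[i] and maf_ok[j]):
                continue
            try:
                res = em_haplotype_frequencies(g, [snp_ids[i], snp_ids[j]])
            except UndefinedStatisticError:
                continue
            if not res.converged:
                continue
            f = np.zeros(4)  # order: 00, 01, 10, 11 over (a2 at i, a2 at j)
            for h, fr in zip(res.haplotypes, res.frequencies):
                f[((h & 1) << 1) | ((h >> 1) & 1)] = fr
            try:
                pair = d_prime([f[3], f[2], f[1], f[0]], snp_ids[i], snp_ids[j])
            except UndefinedStatisticError:
                continue
            dp[i, j] = dp[j, i] = pair.Dprime
            informative[i, j] = informative[j, i] = True
    return dp, informative


# ---------------------------------------------------------------------------
# Block detection
# ---------------------------------------------------------------------------

def _interval_ok(
    dp: np.ndarray,
    informative: np.ndarray,
    i: int,
    j: int,
    dprime_threshold: float,
    strong_fraction: float,
) -> bool:
    pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
    inf_pairs = [(a, b) for a, b in pairs if informative[a, b]]
    if not inf_pairs:
        return False
    strong = sum(1 for a, b in inf_pairs if dp[a, b] > dprime_threshold)
    return strong / len(inf_pairs) >= strong_fraction


def find_blocks(
    g: GenotypeMatrix,
    dprime_threshold: float = DEFAULT_DPRIME_THRESHOLD,
    strong_fraction: float = DEFAULT_STRONG_FRACTION,
    maf_threshold: float = 0.05,
) -> list[list[str]]:
    """Greedy longest-first haplotype block detection.

    A contiguous run of >= 2 position-ordered SNPs is a block candidate
    when at least ``strong_fraction`` of its informative pairwise
    comparisons have D' > ``dprime_threshold``.  Longest candidates are
    claimed first (leftmost among equals); blocks never overlap.
    Returns member SNP id lists, left to right.
    """
    order = sorted(range(len(g.snps)), key=lambda j: (g.snps[j].chromosome, g.snps[j].position))
    snp_ids = [g.snps[j].id for j in order]
    m = len(snp_ids)
    if m < 2:
        return []
    dp, informative = pairwise_dprime(g, snp_ids, maf_threshold)

    candidates = [
        (i, j)
        for length in range(m, 1, -1)
        for i in range(0, m - length + 1)
        for j in [i + length - 1]
        if _interval_ok(dp, informative, i, j, dprime_threshold, strong_fraction)
    ]
    taken = np.zeros(m, dtype=bool)
    blocks: list[list[str]] = []
    for i, j in candidates:  # already longest-first, leftmost among equals
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(snp_ids[i : j + 1])
    blocks.sort(key=lambda b: snp_ids.index(b[0]))
    return blocks


# ---------------------------------------------------------------------------
# Pooling and the trend-regression dosage design
# ---------------------------------------------------------------------------

POOLED_LABEL = "POOLED"


@dataclass
class HaplotypeBlock:
    """A haplotype block with pooled rare classes and dosage design.

    ``class_labels`` lists the distinguishable haplotype strings followed
    by the pooled class (when present); ``dosage`` rows (one per retained
    individual) are expected diploid haplotype counts and sum to 2.
    """

    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    pooled_mask: np.ndarray
    class_labels: list[str]
    class_frequencies: np.ndarray
    ids: list[str] = field(default_factory=list)
    dosage: np.ndarray | None = None

    @property
    def k(self) -> int:
        """Number of haplotype classes in the trend-regression design."""
        return len(self.class_labels)


def pool_rare_haplotypes(
    haplotypes: Sequence[str],
    frequencies: Sequence[float],
    threshold: float = DEFAULT_POOL_THRESHOLD,
    snp_ids: Sequence[str] | None = None,
) -> HaplotypeBlock:
    """Keep haplotypes with frequency > ``threshold``; pool the rest.

    Kept haplotypes are ordered by decreasing frequency; the pooled class
    (sum of all rare frequencies) is appended last when non-empty.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise ValueError("haplotype frequencies must sum to 1")
    pooled = freqs <= threshold
    if pooled.all():
        raise UndefinedStatisticError(
            "no haplotype exceeds the pooling threshold; design is degenerate"
        )
    kept = np.argsort(-freqs, kind="stable")
    kept = [i for i in kept if not pooled[i]]
    labels = [haplotypes[i] for i in kept]
    class_freqs = [freqs[i] for i in kept]
    if pooled.any():
        labels.append(POOLED_LABEL)
        class_freqs.append(float(freqs[pooled].sum()))
    return HaplotypeBlock(
        snp_ids=list(snp_ids) if snp_ids is not None else [],
        haplotypes=list(haplotypes),
        frequencies=freqs,
        pooled_mask=pooled,
        class_labels=labels,
        class_frequencies=np.array(class_freqs),
    )


def haplotype_dosage_design(
    block: HaplotypeBlock, em: HaplotypeFreqResult, hard_assign: bool = False
) -> HaplotypeBlock:
    """Fill the per-individual expected haplotype dosage design.

    Row i, column j is the expected number of copies (0-2) of class j
    carried by individual i under the EM phase posteriors; all pooled
    haplotypes accumulate into the pooled column.  With ``hard_assign``
    the single most probable phase pair is used instead of the posterior
    mean.  Every row sums to 2 (diploid conservation).
    """
    strings = em.haplotype_strings
    class_of = {}
    kept = {lab: j for j, lab in enumerate(block.class_labels) if lab != POOLED_LABEL}
    pooled_col = block.class_labels.index(POOLED_LABEL) if POOLED_LABEL in block.class_labels else None
    for h, s in zip(em.haplotypes, strings):
        if s in kept:
            class_of[h] = kept[s]
        elif pooled_col is not None:
            class_of[h] = pooled_col
        else:
            class_of[h] = None  # unseen-by-pooling haplotype with no pooled class
    k = block.k
    D = np.zeros((len(em.kept_ids), k))
    for i, pairs in enumerate(em.posteriors):
        if hard_assign:
            a, b, _ = max(pairs, key=lambda t: t[2])
            pairs = [(a, b, 1.0)]
        for a, b, w in pairs:
            for h in (a, b):
                col = class_of[h]
                if col is None:
                    raise UndefinedStatisticError(
                        f"haplotype {strings[em.haplotypes.index(h)]} has no class "
                        "(block pooled without a pooled column)"
                    )
                D[i, col] += w
    block.ids = list(em.kept_ids)
    block.dosage = D
    return block


def build_block(
    g: GenotypeMatrix,
    snp_ids: Sequence[str],
    pool_threshold: float = DEFAULT_POOL_THRESHOLD,
    tol: float = 1e-6,
    max_iter: int = 1000,
    hard_assign: bool = False,
) -> HaplotypeBlock:
    """EM + pooling + dosage design for one block in a single call."""
    em = em_haplotype_frequencies(g, snp_ids, tol=tol, max_iter=max_iter)
    block = pool_rare_haplotypes(
        em.haplotype_strings, em.frequencies, threshold=pool_threshold, snp_ids=snp_ids
    )
    return haplotype_dosage_design(block, em, hard_assign=hard_assign)
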