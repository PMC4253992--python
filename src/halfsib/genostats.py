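"""Per-SNP descriptive statistics and the Hardy-Weinberg chi-square test.

Genotype counts (n11, n12, n22) count copies of allele2 (0, 1 and 2
copies respectively); missing calls are dropped per SNP.  The HWE test is
the plain Pearson goodness-of-fit chi-square against expected counts
(np^2, 2npq, nq^2) from the sample allele frequencies, on 1 degree of
freedom (3 classes - 1 - 1 estimated frequency), with no continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given counts."""


@dataclass(frozen=True)
class SnpSummary:
    snp_id: str
    counts: tuple[int, int, int]
    frequencies: tuple[float, float, float]
    maf: float
    hwe_chi2: float | None
    hwe_p: float | None


def genotype_counts(g: GenotypeMatrix, snp_id: str) -> tuple[int, int, int]:
    """Observed genotype counts (n11, n12, n22), missing excluded."""
    col = g.column(snp_id)
    obs = col[col != MISSING]
    return int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2))


def minor_allele_frequency(counts: tuple[int, int, int]) -> float:
    """MAF = min(p, 1-p) with p the allele-2 frequency from the counts."""
    n11, n12, n22 = counts
    n = n11 + n12 + n22
    if n == 0:
        raise UndefinedStatisticError("MAF undefined: zero genotyped individuals")
    p2 = (2 * n22 + n12) / (2 * n)
    return float(min(p2, 1.0 - p2))


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions.

    Returns (chi2, p) with p from a chi-square distribution on 1 df.
    Monomorphic counts raise :class:`UndefinedStatisticError` rather than
    reporting a vacuous p = 1.
    """
    n11, n12, n22 = counts
    n = n11 + n12 + n22
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined: zero genotyped individuals")
    p = (2 * n11 + n12) / (2 * n)  # frequency of allele 1
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise UndefinedStatisticError("HWE test undefined for a monomorphic SNP")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n11, n12, n22], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def summarize_snp(g: GenotypeMatrix, snp_id: str) -> SnpSummary:
    counts = genotype_counts(g, snp_id)
    n = sum(counts)
    if n == 0:
        return SnpSummary(snp_id, counts, (np.nan,) * 3, np.nan, None, None)
    freqs = tuple(c / n for c in counts)
    maf = minor_allele_frequency(counts)
    try:
        chi2, p = hwe_test(counts)
    except UndefinedStatisticError:
        chi2, p = None, None
    return SnpSummary(snp_id, counts, freqs, maf, chi2, p)


def summary_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Panel summary mirroring a genotype-frequency table: one row per SNP."""
    rows = []
    for s in g.snps:
        summ = summarize_snp(g, s.id)
        rows.append(
            {
                "snp": s.id,
                "region": s.region,
                "chromosome": s.chromosome,
                "position": s.position,
                "allele1": s.allele1,
                "allele2": s.allele2,
                "n": sum(summ.counts),
                "n11": summ.counts[0],
                "n12": summ.counts[1],
                "n22": summ.counts[2],
                "freq11": summ.frequencies[0],
                "freq12": summ.frequencies[1],
                "freq22": summ.frequencies[2],
                "maf": summ.maf,
                "hwe_chi2": summ.hwe_chi2,
                "hwe_p": summ.hwe_p,
            }
        )
    return pd.DataFrame(rows)


def write_summary(g: GenotypeMatrix, path: str | Path) -> pd.DataFrame:
    df = summary_table(g)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
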