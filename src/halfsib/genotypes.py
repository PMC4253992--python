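"""In-memory container for unphased biallelic SNP genotypes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = -1


@dataclass(frozen=True)
class SnpInfo:
    """Descriptor of one biallelic SNP.

    ``allele2`` is the counted allele: genotype codes 0/1/2 are copies of
    allele2.  After minor-allele orientation allele2 is the minor allele.
    """

    id: str
    chromosome: str
    position: int  # 1-based bp
    allele1: str
    allele2: str
    region: str = ""


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs, codes in {0, 1, 2, -1(missing)}."""

    ids: list[str]
    snps: list[SnpInfo]
    calls: np.ndarray  # int8, shape (n, m)
    _snp_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.snps)):
            raise ValueError("calls shape inconsistent with ids/snps")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or -1 (missing)")
        self._snp_index = {s.id: j for j, s in enumerate(self.snps)}
        if len(self._snp_index) != len(self.snps):
            raise ValueError("duplicate SNP id")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def column(self, snp_id: str) -> np.ndarray:
        """Codes for one SNP over all individuals (missing = -1)."""
        return self.calls[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(list(self.ids), [self.snps[j] for j in idx], self.calls[:, idx])

    def orient_to_minor(self) -> tuple["GenotypeMatrix", dict[str, bool]]:
        """Flip codes so that 1 counts the minor allele at every SNP.

        Returns the re-oriented matrix and a per-SNP flag marking which
        SNPs were flipped (allele2 was the major allele in this sample).
        """
        calls = self.calls.copy()
        snps: list[SnpInfo] = []
        flipped: dict[str, bool] = {}
        for j, s in enumerate(self.snps):
            col = calls[:, j]
            obs = col[col != MISSING]
            p2 = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
            if p2 > 0.5:
                col_new = col.copy()
                mask = col != MISSING
                col_new[mask] = 2 - col_new[mask]
                calls[:, j] = col_new
                snps.append(SnpInfo(s.id, s.chromosome, s.position, s.allele2, s.allele1, s.region))
                flipped[s.id] = True
            else:
                snps.append(s)
                flipped[s.id] = False
        return GenotypeMatrix(list(self.ids), snps, calls), flipped
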