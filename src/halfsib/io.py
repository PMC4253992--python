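"""Reading and writing genotype files (PLINK .ped/.map and VCF).

PLINK text dialect: whitespace-separated .ped with the six leading
columns (family, individual, sire, dam, sex, phenotype) followed by two
allele letters per SNP ("0" = missing), and a four-column .map
(chromosome, snp id, genetic distance, 1-based bp position).  VCF is
read through cyvcf2 when available; only biallelic records are accepted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, SnpInfo
from .pedigree import Pedigree


class GenotypeFileError(ValueError):
    pass


def write_ped_map(
    g: GenotypeMatrix, prefix: str | Path, pedigree: Pedigree | None = None
) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\n")
    parent = {}
    if pedigree is not None:
        parent = {r.individual: (r.sire or "0", r.dam or "0") for r in pedigree.records}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(g.ids):
            sire, dam = parent.get(ind, ("0", "0"))
            fields = [sire if sire != "0" else "FAM", ind, sire, dam, "0", "-9"]
            for j, s in enumerate(g.snps):
                c = g.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [s.allele1, s.allele1]
                elif c == 1:
                    fields += [s.allele1, s.allele2]
                else:
                    fields += [s.allele2, s.allele2]
            fh.write(" ".join(map(str, fields)) + "\n")


def read_ped_map(
    prefix: str | Path,
    alleles: dict[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a GenotypeMatrix.

    Codes count copies of allele2.  With ``alleles`` given (snp id ->
    (allele1, allele2)), that assignment is used; otherwise allele2 is
    the rarer observed allele (alphabetically later on a tie), so codes
    count the within-sample minor allele.  A SNP observed with more than
    two alleles, or with an allele conflicting with an explicit
    assignment, is an error naming the SNP.
    """
    prefix = Path(prefix)
    snps_raw = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, snp_id, _, pos = line.split()[:4]
            snps_raw.append((snp_id, chrom, int(pos)))
    m = len(snps_raw)
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeFileError(
                    f"ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    allele_pairs = np.array(rows, dtype=object).reshape(len(ids), m, 2) if ids else np.empty((0, m, 2), object)

    calls = np.full((len(ids), m), MISSING, dtype=np.int8)
    infos = []
    for j, (snp_id, chrom, pos) in enumerate(snps_raw):
        col = allele_pairs[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise GenotypeFileError(f"SNP {snp_id} has more than two alleles: {uniq}")
        if alleles and snp_id in alleles:
            a1, a2 = alleles[snp_id]
            if not set(uniq) <= {a1, a2}:
                raise GenotypeFileError(
                    f"SNP {snp_id}: observed alleles {uniq} conflict with assignment ({a1},{a2})"
                )
        else:
            if len(uniq) == 0:
                a1, a2 = "N", "N"
            elif len(uniq) == 1:
                a1, a2 = uniq[0], "N"
            else:
                counts = {u: int(np.sum(observed == u)) for u in uniq}
                # allele2 = minor (alphabetically later on a tie)
                a2 = min(uniq, key=lambda u: (counts[u], -ord(u[0])))
                a1 = [u for u in uniq if u != a2][0]
        miss = (col == "0").any(axis=1)
        calls[:, j] = np.where(miss, MISSING, (col == a2).sum(axis=1))
        infos.append(SnpInfo(snp_id, chrom, pos, a1, a2))
    return GenotypeMatrix(ids, infos, calls)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly uncompressed) VCF of biallelic SNPs via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    infos, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenotypeFileError(
                f"multi-allelic record at {v.CHROM}:{v.POS} ({v.ID or 'no id'})"
            )
        gts = np.array(v.genotypes, dtype=object)
        a = np.array([g[0] for g in gts])
        b = np.array([g[1] for g in gts])
        col = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        infos.append(
            SnpInfo(v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS), v.REF, v.ALT[0])
        )
        cols.append(col)
    calls = np.column_stack(cols) if cols else np.empty((len(ids), 0), dtype=np.int8)
    return GenotypeMatrix(ids, infos, calls)


def read_genotypes(path: str | Path, fmt: str | None = None, **kwargs) -> GenotypeMatrix:
    """Dispatch on format: 'ped' (PLINK prefix or .ped path) or 'vcf'."""
    p = Path(path)
    if fmt is None:
        fmt = "vcf" if p.suffix == ".vcf" else "ped"
    if fmt == "vcf":
        return read_vcf(p)
    if fmt == "ped":
        prefix = p.with_suffix("") if p.suffix in (".ped", ".map") else p
        return read_ped_map(prefix, **kwargs)
    raise ValueError(f"unknown genotype format {fmt!r}")
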