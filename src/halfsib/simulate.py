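"""Synthetic half-sib daughter-design datasets.

Emulates the study population the analysis assumes: a handful of
unrelated sires, each with a paternal half-sib family of daughters out
of unrelated dams; a short candidate-gene SNP panel inherited without
recombination; and EBV phenotypes with heterogeneous reliabilities.

The default configuration is 13 sires and 638 daughters with family
sizes between 5 and 136 averaging about 49 (truncated negative-binomial
draw adjusted to the exact total), reliabilities uniform on (0.3, 0.9)
and unit additive variance.  The EBV noise model is
EBV = TBV + e* with Var(e*) = ((1 - r)/r) * sigma2_a, so that the
reliability r equals sigma2_a / (sigma2_a + Var(e*)); passing an
explicit ``sigma2_e`` switches to Var(e*) = sigma2_e / r, the residual
law the weighted analysis model itself assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix, SnpInfo
from .models import PhenotypeTable, write_phenotypes
from .pedigree import Pedigree, write_pedigree
import pandas as pd


@dataclass
class BlockSpec:
    """Haplotype structure for a run of SNPs: strings and frequencies."""

    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: list[float]

    def __post_init__(self) -> None:
        if any(len(h) != len(self.snp_ids) for h in self.haplotypes):
            raise ValueError("haplotype length must equal the number of member SNPs")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("one frequency per haplotype required")
        tot = float(sum(self.frequencies))
        if not np.isclose(tot, 1.0, atol=1e-6):
            self.frequencies = [f / tot for f in self.frequencies]


@dataclass
class SimConfig:
    seed: int
    n_sires: int = 13
    n_daughters: int = 638
    family_sizes: list[int] | None = None
    family_size_range: tuple[int, int] = (5, 136)
    snp_panel: list[tuple[str, str, int, float]] = field(default_factory=list)
    # (snp id, chromosome, position, target MAF); ignored for SNPs in a block
    block_spec: BlockSpec | None = None
    traits: tuple[str, ...] = ("MY",)
    snp_effects: dict = field(default_factory=dict)   # trait -> {snp_id: b}
    hap_effects: dict = field(default_factory=dict)   # trait -> {hap string: h}
    sigma2_a: float = 1.0
    sigma2_e: float | None = None  # None => reliability-consistent noise
    reliability_range: tuple[float, float] = (0.3, 0.9)

    def __post_init__(self) -> None:
        if self.family_sizes is not None and any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if self.block_spec is not None:
            panel_ids = [p[0] for p in self.snp_panel]
            if not set(self.block_spec.snp_ids) <= set(panel_ids):
                raise ValueError("block_spec SNPs must appear in snp_panel")


@dataclass
class SimDataset:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict

    def to_comparable(self) -> dict:
        """Canonical representation for determinism/round-trip checks."""
        return {
            "pedigree": [(r.individual, r.sire, r.dam) for r in self.pedigree.records],
            "ids": self.genotypes.ids,
            "snps": [asdict(s) for s in self.genotypes.snps],
            "calls": self.genotypes.calls.tolist(),
            "phenotypes": self.phenotypes.data.round(12).to_dict("list"),
            "truth": self.truth,
        }


def _draw_family_sizes(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    if cfg.family_sizes is not None:
        return list(cfg.family_sizes)
    lo, hi = cfg.family_size_range
    mean = cfg.n_daughters / cfg.n_sires
    # negative binomial with dispersion r=2 around the target mean, truncated
    r_disp = 2.0
    p = r_disp / (r_disp + mean)
    sizes = []
    while len(sizes) < cfg.n_sires:
        s = int(rng.negative_binomial(r_disp, p))
        if lo <= s <= hi:
            sizes.append(s)
    # adjust to the exact configured total, respecting the bounds
    diff = cfg.n_daughters - sum(sizes)
    while diff != 0:
        j = int(rng.integers(cfg.n_sires))
        step = 1 if diff > 0 else -1
        if lo <= sizes[j] + step <= hi:
            sizes[j] += step
            diff -= step
    return sizes


def _draw_gametes(cfg: SimConfig, n: int, rng: np.random.Generator,
                  panel: list[tuple[str, str, int, float]]) -> np.ndarray:
    """n gametes over the panel: block SNPs from haplotype frequencies,
    the rest independently from target MAFs.  1 = counted allele."""
    m = len(panel)
    out = np.zeros((n, m), dtype=np.int8)
    block_cols: dict[str, int] = {}
    if cfg.block_spec is not None:
        ids = [p[0] for p in panel]
        block_cols = {s: ids.index(s) for s in cfg.block_spec.snp_ids}
        haps = np.array(
            [[1 if c == "1" else 0 for c in h] for h in cfg.block_spec.haplotypes],
            dtype=np.int8,
        )
        choice = rng.choice(len(haps), size=n, p=np.array(cfg.block_spec.frequencies))
        for local, snp in enumerate(cfg.block_spec.snp_ids):
            out[:, block_cols[snp]] = haps[choice, local]
    for j, (snp, _, _, maf) in enumerate(panel):
        if snp in block_cols:
            continue
        out[:, j] = rng.random(n) < maf
    return out


def simulate_population(cfg: SimConfig) -> SimDataset:
    """Generate a seeded half-sib dataset (pedigree, genotypes, EBVs).

    Each daughter inherits one recombination-free sire gamete and one
    dam gamete; dams are unrelated, ungenotyped founders.  True breeding
    values follow the gametic recursion (all parents are non-inbred
    founders, so the Mendelian sampling variance is exactly sigma2_a/2),
    giving Cov(a) = A * sigma2_a.  Deterministic given ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_geno, rng_pheno = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    panel = list(cfg.snp_panel)
    if not panel:
        raise ValueError("snp_panel must contain at least one SNP")
    sizes = _draw_family_sizes(cfg, rng_struct)
    if len(sizes) != cfg.n_sires:
        raise ValueError("family_sizes length must equal n_sires")

    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    daughters, dams, triples = [], [], [(s, None, None) for s in sires]
    k = 0
    for si, s in enumerate(sires):
        for _ in range(sizes[si]):
            k += 1
            d, dam = f"D{k}", f"M{k}"
            daughters.append(d)
            dams.append(dam)
            triples.append((dam, None, None))
            triples.append((d, s, dam))
    ped = Pedigree.from_tuples(triples)

    n_d = len(daughters)
    # one haplotype string encodes which allele (0 = allele1, 1 = allele2)
    sire_gam = _draw_gametes(cfg, 2 * cfg.n_sires, rng_geno, panel).reshape(cfg.n_sires, 2, -1)
    dam_gam = _draw_gametes(cfg, 2 * n_d, rng_geno, panel).reshape(n_d, 2, -1)
    sire_of = np.repeat(np.arange(cfg.n_sires), sizes)
    pat_choice = rng_geno.integers(2, size=n_d)
    paternal = sire_gam[sire_of, pat_choice, :]
    maternal = dam_gam[np.arange(n_d), rng_geno.integers(2, size=n_d), :]
    calls = (paternal + maternal).astype(np.int8)

    snps = [
        SnpInfo(snp, chrom, pos, allele1="A", allele2="B")
        for snp, chrom, pos, _ in panel
    ]
    genotypes = GenotypeMatrix(daughters, snps, calls)

    # true breeding values via the gametic recursion (founder parents)
    sa = np.sqrt(cfg.sigma2_a)
    tbv_sire = rng_pheno.normal(0.0, sa, cfg.n_sires)
    tbv_dam = rng_pheno.normal(0.0, sa, n_d)
    mendelian = rng_pheno.normal(0.0, sa * np.sqrt(0.5), n_d)
    tbv = 0.5 * (tbv_sire[sire_of] + tbv_dam) + mendelian

    rel = rng_pheno.uniform(*cfg.reliability_range, n_d)
    if cfg.sigma2_e is None:
        noise_sd = np.sqrt((1.0 - rel) / rel * cfg.sigma2_a)
    else:
        noise_sd = np.sqrt(cfg.sigma2_e / rel)

    hap_strings_pat = None
    if cfg.hap_effects:
        cols = [[p[0] for p in panel].index(s) for s in cfg.block_spec.snp_ids]
        hap_strings_pat = ["".join(map(str, paternal[i, cols])) for i in range(n_d)]
        hap_strings_mat = ["".join(map(str, maternal[i, cols])) for i in range(n_d)]

    records = []
    for t in cfg.traits:
        eff = np.zeros(n_d)
        for snp, b in cfg.snp_effects.get(t, {}).items():
            eff += b * genotypes.column(snp).astype(float)
        for hap, h in cfg.hap_effects.get(t, {}).items():
            eff += h * (
                np.array([s == hap for s in hap_strings_pat], float)
                + np.array([s == hap for s in hap_strings_mat], float)
            )
        noise = rng_pheno.normal(0.0, 1.0, n_d) * noise_sd
        ebv = tbv + eff + noise
        for i, d in enumerate(daughters):
            records.append((d, t, float(ebv[i]), float(rel[i])))
    phen = PhenotypeTable(
        pd.DataFrame(records, columns=["id", "trait", "ebv", "reliability"])
    )

    truth = {
        "seed": cfg.seed,
        "n_sires": cfg.n_sires,
        "family_sizes": sizes,
        "sigma2_a": cfg.sigma2_a,
        "sigma2_e": cfg.sigma2_e,
        "reliability_range": list(cfg.reliability_range),
        "snp_effects": cfg.snp_effects,
        "hap_effects": cfg.hap_effects,
        "snp_panel": [list(p) for p in panel],
        "block_spec": asdict(cfg.block_spec) if cfg.block_spec else None,
        "sire_gametes": sire_gam.tolist(),
        "paternal_gamete_choice": pat_choice.tolist(),
        "tbv": tbv.tolist(),
    }
    return SimDataset(ped, genotypes, phen, truth)


# ---------------------------------------------------------------------------
# File round trip (PLINK .ped/.map + TSV)
# ---------------------------------------------------------------------------

def write_dataset(d: SimDataset, directory: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Write PLINK .ped/.map, pedigree TSV, phenotype TSV and truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .io import write_ped_map  # local import to avoid a cycle

    paths = {
        "ped": directory / f"{prefix}.ped",
        "map": directory / f"{prefix}.map",
        "pedigree": directory / f"{prefix}.pedigree.tsv",
        "phenotypes": directory / f"{prefix}.phenotypes.tsv",
        "truth": directory / f"{prefix}.truth.json",
    }
    write_ped_map(d.genotypes, directory / prefix, pedigree=d.pedigree)
    write_pedigree(d.pedigree, paths["pedigree"])
    write_phenotypes(d.phenotypes, paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(d.truth, fh, indent=1, sort_keys=True)
    return paths
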