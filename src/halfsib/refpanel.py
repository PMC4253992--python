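"""Published summary data for the bovine HAL candidate-gene SNP panel.

Nine SNPs in the histidine ammonia-lyase (HAL) gene on BTA5, genotyped
in 638 Chinese Holstein half-sib daughters of 13 sires.  Only summary
statistics were ever published — per-SNP genotype frequencies (rounded
to three decimals) and block haplotype frequencies — so these tables are
the package's reference inputs: genotype counts are reconstructed as
round(frequency x 638), and the block-1 haplotype frequencies seed the
default simulation scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import BlockSpec, SimConfig

N_DAUGHTERS = 638
N_SIRES = 13


@dataclass(frozen=True)
class PanelSnp:
    id: str
    region: str
    position: int  # bp on BTA5 (Btau_4.6.1)
    allele1: str
    allele2: str
    genotype_freqs: tuple[float, float, float]  # (hom allele1, het, hom allele2)
    maf_printed: float
    hwe_p_printed: float


PANEL: list[PanelSnp] = [
    PanelSnp("ss974768522", "promoter", 64547553, "C", "T", (0.426, 0.468, 0.106), 0.339, 0.253),
    PanelSnp("ss974768523", "exon1", 64547394, "T", "C", (0.527, 0.385, 0.086), 0.281, 0.257),
    PanelSnp("ss974768524", "intron2", 64546261, "T", "C", (0.588, 0.323, 0.089), 0.251, 0.0004),
    PanelSnp("ss974768525", "exon5", 64545391, "C", "T", (0.647, 0.314, 0.039), 0.196, 0.898),
    PanelSnp("ss974768527", "exon8", 64543949, "G", "A", (0.523, 0.389, 0.088), 0.282, 0.307),
    PanelSnp("ss974768529", "intron11", 64537682, "A", "G", (0.078, 0.378, 0.544), 0.267, 0.370),
    PanelSnp("ss974768531", "intron17", 64529509, "T", "C", (0.433, 0.481, 0.086), 0.327, 0.018),
    PanelSnp("ss974768533", "3utr", 64525640, "C", "A", (0.091, 0.433, 0.476), 0.307, 0.680),
    PanelSnp("ss974768534", "3utr", 64524579, "C", "T", (0.486, 0.420, 0.094), 0.304, 0.850),
]

# Haplotype block 1 (six SNPs): strings over the first six panel SNPs,
# published frequencies in percent (they sum to 99.28 and are
# renormalized wherever a proper distribution is required).
BLOCK1_SNPS = [s.id for s in PANEL[:6]]
BLOCK1_HAPLOTYPES: list[tuple[str, float]] = [
    ("TTTCGG", 33.9),
    ("CCCCAG", 24.8),
    ("CTTTGA", 16.6),
    ("CTTCGA", 9.4),
    ("CTTCGG", 9.1),
    ("CTTTGG", 3.0),
    ("CCTCAG", 2.4),
    ("CCTCAA", 0.07),
    ("CTTCAG", 0.01),
]

# Haplotype block 2 (four-locus strings as published).
BLOCK2_HAPLOTYPES: list[tuple[str, float]] = [
    ("ACAC", 38.8),
    ("CCCC", 30.8),
    ("ATAT", 30.4),
]


def reconstructed_counts(snp: PanelSnp, n: int = N_DAUGHTERS) -> tuple[int, int, int]:
    """Genotype counts recovered from the printed frequencies: round(f*n)."""
    return tuple(int(round(f * n)) for f in snp.genotype_freqs)  # type: ignore[return-value]


def panel_snp(snp_id: str) -> PanelSnp:
    for s in PANEL:
        if s.id == snp_id:
            return s
    raise KeyError(f"unknown panel SNP {snp_id}")


def block1_spec() -> BlockSpec:
    """Block-1 haplotype structure as a binary BlockSpec.

    Letters translate to the counted-allele indicator per site using the
    panel's allele assignment (allele2 -> '1').
    """
    a2 = {s.id: s.allele2 for s in PANEL}
    binary = [
        "".join("1" if h[i] == a2[snp] else "0" for i, snp in enumerate(BLOCK1_SNPS))
        for h, _ in BLOCK1_HAPLOTYPES
    ]
    freqs = np.array([f for _, f in BLOCK1_HAPLOTYPES])
    return BlockSpec(list(BLOCK1_SNPS), binary, list(freqs / freqs.sum()))


def default_sim_config(seed: int, **overrides) -> SimConfig:
    """Simulation scenario matching the study design.

    13 sires, 638 daughters, the nine-SNP panel at the published MAFs,
    and block-1 LD structure over its six member SNPs.
    """
    a2_maf = []
    for s in PANEL:
        f11, f12, f22 = s.genotype_freqs
        p2 = f22 + f12 / 2.0
        a2_maf.append(min(p2, 1 - p2))
    panel = [
        (s.id, "5", s.position, a2_maf[i]) for i, s in enumerate(PANEL)
    ]
    panel = sorted(panel, key=lambda t: t[2])
    cfg = dict(
        seed=seed,
        n_sires=N_SIRES,
        n_daughters=N_DAUGHTERS,
        snp_panel=panel,
        block_spec=block1_spec(),
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
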