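"""End-to-end candidate-gene association workflow.

Order of stages: SNP summaries + HWE -> per-SNP weighted polygenic
regression per trait -> D'-based block detection -> haplotype frequency
EM + rare-haplotype pooling -> haplotype trend regression per block per
trait -> Benjamini-Hochberg FDR over the declared family.  All outputs
are TSV (plus a BED-like block interval file and a JSON run log
recording seed, thresholds, the FDR family definition and n-used per
test).
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genostats import UndefinedStatisticError, write_summary
from .genotypes import GenotypeMatrix
from .haplotypes import (
    DEFAULT_DPRIME_THRESHOLD,
    DEFAULT_POOL_THRESHOLD,
    DEFAULT_STRONG_FRACTION,
    build_block,
    find_blocks,
)
from .io import read_genotypes
from .models import (
    MonomorphicSnpError,
    attach_fdr,
    fit_weighted_animal_model,
    read_phenotypes,
    results_table,
    test_haplotype_block,
    test_snp,
    VarianceComponents,
)
from .pedigree import build_A, build_A_inverse, read_pedigree

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class RunConfig:
    genotypes: str
    pedigree: str
    phenotypes: str
    out_dir: str
    genotype_format: str | None = None
    traits: list[str] | None = None  # None = every trait in the phenotype file
    dprime_threshold: float = DEFAULT_DPRIME_THRESHOLD
    strong_fraction: float = DEFAULT_STRONG_FRACTION
    pool_threshold: float = DEFAULT_POOL_THRESHOLD
    fdr_alpha: float = 0.05
    fdr_family: str = "global"  # or "per-trait"
    vc_mode: str = "estimate"   # or "sigma2_a,sigma2_e"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v, lo, hi in [
            ("dprime_threshold", self.dprime_threshold, 0, 1),
            ("strong_fraction", self.strong_fraction, 0, 1),
            ("pool_threshold", self.pool_threshold, 0, 1),
            ("fdr_alpha", self.fdr_alpha, 0, 1),
        ]:
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _parse_vc(mode: str) -> VarianceComponents | str:
    if mode == "estimate":
        return "estimate"
    try:
        sa, se = (float(x) for x in mode.split(","))
    except Exception as exc:
        raise ValueError("vc_mode must be 'estimate' or 'sigma2_a,sigma2_e'") from exc
    return VarianceComponents(sa, se)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow; returns the structured run report.

    Any stage failure aborts with a stage-tagged :class:`PipelineError`
    and removes partial outputs.
    """
    out = Path(cfg.out_dir)
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(cfg, out)
    except Exception as exc:
        if fresh:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in out.glob("*.tsv"):
                f.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc


def _run(cfg: RunConfig, out: Path) -> dict:
    stage = "load"
    try:
        g_raw = read_genotypes(cfg.genotypes, cfg.genotype_format)
        ped = read_pedigree(cfg.pedigree)
        phen = read_phenotypes(cfg.phenotypes)
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    traits = cfg.traits or phen.traits
    if not traits:
        raise PipelineError("[load] no traits to analyse")

    stage = "orient"
    g, flipped = g_raw.orient_to_minor()

    stage = "pedigree"
    try:
        pheno_ids = sorted(set(phen.data["id"]))
        ped = ped.with_founders([i for i in pheno_ids if i not in ped])
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A)
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    stage = "summaries"
    summary = write_summary(g, out / "snp_summary.tsv")

    stage = "assoc-snp"
    results, skipped = [], []
    contexts = {}
    vc_used = {}
    try:
        for trait in traits:
            ids, _, _ = phen.for_trait(trait)
            A_pheno = A.submatrix(ids)
            fit, ctx = fit_weighted_animal_model(
                phen, trait, Ainv, vc=_parse_vc(cfg.vc_mode), A_pheno=A_pheno
            )
            contexts[trait] = ctx
            vc_used[trait] = {"sigma2_a": ctx.vc.sigma2_a, "sigma2_e": ctx.vc.sigma2_e}
            for snp in g.snp_ids:
                try:
                    results.append(test_snp(ctx, g, snp, trait=trait))
                except MonomorphicSnpError as exc:
                    skipped.append({"test": snp, "trait": trait, "reason": str(exc)})
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    stage = "blocks"
    try:
        block_members = find_blocks(
            g, dprime_threshold=cfg.dprime_threshold, strong_fraction=cfg.strong_fraction
        )
        blocks = []
        for bi, members in enumerate(block_members, start=1):
            try:
                blocks.append((f"block{bi}", build_block(g, members, cfg.pool_threshold)))
            except UndefinedStatisticError as exc:
                skipped.append({"test": f"block{bi}", "trait": "*", "reason": str(exc)})
        _write_blocks(g, block_members, out / "blocks.bed")
        _write_haplotypes(blocks, out / "haplotypes.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    stage = "assoc-hap"
    try:
        for trait in traits:
            ctx = contexts[trait]
            for name, block in blocks:
                try:
                    results.append(test_haplotype_block(ctx, block, trait=trait, test_id=name))
                except UndefinedStatisticError as exc:
                    skipped.append({"test": name, "trait": trait, "reason": str(exc)})
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    stage = "fdr"
    results = attach_fdr(results, family=cfg.fdr_family)
    table = results_table(results)
    table.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.8g")

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "variance_components": vc_used,
        "minor_allele_flips": flipped,
        "fdr_family": cfg.fdr_family,
        "n_snps": len(g.snp_ids),
        "n_traits": len(traits),
        "blocks": [members for members in block_members],
        "n_tests": len(results),
        "n_used": {f"{r.test_id}/{r.trait}": r.n_used for r in results},
        "skipped": skipped,
        "significant": table[table["p_fdr"] <= cfg.fdr_alpha]["test_id"].tolist()
        if len(table)
        else [],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _write_blocks(g: GenotypeMatrix, block_members: list[list[str]], path: Path) -> None:
    """BED-like intervals: chromosome, 0-based half-open span, members."""
    with open(path, "w") as fh:
        for bi, members in enumerate(block_members, start=1):
            infos = [g.snps[g.snp_index(s)] for s in members]
            start = min(s.position for s in infos) - 1
            end = max(s.position for s in infos)
            fh.write(f"{infos[0].chromosome}\t{start}\t{end}\tblock{bi}\t{','.join(members)}\n")


def _write_haplotypes(blocks, path: Path) -> None:
    rows = []
    for name, block in blocks:
        for h, f, pooled in zip(block.haplotypes, block.frequencies, block.pooled_mask):
            rows.append(
                {"block": name, "haplotype": h, "frequency_pct": 100 * f, "pooled": bool(pooled)}
            )
    pd.DataFrame(rows, columns=["block", "haplotype", "frequency_pct", "pooled"]).to_csv(
        path, sep="\t", index=False, float_format="%.4g"
    )
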