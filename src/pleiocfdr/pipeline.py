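"""End-to-end orchestration: simulate/load → align → enrichment/correlation/Q-Q
→ conditional FDR per auxiliary trait → locus clumping → cross-analysis merge
→ expected-false-discovery accounting, driven by one config and one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cfdr as cfdr_mod
from . import crosstrait, io, loci, simulate
from .errors import ConfigError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the analysis chain, each appearing exactly once.

    Defaults are the published operating point: alpha 0.05, cFDR levels
    1%/5%, 500 pruning iterations at r² < 0.2, clumping at r² = 0.1 with a
    250 kb merge window.
    """

    outdir: str = "pleiocfdr_run"
    seed: int = 0
    # either a simulation block ...
    simulation: Mapping[str, Any] | None = None
    hit_rate: float = 0.5
    decoy_rate: float = 0.15
    # ... or input paths
    target_path: str | None = None
    aux_paths: Mapping[str, str] = field(default_factory=dict)
    ld_pairs_path: str | None = None
    blocks_path: str | None = None
    annotation_path: str | None = None
    exclusions_path: str | None = None  # None -> packaged MHC + 8p23.1 regions
    variant_filter_path: str | None = None
    restrict_cfdr_to_filter: bool = False
    # thresholds
    alpha: float = 0.05
    cfdr_levels: tuple = (0.01, 0.05)
    qq_thresholds: tuple = (1.0, 0.1, 0.01, 0.001)
    # cFDR settings
    n_iter: int = 500
    prune_r2: float = 0.2
    grid_step: float = 0.1
    # clumping settings
    clump_r2: float = 0.1
    merge_kb: int = 250

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.cfdr_levels, list):
            cfg.cfdr_levels = tuple(cfg.cfdr_levels)
        if isinstance(cfg.qq_thresholds, list):
            cfg.qq_thresholds = tuple(cfg.qq_thresholds)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(cfg: RunConfig, outdir: Path):
    """Simulate or load the study; returns (joined, aux names, ld, blocks, ann, truth)."""
    if cfg.simulation is not None:
        sim = simulate.SimulationConfig(**dict(cfg.simulation, seed=cfg.seed))
        target, aux, truth = simulate.simulate_sumstats(sim)
        ld = simulate.simulate_ld_model(sim)
        blocks = simulate.blocks_bed(sim)
        ann = simulate.simulate_annotation(sim, truth, cfg.hit_rate, cfg.decoy_rate)
        simulate.write_simulation(sim, outdir / "inputs", cfg.hit_rate, cfg.decoy_rate)
        joined = io.align_variants([target, aux])
        return joined, [aux.trait_name], ld, blocks, ann, truth
    if cfg.target_path is None or not cfg.aux_paths:
        raise ConfigError("need either a simulation block or target_path + aux_paths")
    target = io.read_sumstats(cfg.target_path, trait_name="target")
    auxes = [io.read_sumstats(p, trait_name=n) for n, p in cfg.aux_paths.items()]
    if cfg.variant_filter_path:
        keep = set(pd.read_csv(cfg.variant_filter_path, header=None)[0].astype(str))
        if cfg.restrict_cfdr_to_filter:
            target = io.SummaryStats(
                target.df[target.df["variant_id"].isin(keep)].reset_index(drop=True),
                trait_name=target.trait_name,
            )
    joined = io.align_variants([target] + auxes)
    blocks = io.read_ld_blocks(cfg.blocks_path) if cfg.blocks_path else None
    ld = None
    if cfg.ld_pairs_path:
        block_of = io.assign_blocks(target, blocks) if blocks else {}
        block_of = {v: block_of.get(v, 0) for v in target.df["variant_id"]}
        ld = io.read_ld_pairs(cfg.ld_pairs_path, block_of)
    ann = io.read_intervals(cfg.annotation_path) if cfg.annotation_path else None
    return joined, [a.trait_name for a in auxes], ld, blocks, ann, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full chain; writes per-stage artifacts and returns the report.

    The report (also written to ``report.json``) is a pure function of the
    config and seed: identical inputs give a byte-identical report.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "cfdr_levels": list(cfg.cfdr_levels),
            "n_iter": cfg.n_iter,
            "prune_r2": cfg.prune_r2,
            "grid_step": cfg.grid_step,
            "clump_r2": cfg.clump_r2,
            "merge_kb": cfg.merge_kb,
            "qq_thresholds": list(cfg.qq_thresholds),
        }
    }
    joined, aux_names, ld, blocks, ann, truth = _load_inputs(cfg, outdir)
    target_col = io.trait_columns(joined)[0]
    exclusions = (
        io.read_intervals(cfg.exclusions_path, name="exclusions")
        if cfg.exclusions_path
        else io.default_exclusions()
    )
    logger.info("effective parameters: %s", report["parameters"])

    report["enrichment"] = _enrichment_stage(cfg, joined, aux_names, blocks, ann, exclusions, outdir)
    surfaces, snp_tables = _cfdr_stage(cfg, joined, aux_names, ld, exclusions, outdir, target_col)
    report["loci"] = _loci_stage(cfg, joined, aux_names, ld, exclusions, snp_tables, outdir, target_col)
    if truth is not None:
        report["truth_scoring"] = _truth_stage(cfg, truth, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


@_stage("enrichment")
def _enrichment_stage(cfg, joined, aux_names, blocks, ann, exclusions, outdir):
    out: dict[str, Any] = {}
    rows = []
    for name in aux_names:
        res = crosstrait.fold_enrichment(joined, cfg.alpha, aux=f"p_{name}")
        fold_xy, fold_yx = crosstrait.enrichment_reciprocity_check(
            joined, cfg.alpha, aux=f"p_{name}"
        )
        out[name] = {"fold": res.fold, "fold_reciprocal": fold_yx}
        rows.append({"aux": name, "stratum": "genome", **res.__dict__})
        if ann is not None and len(ann):
            strat = crosstrait.stratified_enrichment(joined, ann, cfg.alpha, aux=f"p_{name}")
            out[name]["fold_stratified"] = strat.fold
            rows.append({"aux": name, "stratum": ann.name, **strat.__dict__})
        if blocks is not None and len(blocks):
            rho = crosstrait.genomic_spearman(joined, blocks, exclusions, aux=f"p_{name}")
            out[name]["genomic_spearman"] = rho
        curves = crosstrait.conditional_qq(
            joined, cfg.qq_thresholds, aux=f"p_{name}"
        )
        crosstrait.qq_table(curves).to_csv(
            outdir / f"qq_{name}.tsv", sep="\t", index=False, float_format="%.17g"
        )
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.17g")
    return out


@_stage("cfdr")
def _cfdr_stage(cfg, joined, aux_names, ld, exclusions, outdir, target_col):
    if ld is None:
        raise ConfigError("cFDR model fitting requires LD input")
    surfaces = {}
    snp_tables = {}
    base = io.exclude_rows(joined, exclusions)
    for name in aux_names:
        surface = cfdr_mod.build_cfdr_surface(
            joined,
            ld,
            n_iter=cfg.n_iter,
            prune_r2=cfg.prune_r2,
            exclusions=exclusions,
            grid_step=cfg.grid_step,
            seed=cfg.seed,
            target=target_col,
            aux=f"p_{name}",
        )
        surface.write(outdir / f"cfdr_surface_{name}.tsv")
        snp = cfdr_mod.per_snp_cfdr(base, surface, target=target_col, aux=f"p_{name}")
        snp[["variant_id", "chrom", "pos", target_col, f"p_{name}", "cfdr"]].to_csv(
            outdir / f"cfdr_{name}.tsv", sep="\t", index=False, float_format="%.17g"
        )
        surfaces[name] = surface
        snp_tables[name] = snp
    uncond = base.copy()
    uncond["fdr"] = cfdr_mod.unconditioned_fdr(uncond[target_col].to_numpy())
    snp_tables["__unconditioned__"] = uncond
    uncond[["variant_id", "chrom", "pos", target_col, "fdr"]].to_csv(
        outdir / "fdr_unconditioned.tsv", sep="\t", index=False, float_format="%.17g"
    )
    return surfaces, snp_tables


@_stage("loci")
def _loci_stage(cfg, joined, aux_names, ld, exclusions, snp_tables, outdir, target_col):
    if ld is None:
        raise ConfigError("locus clumping requires LD input")
    out: dict[str, Any] = {}
    _tables_by_level: dict[float, list[pd.DataFrame]] = {}
    for level in cfg.cfdr_levels:
        per_analysis = {}
        tables = []
        for name in aux_names:
            tab = loci.clump(
                snp_tables[name],
                ld,
                clump_r2=cfg.clump_r2,
                merge_kb=cfg.merge_kb,
                threshold=level,
                value_col="cfdr",
                source=f"cfdr|{name}",
            )
            loci.write_locus_table(tab, outdir / f"loci_cfdr_{name}_{level}.tsv")
            per_analysis[name] = len(tab)
            tables.append(tab)
        uncond = loci.clump(
            snp_tables["__unconditioned__"],
            ld,
            clump_r2=cfg.clump_r2,
            merge_kb=cfg.merge_kb,
            threshold=level,
            value_col="fdr",
            source="unconditioned",
        )
        loci.write_locus_table(uncond, outdir / f"loci_unconditioned_{level}.tsv")
        merged = loci.merge_across(tables, merge_kb=cfg.merge_kb) if tables else loci._empty_table()
        loci.write_locus_table(merged, outdir / f"loci_merged_{level}.tsv")
        loci.loci_bed(merged).to_csv(
            outdir / f"loci_merged_{level}.bed", sep="\t", header=False, index=False
        )
        by_sources: dict[str, int] = {}
        for s in merged["sources"]:
            by_sources[s] = by_sources.get(s, 0) + 1
        out[str(level)] = {
            "per_analysis": per_analysis,
            "unconditioned": len(uncond),
            "merged": len(merged),
            "by_source_set": by_sources,
            "expected_false_discoveries": loci.expected_false_discoveries(tables, level),
        }
        _tables_by_level[level] = tables + [uncond, merged]
    return out


@_stage("truth_scoring")
def _truth_stage(cfg, truth, outdir):
    scores = {}
    for level in cfg.cfdr_levels:
        tabs = []
        for p in sorted(outdir.glob(f"loci_cfdr_*_{level}.tsv")):
            tabs.append(loci.read_locus_table(p))
        merged_path = outdir / f"loci_merged_{level}.tsv"
        entry = {}
        if merged_path.exists():
            merged = loci.read_locus_table(merged_path)
            sc = loci.score_against_truth(merged, truth)
            entry["merged"] = sc.__dict__
        uncond_path = outdir / f"loci_unconditioned_{level}.tsv"
        if uncond_path.exists():
            sc = loci.score_against_truth(loci.read_locus_table(uncond_path), truth)
            entry["unconditioned"] = sc.__dict__
        scores[str(level)] = entry
    return scores
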