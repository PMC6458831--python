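"""Seeded end-to-end orchestration: simulate -> design -> traits -> BLUEs
-> GWAS -> report.

Every stage draws from a named substream of one root seed, writes its
outputs as TSV into the run directory, and logs a checksum per file, so
reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import report as report_mod
from .config import PipelineConfig
from .design import generate_year
from .genmap import simulate_map
from .io import ensure_dir, write_table
from .phenosim import SimulationTruth, TraitArchitecture, simulate_experiment
from .population import simulate_population, draw_family_sizes
from .stage import (build_design_matrices, combine_years, cullis_h2,
                    extract_blues, fit_stage_one, reduce_model)
from .traits import derive_trait_table

log = logging.getLogger("namgwas")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, checksums: dict) -> None:
    write_table(df, path)
    checksums[path.name] = _checksum(path)
    log.info("wrote %s (%s rows, sha %s)", path.name, len(df), checksums[path.name])


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the whole pipeline into ``outdir``; returns the path."""
    out = ensure_dir(outdir)
    checksums: dict[str, str] = {}
    config.to_yaml(out / "config.yaml")

    sim = config.simulation
    gmap = simulate_map(sim.n_snps_per_chrom, sim.chrom_length_cM,
                        seed=stage_rng(config.seed, "map"))
    gmap.write_tsv(out / "map.tsv")
    checksums["map.tsv"] = _checksum(out / "map.tsv")

    if sim.family_size is not None:
        sizes = [sim.family_size] * sim.n_families
    else:
        sizes = draw_family_sizes(sim.n_families, sim.family_size_low,
                                  sim.family_size_high,
                                  seed=stage_rng(config.seed, "sizes"))
    pop = simulate_population(gmap, sizes, seed=stage_rng(config.seed, "pop"),
                              allow_any_family_count=sim.n_families != 25,
                              missing_rate=sim.missing_rate)
    pop.write_tsv(out / "genotypes.tsv")
    checksums["genotypes.tsv"] = _checksum(out / "genotypes.tsv")

    qtl = {}
    snp_ids = gmap.snp_ids
    for spec in sim.qtl:
        snp = snp_ids[int(spec["snp_index"])]
        qtl[snp] = spec["effect"]
    arch = TraitArchitecture(qtl=qtl, intercept=sim.intercept,
                             family_effect_sd=sim.family_effect_sd)
    truth = SimulationTruth.from_dict(
        {**{"architecture": {}, }, **sim.truth,
         "architecture": {"qtl": qtl, "intercept": sim.intercept,
                          "family_effect_sd": sim.family_effect_sd}})

    families = sorted({f for f in pop.family.unique()
                       if f.startswith("F")})
    year_families = [families[i::config.years] for i in range(config.years)]

    blues_frames = []
    h2_rows = []
    for yi in range(config.years):
        year = 2014 + yi
        fam_set = set(year_families[yi])
        lines = [ln for ln in pop.nam_lines() if pop.family[ln] in fam_set]
        layouts = generate_year(
            lines, seed=stage_rng(config.seed, f"design{year}"),
            zones=config.design.zones, lanes=config.design.lanes,
            positions=config.design.positions,
            n_check_mainplots_per_zone=config.design.n_check_mainplots_per_zone,
            **({"n_recurrent_mainplots": config.design.n_recurrent_mainplots}
               if config.design.n_recurrent_mainplots is not None else {}),
        )
        layout = pd.concat(layouts.values(), ignore_index=True)
        truth.year_effect = 4.0 * yi
        psa, harvest = simulate_experiment(
            pop, layout, truth, seed=stage_rng(config.seed, f"exp{year}"))
        harvest["year"] = year
        _write(layout, out / f"design_{year}.tsv", checksums)
        _write(psa, out / f"psa_{year}.tsv", checksums)
        _write(harvest, out / f"harvest_{year}.tsv", checksums)

        trait_table = derive_trait_table(psa, harvest,
                                         lam=config.smoothing.lam,
                                         df=config.smoothing.df)
        _write(trait_table, out / f"traits_{year}.tsv", checksums)

        include_zadoks = yi > 0  # developmental covariate absent in year 1
        for trait in config.traits:
            design = build_design_matrices(trait_table, trait,
                                           include_zadoks=include_zadoks)
            fit = reduce_model(fit_stage_one(design))
            blues = extract_blues(fit, year=year)
            blues["trait"] = trait
            blues_frames.append(blues)
            for trt in config.treatments:
                h2 = cullis_h2(trait_table, trait, trt)
                h2_rows.append({"trait": trait, "treatment": trt, "year": year,
                                "H2": h2.h2, "sigma2_g": h2.sigma2_g,
                                "vbar_delta": h2.vbar_delta})
    blues_all = pd.concat(blues_frames, ignore_index=True)
    _write(blues_all, out / "blues_stage1.tsv", checksums)
    _write(pd.DataFrame(h2_rows), out / "heritability.tsv", checksums)

    final_frames = []
    for trait in config.traits:
        for trt in config.treatments:
            sub = blues_all[blues_all["trait"] == trait]
            comb = combine_years(sub, trt)
            comb["trait"] = trait
            final_frames.append(comb)
    final_blues = pd.concat(final_frames, ignore_index=True)
    _write(final_blues, out / "blues_final.tsv", checksums)

    gcfg_seed = int(stage_rng(config.seed, "gwas").integers(0, 2**31 - 1))
    gcfg = gwas_mod.GwasConfig(
        maf_threshold=config.gwas.maf_threshold, alpha=config.gwas.alpha,
        folds=config.gwas.folds, repeats=config.gwas.repeats,
        detection_threshold=config.gwas.detection_threshold,
        window_cM=config.gwas.window_cM, seed=gcfg_seed)
    filtered = gwas_mod.maf_filter(pop, gcfg.maf_threshold)
    qtl_rows = []
    runlog_rows = []
    regions_by_trait_trt: dict[tuple, list] = {}
    mapt = gmap.table.set_index("snp_id")
    for trait in config.traits:
        for trt in config.treatments:
            sub = final_blues[(final_blues["trait"] == trait)
                              & (final_blues["treatment"] == trt)]
            y = sub.set_index("genotype")["blue"]
            scan = gwas_mod.cross_validated_scan(y, filtered, gmap, gcfg)
            put = scan.putative_qtl()
            for rec in scan.run_selections:
                runlog_rows.append({"trait": trait, "treatment": trt,
                                    "repeat": rec["repeat"], "fold": rec["fold"],
                                    "snps": ";".join(rec["snps"])})
            if len(put):
                total_r2, shares = gwas_mod.variance_explained(
                    y, filtered, list(put.index))
                effects = gwas_mod.estimate_parent_effects(
                    y, filtered, list(put.index))
                eff_wide = effects.pivot(index="snp_id", columns="family",
                                         values="effect")
                for snp, count in put.items():
                    row = {"trait": trait, "treatment": trt, "snp_id": snp,
                           "chromosome": mapt.at[snp, "chromosome"],
                           "position": float(mapt.at[snp, "position"]),
                           "detection_count": int(count),
                           "total_R2": total_r2,
                           "variance_explained": float(shares.get(snp, 0.0))}
                    if snp in eff_wide.index:
                        for fam in eff_wide.columns:
                            row[f"e{fam}"] = eff_wide.at[snp, fam]
                    qtl_rows.append(row)
                calls = pd.DataFrame([
                    {"snp_id": s, "chromosome": mapt.at[s, "chromosome"],
                     "position": float(mapt.at[s, "position"]),
                     "detection_count": int(c), "trait": trait,
                     "treatment": trt}
                    for s, c in put.items()])
                regions_by_trait_trt[(trait, trt)] = report_mod.group_qtl(
                    calls, config.report.group_window_cM)
            else:
                regions_by_trait_trt[(trait, trt)] = []
    qtl_frame = pd.DataFrame(
        qtl_rows, columns=None if qtl_rows else
        ["trait", "treatment", "snp_id", "chromosome", "position",
         "detection_count", "total_R2", "variance_explained"])
    _write(qtl_frame, out / "qtl.tsv", checksums)
    _write(pd.DataFrame(runlog_rows), out / "gwas_runs.tsv", checksums)

    class_frames = []
    for trait in config.traits:
        ctrl = regions_by_trait_trt.get((trait, "control"), [])
        drt = regions_by_trait_trt.get((trait, "drought"), [])
        cls = report_mod.classify_by_treatment(ctrl, drt,
                                               config.report.group_window_cM)
        cls["trait"] = trait
        class_frames.append(cls)
    _write(pd.concat(class_frames, ignore_index=True),
           out / "qtl_classification.tsv", checksums)
    regions_by_trait = {
        trait: [r for trt in config.treatments
                for r in regions_by_trait_trt.get((trait, trt), [])]
        for trait in config.traits}
    _write(report_mod.multi_trait_summary(regions_by_trait,
                                          config.report.group_window_cM),
           out / "multi_trait_regions.tsv", checksums)
    if config.report.gene_table:
        genes = pd.read_csv(config.report.gene_table, sep="\t")
        all_regions = [r for rs in regions_by_trait.values() for r in rs]
        _write(report_mod.match_candidates(all_regions, genes,
                                           config.report.match_window_cM),
               out / "candidate_genes.tsv", checksums)

    (out / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return out
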