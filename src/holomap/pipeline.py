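"""End-to-end orchestration: simulate -> layers -> SDMs -> overlay -> JSDM
-> networks -> traits, with a provenance manifest.

Each stage writes plain-text artifacts (NetCDF via the scipy engine, CSV,
JSON) into the configured output directory and registers them in a
manifest carrying the full configuration, the package version and the
per-stage seeds, so any run can be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import holomap
from holomap._util import stage_seed
from holomap.config import PipelineConfig
from holomap.diversity import mean_richness_by_host, rarefy, select_key_asvs
from holomap.env_layers import apply_study_mask
from holomap.grid import PRESENT
from holomap.jsdm import (augment_locations, build_jsdm_input, cross_validate,
                          explanatory_predictive_ratio, fit_jsdm,
                          optimal_temperature)
from holomap.networks import (biomass_network, build_network,
                              classify_connectivity, degree_fit_correlation,
                              export_edge_list, filter_biomass_species,
                              group_biomass, sparcc_correlations)
from holomap.overlay import cumulative_richness, temporal_change
from holomap.sdm import (add_pseudo_absences, binary_map, cross_validate_sdm,
                         grid_records, project)
from holomap.simulate import (default_microbiome, default_niches,
                              generate_asv_table, generate_biomass_table,
                              generate_env_grid, generate_host_occurrences)
from holomap.traits import fit_trait_rf, function_correlation, trait_presence

log = logging.getLogger(__name__)

STAGES = ("simulate", "layers", "sdm", "microbiome", "overlay", "jsdm",
          "networks", "traits")


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Stage dependencies are strict: every stage consumes in-memory results
    of earlier stages, so requesting a stage without its prerequisites
    raises a dependency error naming the missing stage.
    """
    stages = list(stages)
    order = [s for s in STAGES if s in stages]
    deps = {"layers": "simulate", "sdm": "layers", "microbiome": "simulate",
            "overlay": "sdm", "jsdm": "overlay", "networks": "jsdm",
            "traits": "sdm"}
    done = set()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "holomap", "version": holomap.__version__,
                "config": config.to_dict(), "stages": {}, "artifacts": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    ctx: dict = {}

    for stage in order:
        dep = deps.get(stage)
        if dep is not None and dep not in done:
            raise RuntimeError(f"stage {stage!r} requires stage {dep!r} "
                               "to run first")
        t0 = time.perf_counter()
        _STAGE_FN[stage](config, ctx, out_dir, manifest)
        manifest["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "seed": stage_seed(config.seed, _STAGE_SEED_NAME.get(stage, "cv")),
        }
        done.add(stage)
        log.info("stage %s done (%.1fs)", stage,
                 manifest["stages"][stage]["elapsed_s"])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest


_STAGE_SEED_NAME = {"simulate": "simulate", "layers": "env", "sdm": "sdm",
                    "microbiome": "rarefy", "overlay": "cv", "jsdm": "jsdm",
                    "networks": "sparcc", "traits": "traits"}


def _register(manifest, name, path):
    manifest["artifacts"][name] = str(path)


def _stage_simulate(config, ctx, out_dir, manifest):
    sim = config.sim
    ctx["grid_raw"] = generate_env_grid(sim)
    ctx["niches"] = default_niches(sim)
    ctx["records"] = generate_host_occurrences(ctx["grid_raw"], ctx["niches"],
                                               sim)
    ctx["truth"] = default_microbiome(sim)
    ctx["asv_table"] = generate_asv_table(ctx["records"], ctx["grid_raw"],
                                          ctx["truth"], sim)
    ctx["biomass"] = generate_biomass_table(sim)
    p = out_dir / "occurrences.csv"
    ctx["records"].to_csv(p, index=False)
    _register(manifest, "occurrences", p)
    ctx["asv_table"].to_files(out_dir / "asv_counts.tsv",
                              out_dir / "asv_metadata.csv")
    _register(manifest, "asv_counts", out_dir / "asv_counts.tsv")
    ctx["biomass"].to_csv(out_dir / "biomass.csv", index=False)
    _register(manifest, "biomass", out_dir / "biomass.csv")


def _stage_layers(config, ctx, out_dir, manifest):
    grid = apply_study_mask(ctx["grid_raw"], buffer_km=config.buffer_km,
                            max_depth_m=config.max_depth_m)
    ctx["grid"] = grid
    p = out_dir / "env_layers.nc"
    grid.to_netcdf(p)
    _register(manifest, "env_layers", p)


def _stage_sdm(config, ctx, out_dir, manifest):
    grid = ctx["grid"]
    gridded = grid_records(ctx["records"], grid)
    full = add_pseudo_absences(gridded)
    ctx["gridded"] = gridded
    ctx["sdm_records"] = full
    seed = stage_seed(config.seed, "sdm")
    results, surfaces = {}, {}
    for sp in full["species"].unique():
        sub = full[full["species"] == sp].reset_index(drop=True)
        res = cross_validate_sdm(sub, grid, PRESENT, k=config.cv_folds,
                                 n_trees=config.n_trees,
                                 block_size_cells=config.block_size_cells,
                                 seed=seed)
        results[sp] = res
        surfaces[sp] = {}
        for tf in grid.timeframes:
            mean, sd = project(res, grid, tf)
            surfaces[sp][tf] = {"prob": mean, "sd": sd,
                                "binary": binary_map(mean, res.threshold)}
    ctx["sdm_results"] = results
    ctx["sdm_surfaces"] = surfaces
    p = out_dir / "sdm_metrics.json"
    p.write_text(json.dumps({sp: r.metrics_json() for sp, r in
                             results.items()}, indent=2))
    _register(manifest, "sdm_metrics", p)


def _stage_microbiome(config, ctx, out_dir, manifest):
    rare = rarefy(ctx["asv_table"], config.rarefaction_depth,
                  seed=stage_seed(config.seed, "rarefy"))
    ctx["rarefied"] = rare
    ctx["richness"] = mean_richness_by_host(rare)
    focal = rare.restrict_host("V. pourtalesii")
    ctx["key_asvs"] = select_key_asvs(focal)
    p = out_dir / "richness_summary.csv"
    ctx["richness"].to_frame().to_csv(p)
    _register(manifest, "richness_summary", p)


def _stage_overlay(config, ctx, out_dir, manifest):
    grid = ctx["grid"]
    rich = ctx["richness"].mean_richness
    maps, changes = {}, {}
    for tf in grid.timeframes:
        binary = {sp: ctx["sdm_surfaces"][sp][tf]["binary"]
                  for sp in ctx["sdm_results"]}
        maps[tf] = cumulative_richness(binary, rich)
    for tf in grid.timeframes:
        if tf == PRESENT:
            continue
        ch = temporal_change(maps[tf], maps[PRESENT], lat=grid.lat,
                             cell_size=grid.cell_size)
        changes[tf] = {"n_gain": ch.n_gain, "n_loss": ch.n_loss,
                       "pct_gains": ch.pct_gains, "pct_losses": ch.pct_losses,
                       "shifted_area_km2": ch.shifted_area_km2}
    ctx["cumulative"] = maps
    p = out_dir / "richness_change.json"
    p.write_text(json.dumps(changes, indent=2))
    _register(manifest, "richness_change", p)


def _stage_jsdm(config, ctx, out_dir, manifest):
    grid = ctx["grid"]
    present = ctx["sdm_surfaces"]["V. pourtalesii"][PRESENT]["binary"]
    key = list(ctx["key_asvs"]["asv"])
    sampled = build_jsdm_input(ctx["rarefied"], key, grid, PRESENT)
    data = augment_locations(sampled, grid, PRESENT, present)
    seed = stage_seed(config.seed, "jsdm")
    fit = fit_jsdm(data, chains=config.jsdm_chains,
                   samples=config.jsdm_samples, warmup=config.jsdm_warmup,
                   seed=seed)
    pred_r2 = cross_validate(data, folds=2, seed=seed,
                             chains=config.jsdm_chains,
                             samples=max(config.jsdm_samples // 2, 100),
                             warmup=max(config.jsdm_warmup // 2, 100))
    ratios = explanatory_predictive_ratio(fit.explanatory_r2, pred_r2,
                                          list(fit.asvs))
    ctx["jsdm_fit"] = fit
    ctx["jsdm_ratios"] = ratios
    optima = {}
    for asv in fit.asvs[:2]:
        t_opt, interior = optimal_temperature(fit, asv, config.temp_window)
        optima[asv] = {"optimum_c": t_opt, "interior": interior}
    summary = {"psrf_mean": fit.psrf["mean"], "psrf_ci95": fit.psrf["ci95"],
               "tjur_mean": fit.tjur.get("mean"),
               "explanatory_r2": dict(zip(fit.asvs,
                                          map(float, fit.explanatory_r2))),
               "predictive_r2": dict(zip(fit.asvs, map(float, pred_r2))),
               "n_locations": int(data.n_locations), "optima": optima}
    p = out_dir / "jsdm_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    _register(manifest, "jsdm_summary", p)


def _stage_networks(config, ctx, out_dir, manifest):
    focal = ctx["rarefied"].restrict_host("V. pourtalesii")
    # drop ASVs absent from every sample to keep the system well-posed
    keep = focal.counts.sum(axis=0) > 0
    counts = focal.counts.loc[:, keep]
    corr = sparcc_correlations(counts.values,
                               n_rounds=config.sparcc_rounds,
                               exclusion_threshold=config.sparcc_exclusion_threshold,
                               seed=stage_seed(config.seed, "sparcc"))
    key = [a for a in ctx["key_asvs"]["asv"] if a in counts.columns]
    g = build_network(corr, list(counts.columns), key,
                      edge_threshold=config.edge_threshold)
    classes = classify_connectivity(g)
    ratios = ctx["jsdm_ratios"].set_index("asv")
    deg, fitm = [], []
    for asv in key:
        if asv in g and asv in ratios.index:
            deg.append(g.degree(asv))
            fitm.append(float(ratios.loc[asv, "explanatory_r2"]))
    r = p_val = float("nan")
    if len(deg) >= 3 and np.std(deg) > 0 and np.std(fitm) > 0:
        r, p_val = degree_fit_correlation(deg, fitm)
    export_edge_list(g, out_dir / "cooccurrence_edges.csv")
    _register(manifest, "cooccurrence_edges", out_dir / "cooccurrence_edges.csv")
    filtered = filter_biomass_species(ctx["biomass"])
    grouped = group_biomass(filtered)
    bg = biomass_network(grouped)
    export_edge_list(bg, out_dir / "biomass_edges.csv")
    _register(manifest, "biomass_edges", out_dir / "biomass_edges.csv")
    summary = {
        "classes": classes,
        "n_highly_interconnected": sum(1 for v in classes.values()
                                       if v == "highly interconnected"),
        "degree_fit_pearson_r": r, "degree_fit_p": p_val,
        "biomass_groups": int(grouped.shape[0]),
        "biomass_edges": int(bg.number_of_edges()),
    }
    p = out_dir / "network_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    _register(manifest, "network_summary", p)
    ctx["network_summary"] = summary


def _stage_traits(config, ctx, out_dir, manifest):
    # HMA/LMA assignment of the five synthetic sponge hosts is temperature-
    # structured: warm-niche species HMA, cold-niche species LMA.
    species = list(ctx["gridded"]["species"].unique())
    assignment = {sp: ("HMA" if i % 2 == 0 else "LMA")
                  for i, sp in enumerate(sorted(species))}
    records = trait_presence(ctx["gridded"], assignment)
    records = add_pseudo_absences(records)
    results = fit_trait_rf(records, ctx["grid"], PRESENT,
                           k=config.cv_folds, n_trees=config.n_trees,
                           block_size_cells=config.block_size_cells,
                           seed=stage_seed(config.seed, "traits"))
    out = {}
    for trait, res in results.items():
        prob, _sd = project(res, ctx["grid"], PRESENT)
        # synthetic stand-in function surface: smooth transform of depth
        func = np.sqrt(np.clip(ctx["grid"].layer("depth"), 0, None))
        rho, p_val = function_correlation(prob, func)
        out[trait] = {"auc_mean": res.auc_mean, "mss": res.threshold,
                      **res.metrics,
                      "function_spearman_rho": rho, "function_p": p_val}
    p = out_dir / "trait_summary.json"
    p.write_text(json.dumps(out, indent=2))
    _register(manifest, "trait_summary", p)
    ctx["trait_summary"] = out


_STAGE_FN = {
    "simulate": _stage_simulate,
    "layers": _stage_layers,
    "sdm": _stage_sdm,
    "microbiome": _stage_microbiome,
    "overlay": _stage_overlay,
    "jsdm": _stage_jsdm,
    "networks": _stage_networks,
    "traits": _stage_traits,
}
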