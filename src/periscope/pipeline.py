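"""End-to-end workflows binding the analysis stages together.

Two workflows mirror the two experimental readouts: the confocal/FISH
quantification (segment → layer → spots → distances → classify → summarize →
stats) and the STORM clustering (tessellate → CSR reference → thresholds →
segment). Both are pure functions of (inputs, config, seed): re-running with
an identical config reproduces every artifact bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import confocal, spots as spots_mod, stats as stats_mod, storm, synthetic
from .io import (RunConfig, read_localizations, read_stack,
                 write_csv_with_provenance, write_json_with_provenance,
                 write_localizations, write_stack)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _simulated_cells(config: RunConfig):
    sim = dict(config.simulate)
    n_cells = int(sim.pop("n_cells", 5))
    for i in range(n_cells):
        params = synthetic.NucleusParams(**sim, seed=config.seed + i)
        channels, truth = synthetic.generate_nucleus_image(params)
        yield f"cell{i:03d}", channels, truth


def _loaded_cells(config: RunConfig, base: Path):
    for cell in config.cells:
        cid = cell.get("id", "cell")
        channels = {}
        for key, val in cell.items():
            if key == "id":
                continue
            p = Path(val) if Path(val).is_absolute() else base / val
            channels[key] = read_stack(p)
        yield cid, channels, None


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 config_dir: str | Path = ".") -> dict[str, Path]:
    """Execute the configured workflow; returns the artifact paths."""
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    if config.workflow == "simulate":
        return _run_simulate(config, out, prov)
    if config.workflow in ("quantify", "spots"):
        return _run_confocal(config, out, prov, Path(config_dir))
    if config.workflow == "storm-cluster":
        return _run_storm(config, out, prov, Path(config_dir))
    if config.workflow == "stats":
        return _run_stats(config, out, prov, Path(config_dir))
    raise PipelineError("dispatch", f"unknown workflow {config.workflow}")


def _run_simulate(config: RunConfig, out: Path, prov: dict) -> dict[str, Path]:
    artifacts: dict[str, Path] = {}
    truths = []
    for cid, channels, truth in _simulated_cells(config):
        for name, grid in channels.items():
            artifacts[f"{cid}/{name}"] = write_stack(grid, out / cid / f"{name}.tif")
        truths.append({
            "cell_id": cid,
            "center_um": list(truth.center_um),
            "semi_axes_um": list(truth.semi_axes_um),
            "shell_thickness_um": truth.shell_thickness_um,
            "layer_thickness_um": truth.layer_thickness_um,
            "seed": truth.seed,
            "spots": [{"label": s.label, "center_um": list(s.center_um),
                       "signed_distance_um": s.signed_distance_um,
                       "peripheral": s.peripheral} for s in truth.spots],
        })
    artifacts["ground_truth"] = write_json_with_provenance(
        {"cells": truths}, out / "ground_truth.json", prov)
    return artifacts


def _analyze_cell(cid: str, channels: dict, config: RunConfig):
    """Single-cell confocal analysis; returns (spot calls, fraction rows, T)."""
    try:
        nucleus = confocal.segment_nucleus(channels["dna"])
    except Exception as exc:
        raise PipelineError(f"segment_nucleus[{cid}]", str(exc)) from exc

    if config.reference_surface == "dna-edge" or "lamina" not in channels:
        surface = spots_mod.dna_edge_surface(nucleus)
    else:
        try:
            surface = confocal.segment_lamina(channels["lamina"], nucleus)
        except Exception as exc:
            raise PipelineError(f"segment_lamina[{cid}]", str(exc)) from exc

    if config.layer.get("mode", "measured") == "measured" and "h3k9me2" in channels:
        try:
            layer = confocal.measure_layer_thickness(channels["h3k9me2"], surface)
        except confocal.SegmentationError:
            log.warning("cell %s: layer measurement failed; using configured T", cid)
            layer = confocal.PeripheryLayer(config.layer.get("thickness_um", 0.4), "configured")
    else:
        layer = confocal.PeripheryLayer(config.layer.get("thickness_um", 0.4), "configured")

    calls = []
    for ch_key, label in (("lad_fish", "LAD"), ("nonlad_fish", "nonLAD")):
        if ch_key not in channels:
            continue
        found = spots_mod.detect_spots(channels[ch_key], nucleus,
                                       config.spot_diameter_um, cell_id=cid, channel=label)
        found = spots_mod.spot_distances(found, surface)
        calls.extend(spots_mod.classify_spots(found, layer))

    fractions = []
    peri = confocal.periphery_mask(surface, layer, nucleus)
    for ch_key in ("h3k9me2", "signal"):
        if ch_key in channels:
            f = confocal.peripheral_fraction(channels[ch_key], peri, nucleus, cell_id=cid,
                                             background_subtract=config.background_subtract)
            fractions.append({"cell_id": cid, "channel": ch_key,
                              "mask": peri.provenance,
                              "masked_signal": f.masked_signal,
                              "total_signal": f.total_signal,
                              "fraction": f.fraction})
    return calls, fractions, layer


def _run_confocal(config: RunConfig, out: Path, prov: dict, base: Path) -> dict[str, Path]:
    cells = _loaded_cells(config, base) if config.cells else _simulated_cells(config)
    all_calls, all_fractions, thicknesses = [], [], []
    for cid, channels, _truth in cells:
        calls, fractions, layer = _analyze_cell(cid, channels, config)
        all_calls.extend(calls)
        all_fractions.extend(fractions)
        thicknesses.append({"cell_id": cid, "thickness_um": layer.thickness_T,
                            "method": layer.method})

    artifacts: dict[str, Path] = {}
    spot_df = pd.DataFrame([{
        "cell_id": s.cell_id, "channel": s.channel,
        "x_um": s.center_um[0], "y_um": s.center_um[1], "z_um": s.center_um[2],
        "d_um": s.signed_distance_um, "peripheral": s.peripheral,
    } for s in all_calls])
    artifacts["spots_csv"] = write_csv_with_provenance(spot_df, out / "spots.csv", prov)

    if all_fractions:
        artifacts["fractions_csv"] = write_csv_with_provenance(
            pd.DataFrame(all_fractions), out / "fractions.csv", prov)
    artifacts["layer_csv"] = write_csv_with_provenance(
        pd.DataFrame(thicknesses), out / "layer_thickness.csv", prov)

    if all_calls:
        cell_summaries, cohort = spots_mod.summarize_cells(
            all_calls, reference_surface=config.reference_surface)
        cell_df = pd.DataFrame([{
            "cell_id": c.cell_id,
            **{f"n_{ch}": c.n_spots.get(ch) for ch in cohort.pooled_distances_um},
            **{f"pct_peripheral_{ch}": c.percent_peripheral.get(ch)
               for ch in cohort.pooled_distances_um},
        } for c in cell_summaries])
        artifacts["cells_csv"] = write_csv_with_provenance(cell_df, out / "cells.csv", prov)
        cohort_json = {
            "reference_surface": cohort.reference_surface,
            "n_cells": cohort.n_cells,
            "mean_percent_peripheral": cohort.mean_percent_peripheral,
            "range_percent_peripheral": {k: list(v) for k, v in
                                         cohort.range_percent_peripheral.items()},
            "distance_percentiles_um": {k: {str(p): v for p, v in d.items()}
                                        for k, d in cohort.distance_percentiles.items()},
        }
        artifacts["cohort_json"] = write_json_with_provenance(
            cohort_json, out / "cohort.json", prov)

        channels_present = sorted({s.channel for s in all_calls})
        if len(channels_present) == 2:
            a, b = channels_present
            pa = [c.percent_peripheral[a] for c in cell_summaries if a in c.percent_peripheral]
            pb = [c.percent_peripheral[b] for c in cell_summaries if b in c.percent_peripheral]
            if len(pa) >= 2 and len(pb) >= 2:
                comp = stats_mod.mann_whitney(pa, pb, labels=(a, b))
                artifacts["stats_json"] = write_json_with_provenance({
                    "test": comp.test_name, "method": comp.method,
                    "statistic": comp.statistic, "p_value": comp.p_value,
                    "n_per_group": comp.n_per_group,
                    "stars": stats_mod.significance_stars(comp.p_value),
                }, out / "stats.json", prov)
    return artifacts


def _run_storm(config: RunConfig, out: Path, prov: dict, base: Path) -> dict[str, Path]:
    scfg = config.storm
    if scfg.get("csv"):
        p = Path(scfg["csv"])
        df = read_localizations(p if p.is_absolute() or p.exists() else base / p)
    else:  # fall back to a simulated table so the workflow is demonstrable
        params = synthetic.StormParams(seed=config.seed)
        df = synthetic.generate_storm_localizations(params)
    region = tuple(scfg["region"]) if scfg.get("region") else None
    locs = storm.LocalizationTable.from_dataframe(df, region=region)

    tess = storm.voronoi_areas(locs)
    reps = int(scfg.get("reps", 100))
    max_levels = int(scfg.get("max_levels", 4))
    seed = int(scfg.get("seed", config.seed))
    ref, _delta = storm.mc_reference(locs.n, locs.region, reps=reps, seed=seed)
    thresholds = storm.compute_thresholds(tess, ref, max_levels=max_levels,
                                          mc_reps=reps, seed=seed)
    result = storm.segment_localizations(tess, thresholds)

    artifacts: dict[str, Path] = {}
    loc_df = pd.DataFrame({
        "x_nm": tess.points_nm[:, 0], "y_nm": tess.points_nm[:, 1],
        "area_nm2": tess.areas_nm2, "boundary": tess.boundary_flag,
        "level": result.levels,
    })
    artifacts["localizations_csv"] = write_csv_with_provenance(
        loc_df, out / "localizations.csv", prov)
    clus_df = pd.DataFrame([{
        "level": c.level, "cluster": i, "n": c.n, "area_nm2": c.area_nm2,
    } for lvl, cl in result.clusters.items() for i, c in enumerate(cl)])
    artifacts["clusters_csv"] = write_csv_with_provenance(
        clus_df, out / "clusters.csv", prov)
    artifacts["thresholds_json"] = write_json_with_provenance({
        "thresholds_nm2": thresholds.thresholds_nm2,
        "delta_nm2": thresholds.delta_nm2,
        "uniform_flag": thresholds.uniform_flag,
        "mc_reps": thresholds.mc_reps,
        "n": locs.n,
    }, out / "thresholds.json", prov)
    return artifacts


def _run_stats(config: RunConfig, out: Path, prov: dict, base: Path) -> dict[str, Path]:
    scfg = config.stats
    if not scfg.get("csv"):
        raise PipelineError("stats", "stats workflow needs stats.csv (condition,cell_id,value)")
    p = Path(scfg["csv"])
    df = pd.read_csv(p if p.is_absolute() or p.exists() else base / p)
    groups = {k: g["value"].to_numpy() for k, g in df.groupby("condition")}
    reference = scfg.get("reference")
    if len(groups) == 2:
        a, b = sorted(groups)
        comp = stats_mod.mann_whitney(groups[a], groups[b], labels=(a, b))
    else:
        comp = stats_mod.kruskal_dunn(groups, reference=reference)
    report = {
        "test": comp.test_name, "method": comp.method,
        "statistic": comp.statistic, "p_value": comp.p_value,
        "stars": stats_mod.significance_stars(comp.p_value),
        "n_per_group": comp.n_per_group,
        "contrasts": [{
            "a": c.group_a, "b": c.group_b, "z": c.statistic,
            "p": c.p_value, "p_adj": c.p_adjusted,
        } for c in comp.contrasts],
    }
    return {"stats_json": write_json_with_provenance(report, out / "stats.json", prov)}
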