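"""High-level pipeline steps shared by the Python API and the CLI."""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats, extraction, hemodynamics, io, polarity
from .graph import VesselGraph
from .io import AnalysisConfig
from .synthetic import SyntheticScene

log = logging.getLogger("vesselpol")


def save_scene(scene: SyntheticScene, outdir) -> dict[str, Path]:
    """Serialize a synthetic scene: mask TIFF, cells CSV, graph JSON, params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": outdir / "mask.tif",
        "cells": outdir / "cells.csv",
        "graph": outdir / "graph.json",
        "params": outdir / "params.json",
        "flow_edges": outdir / "flow_edges.csv",
        "flow_nodes": outdir / "flow_nodes.csv",
    }
    io.write_mask(scene.mask, paths["mask"])
    scene.cells.to_csv(paths["cells"], index=False, float_format="%.9g")
    io.write_graph(scene.graph, paths["graph"])
    io.write_report(scene.params_dict(), paths["params"])
    edges, nodes = io.flow_to_frames(scene.flow)
    edges.to_csv(paths["flow_edges"], index=False, float_format="%.9g")
    nodes.to_csv(paths["flow_nodes"], index=False, float_format="%.9g")
    return paths


def extract_stage(mask: np.ndarray, config: AnalysisConfig):
    """Mask -> pruned graph + morphometrics."""
    graph, meta = extraction.extract_network(mask, config.pixel_size_um)
    area_mm2 = mask.size * (config.pixel_size_um * 1e-3) ** 2
    morpho = extraction.Morphometrics(
        vessel_area_fraction=extraction.vessel_area_fraction(mask),
        branchpoint_density_per_mm2=extraction.branchpoint_density(graph, area_mm2),
    )
    return graph, morpho, meta


def flow_stage(graph: VesselGraph, config: AnalysisConfig):
    return hemodynamics.solve_flow(
        graph,
        viscosity_pa_s=config.viscosity_pa_s,
        inlet_pressure_pa=config.inlet_pressure_pa,
        viscosity_model=config.viscosity_model,
        hematocrit=config.hematocrit,
    )


def polarity_stage(cells: pd.DataFrame, graph: VesselGraph, flow,
                   config: AnalysisConfig):
    return polarity.build_polarity_dataset(
        cells, graph, flow, max_dist_um=config.max_sampling_dist_um)


def _bin_edges(records: pd.DataFrame, config: AnalysisConfig) -> np.ndarray:
    if config.bin_scheme == "fixed":
        if not config.fixed_bin_edges_pa:
            raise ValueError("bin_scheme 'fixed' needs fixed_bin_edges_pa")
        return np.asarray(config.fixed_bin_edges_pa, dtype=float)
    return circstats.decile_bin_edges(
        records.loc[records["flow_found"], "wss_pa"], config.n_bins)


def stats_stage(records: pd.DataFrame, config: AnalysisConfig,
                reference_uniform: bool = True) -> dict:
    """Full statistics report from a per-cell record table.

    Per-bed circular summaries and Kuiper tests against a uniform reference,
    the WSS-binned anti-aligned fraction with the threshold-crossing shear,
    and the sign-split scalar-product regression.
    """
    matched = records[records["flow_found"]].copy()
    if len(matched) == 0:
        raise ValueError(
            "no cells matched a vessel within max_sampling_dist_um="
            f"{config.max_sampling_dist_um}; increase it or check units")
    rng = np.random.default_rng(config.seed)
    report: dict = {"n_records": int(len(records)),
                    "n_flow_matched": int(len(matched))}

    beds = {}
    for bed, sub in matched.groupby("bed"):
        entry: dict = {"n": int(len(sub))}
        if len(sub) >= 2:
            summ = circstats.circular_mean_ci(sub["angle_deg"].to_numpy())
            entry["angular_summary"] = asdict(summ)
            entry["antialigned_fraction"] = circstats.antialigned_fraction(
                sub["angle_deg"].to_numpy(), config.window_deg)
            if reference_uniform and len(sub) >= 5:
                ref = rng.uniform(0.0, 360.0, size=max(len(sub), 500))
                v, p = circstats.kuiper_two_sample(
                    sub["angle_deg"].to_numpy(), ref,
                    n_perm=config.n_perm,
                    seed=int(rng.integers(2 ** 31)),
                    method=config.kuiper_method)
                entry["kuiper_vs_uniform"] = {"V": v, "p": p}
        beds[bed] = entry
    report["per_bed"] = beds

    edges = _bin_edges(records, config)
    binned = circstats.bin_by_wss(matched["wss_pa"], matched["angle_deg"],
                                  edges, config.window_deg)
    report["binned_polarization"] = {
        "bin_edges_pa": binned.bin_edges,
        "n_cells": binned.n_cells,
        "fraction_antialigned": binned.fraction_antialigned,
        "ci_low": binned.ci_low,
        "ci_high": binned.ci_high,
        "window_deg": binned.window_deg,
        "n_excluded": binned.n_excluded,
    }
    thr = circstats.polarization_threshold_shear(binned, 0.5)
    report["threshold_shear_pa_at_fraction_0.5"] = thr

    pos, neg = circstats.scalar_product_regression(matched)
    report["scalar_regression"] = {"positive": asdict(pos),
                                   "negative": asdict(neg)}
    report["rose_histogram"] = {
        bed: circstats.angle_histogram(sub["angle_deg"].to_numpy()).to_dict("list")
        for bed, sub in matched.groupby("bed") if len(sub) > 0
    }
    return report


def run_all(mask: np.ndarray, cells: pd.DataFrame,
            config: AnalysisConfig) -> dict:
    """mask + cells -> graph -> flow -> records -> statistics report."""
    graph, morpho, extract_meta = extract_stage(mask, config)
    flow = flow_stage(graph, config)
    records, polarity_report = polarity_stage(cells, graph, flow, config)
    stats = stats_stage(records, config)
    return {
        "provenance": io.provenance_block(config),
        "morphometrics": asdict(morpho),
        "extraction": extract_meta,
        "flow": {
            "n_edges": len(flow.edge_flow),
            "conservation_residual": hemodynamics.conservation_residual(
                graph, flow),
            **flow.metadata,
        },
        "polarity": polarity_report,
        "statistics": stats,
        "_records": records,
        "_graph": graph,
    }
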