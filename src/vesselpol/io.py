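"""File formats, configuration and report writing.

Masks travel as single-channel TIFF/PNG (nonzero = foreground, written as
0/255 8-bit); cell tables and per-cell records as CSV; graphs as a JSON
schema (nodes with positions, edges with polylines and per-point radii) or
GraphML with JSON-encoded geometry; analysis reports as JSON with an
embedded provenance block so a run can be reproduced from the report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import Edge, VesselGraph

log = logging.getLogger("vesselpol")

GRAPH_SCHEMA_VERSION = 1
CELL_COLUMNS = ["nucleus_x_um", "nucleus_y_um", "golgi_x_um", "golgi_y_um"]


@dataclass
class AnalysisConfig:
    """Pipeline configuration; CLI flags override file values."""

    pixel_size_um: float = 1.0
    viscosity_pa_s: float = 3.5e-3
    viscosity_model: str = "constant"  # or "pries"
    hematocrit: float = 0.45
    inlet_pressure_pa: float = 2000.0
    outlet_pressure_pa: float = 0.0
    max_sampling_dist_um: float = 20.0
    window_deg: float = 45.0
    bin_scheme: str = "decile"  # or "fixed"
    n_bins: int = 10
    fixed_bin_edges_pa: list | None = None
    n_perm: int = 9999
    kuiper_method: str = "permutation"
    seed: int = 0
    schema_version: int = 1

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("physical quantities must be positive")
        if not 0.0 < self.window_deg < 180.0:
            raise ValueError("window_deg must be in (0, 180)")
        if self.max_sampling_dist_um <= 0:
            raise ValueError("max_sampling_dist_um must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_mask(path) -> np.ndarray:
    """Read a mask image and binarize it (nonzero -> foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        img = tifffile.imread(path)
    else:
        from PIL import Image
        img = np.asarray(Image.open(path))
    if img.ndim == 3:
        img = img[..., 0]
    values = np.unique(img)
    if values.size > 2:
        log.warning("mask %s has %d distinct values; binarizing nonzero",
                    path, values.size)
    return img != 0


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    img = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, img)
    else:
        from PIL import Image
        Image.fromarray(img).save(path)


def read_cells(path) -> pd.DataFrame:
    """Read a nucleus/Golgi CSV, verifying the required columns exist."""
    cells = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cells file {path} missing column(s): {missing}")
    return cells


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def graph_to_dict(graph: VesselGraph) -> dict:
    return {
        "schema_version": GRAPH_SCHEMA_VERSION,
        "nodes": [{"id": int(n), "x_um": float(p[0]), "y_um": float(p[1])}
                  for n, p in sorted(graph.nodes.items())],
        "edges": [{
            "id": int(e.id), "node_a": int(e.node_a), "node_b": int(e.node_b),
            "polyline": np.round(e.polyline, 6).tolist(),
            "radii_um": np.round(e.radii_um, 6).tolist(),
            "bed": e.bed,
        } for _, e in sorted(graph.edges.items())],
    }


def graph_from_dict(data: dict) -> VesselGraph:
    version = data.get("schema_version")
    if version != GRAPH_SCHEMA_VERSION:
        raise ValueError(f"unknown graph schema version: {version!r}")
    g = VesselGraph()
    for nd in data["nodes"]:
        g.add_node(int(nd["id"]), (float(nd["x_um"]), float(nd["y_um"])))
    for ed in data["edges"]:
        g.add_edge(Edge(int(ed["id"]), int(ed["node_a"]), int(ed["node_b"]),
                        np.asarray(ed["polyline"], dtype=float),
                        np.asarray(ed["radii_um"], dtype=float),
                        bed=ed.get("bed", "unassigned")))
    return g


def write_graph(graph: VesselGraph, path) -> None:
    """Write a graph as JSON (``.json``) or GraphML (``.graphml``)."""
    path = Path(path)
    data = graph_to_dict(graph)
    if path.suffix == ".graphml":
        import networkx as nx
        g = nx.MultiGraph(schema_version=str(GRAPH_SCHEMA_VERSION))
        for nd in data["nodes"]:
            g.add_node(nd["id"], x_um=nd["x_um"], y_um=nd["y_um"])
        for ed in data["edges"]:
            g.add_edge(ed["node_a"], ed["node_b"], key=ed["id"],
                       edge_id=ed["id"], bed=ed["bed"],
                       polyline=json.dumps(ed["polyline"]),
                       radii_um=json.dumps(ed["radii_um"]))
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            json.dump(data, fh)


def read_graph(path) -> VesselGraph:
    path = Path(path)
    if path.suffix == ".graphml":
        import networkx as nx
        g = nx.read_graphml(path, node_type=int)
        version = int(g.graph.get("schema_version", -1))
        data = {
            "schema_version": version,
            "nodes": [{"id": n, "x_um": d["x_um"], "y_um": d["y_um"]}
                      for n, d in g.nodes(data=True)],
            "edges": [{"id": int(d["edge_id"]), "node_a": u, "node_b": v,
                       "polyline": json.loads(d["polyline"]),
                       "radii_um": json.loads(d["radii_um"]),
                       "bed": d.get("bed", "unassigned")}
                      for u, v, d in g.edges(data=True)],
        }
        return graph_from_dict(data)
    with open(path) as fh:
        return graph_from_dict(json.load(fh))


def flow_to_frames(flow) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-edge and per-node tables of a flow solution for CSV export."""
    edges = pd.DataFrame({
        "edge_id": sorted(flow.edge_flow),
        "flow_um3_s": [flow.edge_flow[i] for i in sorted(flow.edge_flow)],
        "wss_pa": [flow.edge_wss[i] for i in sorted(flow.edge_wss)],
        "direction_reversed": [flow.edge_flow[i] < 0
                               for i in sorted(flow.edge_flow)],
    })
    nodes = pd.DataFrame({
        "node_id": sorted(flow.node_pressure),
        "pressure_pa": [flow.node_pressure[i]
                        for i in sorted(flow.node_pressure)],
    })
    return edges, nodes


def provenance_block(config: AnalysisConfig, seeds: dict | None = None) -> dict:
    from . import __version__
    return {
        "package": "vesselpol",
        "version": __version__,
        "config": asdict(config),
        "seeds": seeds or {"seed": config.seed},
        "flow_solver": "1D Poiseuille/Kirchhoff network "
                       "(substitution for 3D CFD; per-segment mean WSS only)",
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
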