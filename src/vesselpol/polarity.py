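"""Per-cell polarity records: nucleus-Golgi vectors joined to local flow.

The axial polarity of an endothelial cell is the vector from the centre of
its nucleus to the centre of its Golgi apparatus, a proxy for the direction
the cell is about to migrate. Each cell is matched to the nearest vessel
centreline point, where the flow solution supplies a wall-shear-stress
magnitude and a flow-oriented tangent; the record then carries the
counter-clockwise angle from flow to polarity (180° = polarized against
flow) and the scalar product |p|·τ·cos(angle), whose sign separates cells
polarized with (+) and against (−) the flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import VesselGraph, nearest_centreline_points
from .hemodynamics import FlowSolution

RECORD_COLUMNS = [
    "nucleus_x_um", "nucleus_y_um", "golgi_x_um", "golgi_y_um",
    "polarity_len_um", "wss_pa", "angle_deg", "scalar_product", "bed",
    "flow_found",
]


@dataclass
class CellRecord:
    """One endothelial cell with its polarity and (optional) flow context."""

    nucleus: np.ndarray
    golgi: np.ndarray
    polarity_vec: np.ndarray
    polarity_len: float
    wss_pa: float | None = None
    flow_dir: np.ndarray | None = None
    angle_to_flow_deg: float | None = None
    scalar_product: float | None = None
    bed: str = "unassigned"


class MalformedCellTable(ValueError):
    """Raised when a cell table has no usable rows; carries per-row problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("no valid cell rows: " + "; ".join(problems[:10]))


def axial_polarity_vector(nucleus, golgi):
    """Golgi − nucleus vector and its magnitude (µm)."""
    nucleus = np.asarray(nucleus, dtype=float)
    golgi = np.asarray(golgi, dtype=float)
    vec = golgi - nucleus
    mag = float(np.linalg.norm(vec))
    if mag == 0.0:
        raise ValueError("degenerate cell: nucleus and Golgi coincide")
    return vec, mag


def angle_to_flow(polarity_vec, flow_dir) -> float:
    """CCW angle (degrees, [0, 360)) from the flow direction to the polarity.

    0° means polarized with the flow, 180° against it.
    """
    p = np.asarray(polarity_vec, dtype=float)
    f = np.asarray(flow_dir, dtype=float)
    if np.linalg.norm(p) == 0 or np.linalg.norm(f) == 0:
        raise ValueError("zero vector has no direction")
    cross = f[0] * p[1] - f[1] * p[0]
    ang = math.degrees(math.atan2(cross, float(np.dot(f, p))))
    return ang % 360.0


def cell_scalar_product(polarity_len: float, wss_pa: float,
                        angle_deg: float) -> float:
    """|p| · τ · cos(angle): negative when polarized against the flow."""
    return polarity_len * wss_pa * math.cos(math.radians(angle_deg))


def assign_vascular_bed(nucleus, graph: VesselGraph,
                        max_dist_um: float = 20.0) -> str:
    """Bed label of the nearest edge within ``max_dist_um``, else unassigned."""
    res = nearest_centreline_points(graph, np.asarray(nucleus, dtype=float))
    if res["distance"][0] > max_dist_um:
        return "unassigned"
    return graph.edges[int(res["edge_id"][0])].bed


def _validate_cells(cells: pd.DataFrame):
    required = ["nucleus_x_um", "nucleus_y_um", "golgi_x_um", "golgi_y_um"]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise MalformedCellTable([f"missing column(s) {missing}"])
    problems = []
    coords = cells[required].apply(pd.to_numeric, errors="coerce")
    bad_numeric = coords.isna().any(axis=1)
    for i in np.nonzero(bad_numeric.to_numpy())[0]:
        problems.append(f"row {i}: non-numeric coordinate")
    nuc = coords[["nucleus_x_um", "nucleus_y_um"]].to_numpy(dtype=float)
    gol = coords[["golgi_x_um", "golgi_y_um"]].to_numpy(dtype=float)
    degenerate = (np.linalg.norm(gol - nuc, axis=1) == 0) & ~bad_numeric.to_numpy()
    for i in np.nonzero(degenerate)[0]:
        problems.append(f"row {i}: nucleus and Golgi coincide")
    valid = ~(bad_numeric.to_numpy() | degenerate)
    return nuc, gol, valid, problems


def build_polarity_dataset(cells: pd.DataFrame, graph: VesselGraph,
                           flow: FlowSolution, max_dist_um: float = 20.0,
                           ) -> tuple[pd.DataFrame, dict]:
    """Join a nucleus/Golgi table to the flow field.

    Returns ``(records, report)`` where ``records`` has one row per valid
    input row (order preserved) and ``report`` counts dropped and
    flow-unmatched cells. Cells farther than ``max_dist_um`` from any vessel
    keep their polarity fields but have missing (NaN) flow fields and
    ``flow_found = False`` — excluded from angle statistics, never silently.
    """
    if len(cells) == 0:
        raise MalformedCellTable(["empty cell table"])
    nuc, gol, valid, problems = _validate_cells(cells)
    if not valid.any():
        raise MalformedCellTable(problems or ["empty cell table"])
    nuc, gol = nuc[valid], gol[valid]
    vecs = gol - nuc
    plen = np.linalg.norm(vecs, axis=1)

    near = nearest_centreline_points(graph, nuc)
    n = len(nuc)
    wss = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    sprod = np.full(n, np.nan)
    beds = np.array(["unassigned"] * n, dtype=object)
    found = near["distance"] <= max_dist_um
    for i in np.nonzero(found)[0]:
        eid = int(near["edge_id"][i])
        s = float(near["arc_s"][i])
        e = graph.edges[eid]
        mu = flow.edge_viscosity.get(eid, flow.viscosity_pa_s)
        q = flow.edge_flow[eid]
        r = e.radius_at(s)
        tau = 4.0 * mu * abs(q) / (np.pi * r ** 3)
        direction = e.tangent_at(s) * flow.flow_sign(eid)
        wss[i] = tau
        angle[i] = angle_to_flow(vecs[i], direction)
        sprod[i] = cell_scalar_product(plen[i], tau, angle[i])
        beds[i] = e.bed

    records = pd.DataFrame({
        "nucleus_x_um": nuc[:, 0], "nucleus_y_um": nuc[:, 1],
        "golgi_x_um": gol[:, 0], "golgi_y_um": gol[:, 1],
        "polarity_len_um": plen,
        "wss_pa": wss,
        "angle_deg": angle,
        "scalar_product": sprod,
        "bed": beds,
        "flow_found": found,
    })
    report = {
        "n_input": int(len(cells)),
        "n_valid": int(n),
        "n_dropped": int(len(cells) - n),
        "n_flow_matched": int(found.sum()),
        "n_flow_unmatched": int((~found).sum()),
        "problems": problems,
        "max_dist_um": float(max_dist_um),
    }
    return records, report
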