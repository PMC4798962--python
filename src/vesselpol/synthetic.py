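"""Synthetic retinal-style plexus with a known shear-threshold polarity response.

The generator builds the ground truth every downstream stage is tested
against: an artery trunk and a vein trunk bridged by a jittered capillary
lattice with blind-ended sprouts on the distal margin, the rasterized lumen
mask, a solved flow field, and endothelial cells whose nucleus-to-Golgi
orientation is drawn from a von Mises distribution centred anti-parallel to
the local flow, with concentration rising sigmoidally with wall shear stress
around a threshold. Because the generating threshold, slope and concentration
ceiling are recorded in the scene, parameter-recovery and null-calibration
tests have exact expected answers.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .graph import Edge, VesselGraph
from .hemodynamics import (
    DEFAULT_VISCOSITY_PA_S,
    FlowSolution,
    default_boundaries,
    solve_flow,
)

_POLYLINE_STEP_UM = 5.0  # centreline sampling interval for generated edges


@dataclass(frozen=True)
class PlexusParams:
    """Geometry of the synthetic plexus (all lengths in µm)."""

    domain_size: tuple[float, float] = (600.0, 600.0)
    pixel_size: float = 1.0
    artery_radius: float = 12.0
    vein_radius: float = 15.0
    capillary_radius_mean: float = 3.5
    capillary_radius_sd: float = 0.5
    mesh_spacing: float = 60.0
    edge_dropout_prob: float = 0.15
    n_sprouts: int = 8
    jitter_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.artery_radius, self.vein_radius,
               self.capillary_radius_mean) <= 0:
            raise ValueError("all radii must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.edge_dropout_prob < 1.0:
            raise ValueError("edge_dropout_prob must be in [0, 1)")
        if self.mesh_spacing <= 0:
            raise ValueError("mesh_spacing must be positive")


@dataclass(frozen=True)
class PolarityResponseParams:
    """Shear-threshold polarity response and cell placement parameters.

    ``tau0`` is the wall-shear threshold (Pa) at which the von Mises
    concentration reaches half its ceiling ``kappa_max``; ``slope_s`` (Pa)
    sets the width of the sigmoidal transition. Nucleus-Golgi distances are
    log-normal with the given mean/sd (µm); ``cells_per_100um`` is the linear
    nucleus density along centrelines.
    """

    tau0: float = 5.0
    slope_s: float = 1.0
    kappa_max: float = 4.0
    polarity_len_mean: float = 7.0
    polarity_len_sd: float = 2.0
    cells_per_100um: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.tau0 < 0:
            raise ValueError("tau0 must be >= 0")
        if self.slope_s <= 0:
            raise ValueError("slope_s must be positive")
        if self.kappa_max < 0:
            raise ValueError("kappa_max must be >= 0")
        if self.polarity_len_mean <= 0:
            raise ValueError("polarity_len_mean must be positive")


@dataclass
class SyntheticScene:
    """Ground-truth bundle: graph, mask, flow, cells, generating parameters."""

    graph: VesselGraph
    mask: np.ndarray
    flow: FlowSolution
    cells: "object"  # pandas.DataFrame, typed loosely to keep imports light
    plexus_params: PlexusParams
    response_params: PolarityResponseParams
    hemo_config: dict = field(default_factory=dict)

    def params_dict(self) -> dict:
        return {
            "plexus": asdict(self.plexus_params),
            "response": asdict(self.response_params),
            "hemodynamics": dict(self.hemo_config),
        }


def lattice_shape(params: PlexusParams) -> tuple[int, int]:
    """(columns, rows) of the capillary lattice implied by the geometry.

    The trunks sit one mesh spacing in from the left/right borders; lattice
    columns fill the span between them and rows fill the vertical extent with
    a one-spacing margin top and bottom.
    """
    w, h = params.domain_size
    span = w - 2.0 * params.mesh_spacing
    n_cols = max(1, int(round(span / params.mesh_spacing)) - 1)
    n_rows = max(2, int(round((h - 2.0 * params.mesh_spacing)
                              / params.mesh_spacing)) + 1)
    return n_cols, n_rows


def lattice_counts(n_cols: int, n_rows: int) -> tuple[int, int]:
    """Closed-form node and edge counts of the intact lattice-plus-trunks.

    Nodes: a·b lattice nodes plus, per trunk, b row-attachment junctions and
    2 free ends. Edges: b·(a+1) horizontals (including trunk connections),
    a·(b-1) verticals, and b+1 trunk pieces per trunk.
    """
    a, b = n_cols, n_rows
    nodes = a * b + 2 * (b + 2)
    edges = b * (a + 1) + a * (b - 1) + 2 * (b + 1)
    return nodes, edges


def _polyline(p0: np.ndarray, p1: np.ndarray, radius: float):
    """Straight segment sampled every ~_POLYLINE_STEP_UM with constant radius."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(math.ceil(length / _POLYLINE_STEP_UM)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0[None, :] * (1 - t) + p1[None, :] * t
    return pts, np.full(n, radius)


def _build_candidate(params: PlexusParams, rng: np.random.Generator) -> VesselGraph:
    w, h = params.domain_size
    n_cols, n_rows = lattice_shape(params)
    margin = params.mesh_spacing
    x_a, x_v = margin, w - margin
    dx = (x_v - x_a) / (n_cols + 1)
    ys = np.linspace(margin, h - margin, n_rows)
    trunk_overhang = margin

    g = VesselGraph()
    next_node = 0

    def new_node(pos):
        nonlocal next_node
        nid = g.add_node(next_node, pos)
        next_node += 1
        return nid

    # trunk nodes: free end below, one junction per row, free end above
    def trunk_nodes(x):
        ids = [new_node((x, ys[0] - trunk_overhang))]
        ids += [new_node((x, y)) for y in ys]
        ids.append(new_node((x, ys[-1] + trunk_overhang)))
        return ids

    artery_ids = trunk_nodes(x_a)
    vein_ids = trunk_nodes(x_v)

    # lattice nodes, jittered; grid[(col, row)] -> node id
    grid = {}
    for c in range(n_cols):
        for r in range(n_rows):
            base = np.array([x_a + (c + 1) * dx, ys[r]])
            pos = base + rng.normal(0.0, params.jitter_sd, size=2)
            grid[(c, r)] = new_node(pos)

    next_edge = 0
    droppable = []  # interior capillary edge ids eligible for dropout

    def add_edge(na, nb, radius, bed, can_drop=False):
        nonlocal next_edge
        pts, radii = _polyline(g.nodes[na], g.nodes[nb], radius)
        eid = next_edge
        g.add_edge(Edge(eid, na, nb, pts, radii, bed=bed))
        next_edge += 1
        if can_drop:
            droppable.append(eid)
        return eid

    def cap_radius():
        r = rng.normal(params.capillary_radius_mean, params.capillary_radius_sd)
        return max(r, 0.3 * params.capillary_radius_mean)

    for ids, radius, bed in ((artery_ids, params.artery_radius, "artery"),
                             (vein_ids, params.vein_radius, "vein")):
        for u, v in zip(ids[:-1], ids[1:]):
            add_edge(u, v, radius, bed)

    for r in range(n_rows):
        add_edge(artery_ids[r + 1], grid[(0, r)], cap_radius(), "capillary")
        add_edge(grid[(n_cols - 1, r)], vein_ids[r + 1], cap_radius(), "capillary")
        for c in range(n_cols - 1):
            add_edge(grid[(c, r)], grid[(c + 1, r)], cap_radius(), "capillary",
                     can_drop=True)
    for c in range(n_cols):
        for r in range(n_rows - 1):
            add_edge(grid[(c, r)], grid[(c, r + 1)], cap_radius(), "capillary",
                     can_drop=True)

    # blind-ended sprouts growing from the distal (top) margin
    top_nodes = [grid[(c, n_rows - 1)] for c in range(n_cols)]
    chosen = rng.choice(len(top_nodes), size=min(params.n_sprouts, len(top_nodes)),
                        replace=False) if params.n_sprouts else []
    for c in np.sort(np.asarray(chosen, dtype=int)):
        base = g.nodes[top_nodes[c]]
        tip = base + np.array([rng.normal(0.0, 0.15 * params.mesh_spacing),
                               0.8 * params.mesh_spacing
                               + rng.normal(0.0, 0.1 * params.mesh_spacing)])
        tip_id = new_node(tip)
        add_edge(top_nodes[c], tip_id, cap_radius(), "sprouting_front")

    # dropout of interior lattice edges
    if params.edge_dropout_prob > 0 and droppable:
        drop = rng.random(len(droppable)) < params.edge_dropout_prob
        for eid, d in zip(droppable, drop):
            if d:
                del g.edges[eid]

    return _largest_perfused_subgraph(g, artery_ids[0], vein_ids[0])


def _largest_perfused_subgraph(g: VesselGraph, artery_root: int, vein_root: int):
    """Keep the component containing both trunks; None if they are split."""
    nxg = g.to_networkx()
    import networkx as nx
    comp = nx.node_connected_component(nxg, artery_root)
    if vein_root not in comp:
        return None
    out = VesselGraph()
    for n in comp:
        out.add_node(n, g.nodes[n])
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if e.node_a in comp:
            out.add_edge(e)
    return out


def generate_graph(params: PlexusParams, max_resamples: int = 20) -> VesselGraph:
    """Build the plexus graph; deterministic for a fixed seed.

    If edge dropout happens to sever the artery from the vein the draw is
    rejected and resampled (bounded); capillary islands disconnected from the
    perfused component are discarded.
    """
    rng = np.random.default_rng(params.seed)
    for _ in range(max_resamples):
        g = _build_candidate(params, rng)
        if g is not None:
            return g
    raise RuntimeError(
        f"dropout prob {params.edge_dropout_prob} disconnected artery from vein "
        f"in {max_resamples} consecutive draws; lower edge_dropout_prob"
    )


def rasterize_mask(graph: VesselGraph, pixel_size: float,
                   shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize the graph's lumen: union of centreline-swept discs.

    A pixel (centre convention: physical position = (index + 0.5)·pixel_size)
    is foreground when it lies within the local radius of the centreline.
    Returns a boolean array of the given ``shape`` (rows, cols), or one just
    covering the graph extent plus the largest radius.
    """
    if not graph.edges:
        if shape is None:
            shape = (1, 1)
        return np.zeros(shape, dtype=bool)
    rmin_px = min(float(e.radii_um.min()) for e in graph.edges.values()) / pixel_size
    if rmin_px < 1.0:
        bad = min(graph.edges.values(), key=lambda e: float(e.radii_um.min()))
        raise ValueError(
            f"edge {bad.id}: radius {bad.radii_um.min():.3g} µm is below one "
            f"pixel at pixel_size={pixel_size} µm"
        )
    if shape is None:
        rmax = max(float(e.radii_um.max()) for e in graph.edges.values())
        xs = np.concatenate([e.polyline[:, 0] for e in graph.edges.values()])
        ys = np.concatenate([e.polyline[:, 1] for e in graph.edges.values()])
        n_cols = int(math.ceil((xs.max() + rmax + 2 * pixel_size) / pixel_size))
        n_rows = int(math.ceil((ys.max() + rmax + 2 * pixel_size) / pixel_size))
        shape = (n_rows, n_cols)
    mask = np.zeros(shape, dtype=bool)
    n_rows, n_cols = shape
    for e in graph.edges.values():
        arc = e.arc_coords
        step = 0.4 * pixel_size
        n_samp = max(2, int(math.ceil(arc[-1] / step)) + 1)
        s = np.linspace(0.0, arc[-1], n_samp)
        px = np.interp(s, arc, e.polyline[:, 0])
        py = np.interp(s, arc, e.polyline[:, 1])
        pr = np.interp(s, arc, e.radii_um)
        for cx, cy, r in zip(px, py, pr):
            # pixel-centre coordinates of the disc's bounding box
            col_c = cx / pixel_size - 0.5
            row_c = cy / pixel_size - 0.5
            r_px = r / pixel_size
            c0 = max(0, int(math.floor(col_c - r_px)))
            c1 = min(n_cols - 1, int(math.ceil(col_c + r_px)))
            r0 = max(0, int(math.floor(row_c - r_px)))
            r1 = min(n_rows - 1, int(math.ceil(row_c + r_px)))
            if c1 < c0 or r1 < r0:
                continue
            cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
            inside = (cc - col_c) ** 2 + (rr - row_c) ** 2 <= r_px ** 2
            mask[r0:r1 + 1, c0:c1 + 1] |= inside
    return mask


def polarity_concentration(tau, params: PolarityResponseParams):
    """Von Mises concentration κ(τ) = κ_max / (1 + exp(−(τ − τ0)/s)).

    A smooth threshold: κ is half its ceiling at τ = τ0, approaches 0 well
    below and κ_max well above, monotone in τ. Accepts scalars or arrays.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("wall shear stress must be >= 0")
    k = params.kappa_max / (1.0 + np.exp(-(tau_arr - params.tau0) / params.slope_s))
    return float(k) if np.isscalar(tau) or tau_arr.ndim == 0 else k


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a given log-normal mean/sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def place_cells(graph: VesselGraph, flow: FlowSolution,
                params: PolarityResponseParams):
    """Scatter endothelial cells on centrelines with flow-dependent polarity.

    Nuclei are evenly spaced along each edge at the configured linear density
    (strictly interior positions, so the local tangent is unambiguous). The
    polarity orientation of each cell is drawn from a von Mises distribution
    centred on the local flow direction rotated by 180°, with concentration
    κ(local WSS); on zero-flow edges κ is evaluated at τ = 0. Returns a
    pandas DataFrame with one row per cell including the ground-truth angle.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    mu_ln, sd_ln = _lognormal_params(params.polarity_len_mean,
                                     params.polarity_len_sd)
    rows = []
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        n_cells = int(round(e.length * params.cells_per_100um / 100.0))
        if n_cells == 0:
            continue
        fracs = (np.arange(n_cells) + 0.5) / n_cells
        sign = flow.flow_sign(eid)
        q = flow.edge_flow[eid]
        mu = flow.edge_viscosity.get(eid, flow.viscosity_pa_s)
        for f in fracs:
            s = f * e.length
            pos = e.point_at(s)
            r = e.radius_at(s)
            tau = 4.0 * mu * abs(q) / (np.pi * r ** 3)
            tangent = e.tangent_at(s) * sign
            flow_angle = math.atan2(tangent[1], tangent[0])
            kappa = polarity_concentration(tau, params)
            # deviation from anti-parallel; kappa=0 degenerates to uniform
            dev = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
            theta_world = flow_angle + np.pi + dev
            plen = float(rng.lognormal(mu_ln, sd_ln))
            golgi = pos + plen * np.array([math.cos(theta_world),
                                           math.sin(theta_world)])
            true_angle = math.degrees(np.pi + dev) % 360.0
            rows.append({
                "nucleus_x_um": pos[0], "nucleus_y_um": pos[1],
                "golgi_x_um": golgi[0], "golgi_y_um": golgi[1],
                "true_angle_deg": true_angle,
                "true_wss_pa": tau,
                "segment_id": eid,
                "bed": e.bed,
            })
    return pd.DataFrame(rows)


def generate_scene(plexus: PlexusParams | None = None,
                   response: PolarityResponseParams | None = None,
                   hemo_config: dict | None = None) -> SyntheticScene:
    """Full ground-truth scene: graph → mask → flow → cells."""
    plexus = plexus or PlexusParams()
    response = response or PolarityResponseParams()
    hemo = {"viscosity_pa_s": DEFAULT_VISCOSITY_PA_S,
            "inlet_pressure_pa": 2000.0,
            "viscosity_model": "constant"}
    hemo.update(hemo_config or {})
    graph = generate_graph(plexus)
    mask = rasterize_mask(graph, plexus.pixel_size)
    boundary = default_boundaries(graph, hemo["inlet_pressure_pa"])
    flow = solve_flow(graph, boundary,
                      viscosity_pa_s=hemo["viscosity_pa_s"],
                      viscosity_model=hemo["viscosity_model"])
    cells = place_cells(graph, flow, response)
    return SyntheticScene(graph=graph, mask=mask, flow=flow, cells=cells,
                          plexus_params=plexus, response_params=response,
                          hemo_config=hemo)
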