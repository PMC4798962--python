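"""Steady Poiseuille flow on a vessel graph and the resulting wall shear stress.

The network is treated as a hydraulic circuit: each edge is a tube of
(possibly varying) circular cross-section with conductance

    G = [ integral 8 mu / (pi R(s)^4) ds ]^-1

and flow conservation (Kirchhoff's current law) holds at every node that does
not carry a fixed-pressure boundary condition. Terminal nodes without a
condition are blind ends (no-flow), which the nodal formulation yields
automatically. Wall shear stress along an edge follows the Poiseuille wall
formula tau(s) = 4 mu |Q| / (pi R(s)^3).

Units: µm for lengths, Pa for pressures, Pa·s for viscosity, so flows come
out in µm³/s and conductances in µm³/(s·Pa) with no conversion factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import Edge, VesselGraph, nearest_centreline_points

DEFAULT_VISCOSITY_PA_S = 3.5e-3  # whole blood, Newtonian approximation

log = logging.getLogger("vesselpol")


@dataclass(frozen=True)
class BoundaryCondition:
    """Pressure or no-flow condition at a node."""

    node_id: int
    kind: str = "fixed_pressure"  # or "no_flow"
    pressure_pa: float = 0.0

    def __post_init__(self):
        if self.kind not in ("fixed_pressure", "no_flow"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")


@dataclass
class FlowSolution:
    """Pressures, signed edge flows and per-edge wall shear stress.

    ``edge_flow`` is signed positive in polyline order (node_a -> node_b).
    ``edge_wss`` is the arc-length-weighted mean of the pointwise wall shear
    stress; ``edge_wss_points`` keeps the pointwise values (one per polyline
    point) for sampling at arbitrary positions.
    """

    node_pressure: dict[int, float]
    edge_flow: dict[int, float]
    edge_wss: dict[int, float]
    edge_wss_points: dict[int, np.ndarray]
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    edge_viscosity: dict[int, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def flow_sign(self, edge_id: int) -> float:
        """+1 if flow runs node_a->node_b, -1 if reversed, +1 for zero flow."""
        return -1.0 if self.edge_flow[edge_id] < 0 else 1.0


def pries_viscosity(diameter_um: float, hematocrit: float = 0.45,
                    plasma_viscosity_pa_s: float = 1.2e-3) -> float:
    """Apparent in vitro blood viscosity (Pa·s) of Pries et al. (1992).

    Captures the Fahraeus-Lindqvist reduction of effective viscosity in
    narrow tubes; used as an optional alternative to the constant-viscosity
    default.
    """
    d = float(diameter_um)
    if d <= 0:
        raise ValueError("diameter must be positive")
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
    f = 1.0 / (1.0 + 10.0 ** -11 * d ** 12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + f) + f
    h = hematocrit
    rel = 1.0 + (eta45 - 1.0) * ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)
    return float(rel * plasma_viscosity_pa_s)


def _edge_viscosity(edge: Edge, viscosity_pa_s: float, model: str,
                    hematocrit: float) -> float:
    if model == "constant":
        return viscosity_pa_s
    if model == "pries":
        return pries_viscosity(2.0 * float(np.mean(edge.radii_um)), hematocrit)
    raise ValueError(f"unknown viscosity model {model!r}")


def segment_conductance(edge: Edge, viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Hydraulic conductance of one edge, µm³/(s·Pa).

    The Poiseuille resistance density 8µ/(πR⁴) is integrated along the
    centreline with the trapezoid rule over the polyline points (series
    composition of resistances); zero-length pieces contribute nothing, so a
    stepped tube can be encoded with a duplicated breakpoint.
    """
    if np.any(edge.radii_um <= 0):
        raise ValueError(f"edge {edge.id}: non-positive radius")
    if edge.length <= 0:
        raise ValueError(f"edge {edge.id}: zero length")
    dens = 8.0 * viscosity_pa_s / (np.pi * edge.radii_um ** 4)
    ds = edge.seg_lengths
    resistance = float(np.sum(0.5 * (dens[:-1] + dens[1:]) * ds))
    return 1.0 / resistance


def default_boundaries(graph: VesselGraph, inlet_pressure_pa: float = 2000.0,
                       outlet_pressure_pa: float = 0.0) -> list[BoundaryCondition]:
    """Artery root at inlet pressure, vein root at the reference pressure.

    The root of a trunk is its endpoint (degree-1) node with the smallest y
    (the proximal margin of the plexus); every other terminal node is a blind
    end and needs no explicit condition. On unlabelled graphs (e.g. freshly
    extracted from a mask) the two terminal nodes with the largest local
    vessel radius stand in for the artery and vein roots — the feeding
    trunks are the widest vessels entering the field.
    """
    deg = graph.degrees()

    def root_of(bed: str) -> int | None:
        candidates = set()
        for e in graph.edges.values():
            if e.bed == bed:
                candidates.update((e.node_a, e.node_b))
        ends = [n for n in candidates if deg[n] == 1]
        if not ends:
            return None
        return min(ends, key=lambda n: (graph.nodes[n][1], n))

    a_root, v_root = root_of("artery"), root_of("vein")
    if a_root is None or v_root is None:
        terminal_radius = {}
        for e in graph.edges.values():
            for node, r in ((e.node_a, e.radii_um[0]),
                            (e.node_b, e.radii_um[-1])):
                if deg[node] == 1:
                    terminal_radius[node] = max(terminal_radius.get(node, 0.0),
                                                float(r))
        if len(terminal_radius) < 2:
            raise ValueError(
                "cannot place default boundaries: need artery/vein labels or "
                "at least two terminal nodes")
        ranked = sorted(terminal_radius, key=lambda n: (-terminal_radius[n], n))
        a_root, v_root = ranked[0], ranked[1]
        log.warning("no artery/vein labels; using widest terminals "
                    "%d (inlet) and %d (outlet) as boundary nodes",
                    a_root, v_root)
    return [
        BoundaryCondition(a_root, "fixed_pressure", inlet_pressure_pa),
        BoundaryCondition(v_root, "fixed_pressure", outlet_pressure_pa),
    ]


def solve_nodal_pressures(graph: VesselGraph, conductances: dict[int, float],
                          boundary: list[BoundaryCondition]) -> dict[int, float]:
    """Solve flow conservation for the nodal pressures (Pa).

    Fixed-pressure nodes are Dirichlet constraints; everything else satisfies
    sum of G_e (P_neighbour - P_node) = 0. Every connected component must
    contain at least one fixed-pressure node for the system to be well posed.
    """
    fixed = {bc.node_id: bc.pressure_pa for bc in boundary
             if bc.kind == "fixed_pressure"}
    if not fixed:
        raise ValueError("at least one fixed_pressure boundary is required")
    for nid in fixed:
        if nid not in graph.nodes:
            raise KeyError(f"boundary node {nid} not in graph")

    g = graph.to_networkx()
    import networkx as nx
    for comp in nx.connected_components(g):
        if not comp & fixed.keys():
            raise ValueError(
                "connected component without a fixed-pressure node: "
                f"nodes {sorted(comp)[:5]}..."
            )

    free = [n for n in sorted(graph.nodes) if n not in fixed]
    index = {n: i for i, n in enumerate(free)}
    n_free = len(free)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_free)
    diag = np.zeros(n_free)
    for eid, e in graph.edges.items():
        if e.node_a == e.node_b:
            continue  # self-loop carries no net nodal flow
        ge = conductances[eid]
        for u, v in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if u in index:
                diag[index[u]] += ge
                if v in index:
                    rows.append(index[u])
                    cols.append(index[v])
                    vals.append(-ge)
                else:
                    rhs[index[u]] += ge * fixed[v]
    if n_free:
        lap = sp.coo_matrix((vals, (rows, cols)), shape=(n_free, n_free)).tocsr()
        lap += sp.diags(diag)
        if np.any(diag == 0):
            isolated = [free[i] for i in np.nonzero(diag == 0)[0]]
            raise ValueError(f"singular system: isolated free nodes {isolated}")
        sol = spla.spsolve(lap.tocsc(), rhs)
        if np.any(~np.isfinite(sol)):
            raise ValueError("singular pressure system")
    else:
        sol = np.empty(0)
    pressures = dict(fixed)
    for n, i in index.items():
        pressures[n] = float(sol[i])
    return pressures


def segment_flows_and_wss(graph: VesselGraph, pressures: dict[int, float],
                          viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
                          conductances: dict[int, float] | None = None,
                          viscosity_model: str = "constant",
                          hematocrit: float = 0.45) -> FlowSolution:
    """Signed edge flows Q = G·ΔP and Poiseuille wall shear stress.

    tau(s) = 4µ|Q|/(πR(s)³) pointwise; the per-edge scalar is the arc-length
    weighted mean of tau over the polyline. Flow direction is from the higher
    to the lower pressure end.
    """
    edge_flow, edge_wss, edge_wss_points = {}, {}, {}
    edge_visc = {}
    for eid, e in graph.edges.items():
        mu = _edge_viscosity(e, viscosity_pa_s, viscosity_model, hematocrit)
        edge_visc[eid] = mu
        ge = conductances[eid] if conductances is not None else segment_conductance(e, mu)
        if e.node_a == e.node_b:
            q = 0.0
        else:
            q = ge * (pressures[e.node_a] - pressures[e.node_b])
        tau_pts = 4.0 * mu * abs(q) / (np.pi * e.radii_um ** 3)
        ds = e.seg_lengths
        w = 0.5 * (tau_pts[:-1] + tau_pts[1:]) * ds
        mean_tau = float(w.sum() / ds.sum()) if ds.sum() > 0 else 0.0
        edge_flow[eid] = float(q)
        edge_wss[eid] = mean_tau
        edge_wss_points[eid] = tau_pts
    return FlowSolution(
        node_pressure=dict(pressures),
        edge_flow=edge_flow,
        edge_wss=edge_wss,
        edge_wss_points=edge_wss_points,
        viscosity_pa_s=viscosity_pa_s,
        edge_viscosity=edge_visc,
        metadata={"viscosity_model": viscosity_model,
                  "solver": "poiseuille-kirchhoff-1d"},
    )


def solve_flow(graph: VesselGraph, boundary: list[BoundaryCondition] | None = None,
               viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
               inlet_pressure_pa: float = 2000.0,
               viscosity_model: str = "constant",
               hematocrit: float = 0.45) -> FlowSolution:
    """Conductances + nodal solve + WSS in one call (the usual entry point)."""
    if boundary is None:
        boundary = default_boundaries(graph, inlet_pressure_pa)
    cond = {}
    for eid, e in graph.edges.items():
        mu = _edge_viscosity(e, viscosity_pa_s, viscosity_model, hematocrit)
        cond[eid] = segment_conductance(e, mu)
    pressures = solve_nodal_pressures(graph, cond, boundary)
    sol = segment_flows_and_wss(graph, pressures, viscosity_pa_s, cond,
                                viscosity_model, hematocrit)
    sol.metadata["boundary"] = [
        (bc.node_id, bc.kind, bc.pressure_pa) for bc in boundary
    ]
    return sol


def conservation_residual(graph: VesselGraph, flow: FlowSolution,
                          boundary_nodes: set[int] | None = None) -> float:
    """Max |net flow| at interior nodes relative to the largest edge flow."""
    if boundary_nodes is None:
        boundary_nodes = {nid for nid, kind, _ in flow.metadata.get("boundary", [])
                          if kind == "fixed_pressure"}
    net = {n: 0.0 for n in graph.nodes}
    for eid, e in graph.edges.items():
        if e.node_a == e.node_b:
            continue
        q = flow.edge_flow[eid]
        net[e.node_a] -= q
        net[e.node_b] += q
    interior = [abs(v) for n, v in net.items() if n not in boundary_nodes]
    qmax = max((abs(q) for q in flow.edge_flow.values()), default=0.0)
    if qmax == 0.0:
        return 0.0
    return max(interior, default=0.0) / qmax


def wss_vector_at_point(flow: FlowSolution, graph: VesselGraph, point,
                        max_dist_um: float = 20.0):
    """WSS magnitude and flow-oriented unit tangent at the nearest wall point.

    Returns ``(tau_pa, direction)`` for the closest centreline point within
    ``max_dist_um`` of ``point``, or ``None`` if no vessel is that close.
    For a zero-flow edge the magnitude is 0 and the tangent is reported in
    polyline order.
    """
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be positive")
    res = nearest_centreline_points(graph, np.asarray(point, dtype=float))
    if res["distance"][0] > max_dist_um:
        return None
    eid = int(res["edge_id"][0])
    s = float(res["arc_s"][0])
    e = graph.edges[eid]
    mu = flow.edge_viscosity.get(eid, flow.viscosity_pa_s)
    q = flow.edge_flow[eid]
    r = e.radius_at(s)
    tau = 4.0 * mu * abs(q) / (np.pi * r ** 3)
    direction = e.tangent_at(s) * flow.flow_sign(eid)
    return tau, direction
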