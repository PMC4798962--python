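"""Geometric vessel graph: junction/endpoint nodes joined by measured centreline edges.

All positions and radii are in micrometres, in the image coordinate frame
(x = column direction, y = row direction). Each edge carries an ordered
centreline polyline with a radius per polyline point, so downstream stages
(rasterization, hydraulic conductance, wall-shear sampling) can integrate
along the vessel rather than assume a uniform tube.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

BED_LABELS = ("artery", "vein", "capillary", "sprouting_front", "unassigned")


@dataclass
class Edge:
    """One vessel segment between two nodes.

    ``polyline`` is an (N, 2) array of (x, y) µm whose first/last points
    coincide with the positions of ``node_a``/``node_b``; ``radii_um`` has one
    entry per polyline point. Duplicate consecutive points are allowed and
    represent zero-length pieces (used e.g. for stepped-radius tubes).
    """

    id: int
    node_a: int
    node_b: int
    polyline: np.ndarray
    radii_um: np.ndarray
    bed: str = "unassigned"

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float).reshape(-1, 2)
        self.radii_um = np.asarray(self.radii_um, dtype=float).ravel()
        if len(self.radii_um) != len(self.polyline):
            raise ValueError(
                f"edge {self.id}: {len(self.polyline)} polyline points but "
                f"{len(self.radii_um)} radii"
            )
        if len(self.polyline) < 2:
            raise ValueError(f"edge {self.id}: polyline needs >= 2 points")
        if np.any(self.radii_um <= 0):
            raise ValueError(f"edge {self.id}: non-positive radius")
        if self.bed not in BED_LABELS:
            raise ValueError(f"edge {self.id}: unknown bed label {self.bed!r}")

    @property
    def seg_lengths(self) -> np.ndarray:
        """Length of each polyline sub-segment (N-1,)."""
        return np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Arc length along the centreline, µm."""
        return float(self.seg_lengths.sum())

    @property
    def arc_coords(self) -> np.ndarray:
        """Cumulative arc length at each polyline point (N,), starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.seg_lengths)])

    def point_at(self, s: float) -> np.ndarray:
        """Position at arc-length coordinate ``s`` (clipped to the edge)."""
        arc = self.arc_coords
        s = float(np.clip(s, 0.0, arc[-1]))
        x = np.interp(s, arc, self.polyline[:, 0])
        y = np.interp(s, arc, self.polyline[:, 1])
        return np.array([x, y])

    def radius_at(self, s: float) -> float:
        """Linearly interpolated radius at arc-length coordinate ``s``, µm."""
        arc = self.arc_coords
        return float(np.interp(np.clip(s, 0.0, arc[-1]), arc, self.radii_um))

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent (in polyline order) of the sub-segment containing ``s``."""
        arc = self.arc_coords
        s = float(np.clip(s, 0.0, arc[-1]))
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(max(i, 0), len(self.polyline) - 2)
        # skip zero-length pieces
        while i < len(self.polyline) - 2 and self.seg_lengths[i] == 0.0:
            i += 1
        d = self.polyline[i + 1] - self.polyline[i]
        n = np.linalg.norm(d)
        if n == 0.0:
            raise ValueError(f"edge {self.id}: degenerate polyline")
        return d / n


@dataclass
class VesselGraph:
    """Planar geometric graph of vessel centrelines."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)

    def add_node(self, node_id: int, position) -> int:
        self.nodes[node_id] = np.asarray(position, dtype=float)
        return node_id

    def add_edge(self, edge: Edge) -> int:
        for end, name in ((edge.node_a, "node_a"), (edge.node_b, "node_b")):
            if end not in self.nodes:
                raise KeyError(f"edge {edge.id}: unknown {name} {end}")
        self.edges[edge.id] = edge
        return edge.id

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node_id: int) -> int:
        d = 0
        for e in self.edges.values():
            if e.node_a == node_id:
                d += 1
            if e.node_b == node_id:
                d += 1  # self-loops count twice
        return d

    def degrees(self) -> dict[int, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges.values():
            d[e.node_a] += 1
            d[e.node_b] += 1
        return d

    def junction_nodes(self) -> list[int]:
        """Nodes of degree >= 3 (branch points)."""
        return [n for n, d in self.degrees().items() if d >= 3]

    def endpoint_nodes(self) -> list[int]:
        """Nodes of degree 1 (free vessel ends)."""
        return [n for n, d in self.degrees().items() if d == 1]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n, pos in self.nodes.items():
            g.add_node(n, x_um=float(pos[0]), y_um=float(pos[1]))
        for e in self.edges.values():
            g.add_edge(e.node_a, e.node_b, key=e.id, edge_id=e.id,
                       length_um=e.length, bed=e.bed)
        return g

    def n_components(self) -> int:
        if not self.nodes:
            return 0
        return nx.number_connected_components(self.to_networkx())

    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges.values()))

    def copy(self) -> "VesselGraph":
        return VesselGraph(
            nodes={n: p.copy() for n, p in self.nodes.items()},
            edges={
                i: replace(e, polyline=e.polyline.copy(), radii_um=e.radii_um.copy())
                for i, e in self.edges.items()
            },
        )

    def transformed(self, rotation_deg: float = 0.0, offset=(0.0, 0.0)) -> "VesselGraph":
        """Rigidly transformed copy (rotation about the origin, then translation)."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        off = np.asarray(offset, dtype=float)
        out = VesselGraph()
        for n, p in self.nodes.items():
            out.add_node(n, rot @ p + off)
        for i, e in self.edges.items():
            out.add_edge(
                replace(e, polyline=(e.polyline @ rot.T) + off, radii_um=e.radii_um.copy())
            )
        return out


def _segment_tables(graph: VesselGraph):
    """Flatten all polyline sub-segments for vectorised nearest-point queries.

    Returns (starts, vecs, lens2, edge_ids, seg_index, arc_start) with segments
    ordered by (edge id, position along polyline) so that ``argmin`` tie-breaks
    deterministically toward the lower edge id.
    """
    starts, vecs, edge_ids, seg_idx, arc0 = [], [], [], [], []
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        p = e.polyline
        arc = e.arc_coords
        d = np.diff(p, axis=0)
        keep = np.linalg.norm(d, axis=1) > 0
        idx = np.nonzero(keep)[0]
        starts.append(p[:-1][keep])
        vecs.append(d[keep])
        edge_ids.append(np.full(keep.sum(), eid))
        seg_idx.append(idx)
        arc0.append(arc[:-1][keep])
    if not starts or sum(len(s) for s in starts) == 0:
        return None
    starts = np.concatenate(starts)
    vecs = np.concatenate(vecs)
    lens2 = np.einsum("ij,ij->i", vecs, vecs)
    return (
        starts,
        vecs,
        lens2,
        np.concatenate(edge_ids),
        np.concatenate(seg_idx),
        np.concatenate(arc0),
    )


def nearest_centreline_points(graph: VesselGraph, points: np.ndarray,
                              chunk: int = 2048):
    """For each query point, the nearest point on any edge centreline.

    Returns a dict of arrays: ``edge_id``, ``distance`` (µm), ``arc_s``
    (arc-length coordinate on the edge) — one entry per query point. Ties in
    distance resolve to the lowest edge id (then earliest polyline segment).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    tab = _segment_tables(graph)
    if tab is None:
        raise ValueError("graph has no edges")
    starts, vecs, lens2, edge_ids, seg_idx, arc0 = tab
    n = len(points)
    out_eid = np.empty(n, dtype=int)
    out_dist = np.empty(n)
    out_arc = np.empty(n)
    for lo in range(0, n, chunk):
        pts = points[lo:lo + chunk]
        # t*: projection parameter clipped to [0,1], (npts, nseg)
        diff = pts[:, None, :] - starts[None, :, :]
        t = np.einsum("pij,ij->pi", diff, vecs) / lens2[None, :]
        t = np.clip(t, 0.0, 1.0)
        close = starts[None, :, :] + t[:, :, None] * vecs[None, :, :]
        d2 = np.sum((pts[:, None, :] - close) ** 2, axis=2)
        best = np.argmin(d2, axis=1)  # first occurrence = lowest edge id
        rows = np.arange(len(pts))
        out_eid[lo:lo + chunk] = edge_ids[best]
        out_dist[lo:lo + chunk] = np.sqrt(d2[rows, best])
        seglen = np.sqrt(lens2[best])
        out_arc[lo:lo + chunk] = arc0[best] + t[rows, best] * seglen
    return {"edge_id": out_eid, "distance": out_dist, "arc_s": out_arc}
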