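import numpy as np
import pytest

import vesselpol as vp
from vesselpol.graph import Edge, VesselGraph


def straight_tube(length_um=100.0, radius_um=5.0, n_pts=2, origin=(0.0, 0.0),
                  angle_deg=0.0, bed="capillary"):
    """Single-edge graph: a straight uniform tube."""
    th = np.deg2rad(angle_deg)
    d = np.array([np.cos(th), np.sin(th)])
    p0 = np.asarray(origin, dtype=float)
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = p0 + t * length_um * d
    g = VesselGraph()
    g.add_node(0, pts[0])
    g.add_node(1, pts[-1])
    g.add_edge(Edge(0, 0, 1, pts, np.full(n_pts, radius_um), bed=bed))
    return g


def diamond_graph(radii=(4.0, 5.0, 6.0, 3.0, 4.5)):
    """In -> {A, B} -> Out with an A-B crossbar; 5 edges, 4 nodes.

    The node layout is mirror-symmetric about y = 50, so equal radii on the
    two parallel branches make the crossbar flow vanish by symmetry.
    """
    g = VesselGraph()
    g.add_node(0, (0.0, 50.0))     # inlet
    g.add_node(1, (100.0, 0.0))    # A
    g.add_node(2, (100.0, 100.0))  # B
    g.add_node(3, (200.0, 50.0))   # outlet
    pairs = [(0, 1), (0, 2), (1, 3), (2, 3), (1, 2)]
    for eid, ((u, v), r) in enumerate(zip(pairs, radii)):
        g.add_edge(Edge(eid, u, v, np.vstack([g.nodes[u], g.nodes[v]]),
                        np.full(2, r)))
    return g


def y_skeleton_image():
    """A 'Y': three straight arms meeting at one junction pixel."""
    img = np.zeros((40, 40), dtype=bool)
    img[20, 5:21] = True              # horizontal arm into (20, 20)
    for k in range(1, 15):            # two diagonal arms
        img[20 - k, 20 + k] = True
        img[20 + k, 20 + k] = True
    img[20, 20] = True
    return img


@pytest.fixture(scope="session")
def small_scene():
    """Default 600 µm plexus with cells; shared by round-trip tests."""
    return vp.generate_scene(vp.PlexusParams(seed=2),
                             vp.PolarityResponseParams(seed=3))


@pytest.fixture(scope="session")
def clean_lattice():
    """Dropout-free plexus and its rasterized mask (clean geometry)."""
    params = vp.PlexusParams(seed=0, edge_dropout_prob=0.0, n_sprouts=4)
    graph = vp.generate_graph(params)
    mask = vp.rasterize_mask(graph, params.pixel_size)
    return params, graph, mask
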