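"""Recover the vessel graph from a binary lumen mask and check it.

Skeletonization gives the 1-px centreline, the distance transform gives the
maximum-inscribed-circle radius at each centreline pixel, and chain tracing
between junctions yields a measured graph. Because the mask here comes from
a known generator graph, topology recovery can be verified exactly.
"""

import numpy as np

import vesselpol as vp

params = vp.PlexusParams(seed=0, edge_dropout_prob=0.0, n_sprouts=4)
truth = vp.generate_graph(params)
mask = vp.rasterize_mask(truth, params.pixel_size)

graph, meta = vp.extract_network(mask, params.pixel_size)
print(f"extraction: {meta['skeletonization']}")
print(f"truth:     {len(truth.junction_nodes())} junctions, "
      f"{len(truth.endpoint_nodes())} endpoints")
print(f"extracted: {len(graph.junction_nodes())} junctions, "
      f"{len(graph.endpoint_nodes())} endpoints")

errs = []
for e in graph.edges.values():
    res = vp.nearest_centreline_points(truth, e.polyline)
    true_r = np.array([truth.edges[int(i)].radius_at(s)
                       for i, s in zip(res["edge_id"], res["arc_s"])])
    errs.append(np.median(np.abs(e.radii_um - true_r)))
print(f"per-edge median radius error: worst {max(errs):.2f} um "
      f"(pixel size {params.pixel_size} um)")

area = vp.vessel_area_fraction(mask)
density = vp.branchpoint_density(graph, mask.size * (params.pixel_size * 1e-3) ** 2)
print(f"morphometrics: vessel area fraction {area:.3f}, "
      f"branch-point density {density:.0f} per mm^2")
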