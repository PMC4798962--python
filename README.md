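# vesselpol

Quantifying how endothelial cells orient themselves relative to blood flow
in a developing vascular plexus.

During vascular remodelling, endothelial cells (ECs) polarize and migrate
*against* the direction of blood flow once the local wall shear stress (WSS)
exceeds a threshold; vessel segments with sub-threshold flow are abandoned
and regress. Measuring this requires joining three very different data
layers: the geometry of the vessel network (from a binary lumen mask), a
flow simulation on that network, and per-cell axial polarity — the vector
from the centre of each EC nucleus to the centre of its Golgi apparatus,
a proxy for the cell's migration direction.

`vesselpol` implements that pipeline end to end for planar (retina-style)
networks:

1. **Network extraction** — skeletonize the mask to a 1-px centreline,
   estimate local vessel radius by maximum inscribed circles (Euclidean
   distance transform), and decompose the skeleton into a measured graph of
   junctions, endpoints and centreline polylines; plus the usual mask-level
   morphometrics (vessel area fraction, branch-point density).
2. **Hemodynamics** — steady Poiseuille flow on the graph: each segment has
   hydraulic conductance `G = [∫ 8μ/(πR(s)⁴) ds]⁻¹`, Kirchhoff's current law
   at junctions yields nodal pressures, and wall shear stress follows the
   Poiseuille wall formula `τ = 4μ|Q|/(πR³)`.
3. **Polarity records** — each cell's polarity vector **p** = Golgi −
   nucleus is matched to the nearest centreline point, giving the WSS
   magnitude, the flow-oriented tangent, the CCW angle θ from flow to
   polarity (180° = against flow), the scalar product `|p|·τ·cos θ`, and a
   vascular-bed label (artery / vein / capillary / sprouting front).
4. **Circular statistics** — circular means with 95% confidence arcs and
   Rayleigh uniformity tests; a two-sample Kuiper test (rotation-invariant
   circular Kolmogorov–Smirnov, permutation or asymptotic p-values); the
   fraction of cells within 45° of anti-parallel, binned by WSS with Wilson
   intervals; the shear at which that fraction first crosses a target
   (threshold readout); and OLS of the scalar product against WSS split by
   sign, whose against-flow gradient equals the mean projection
   `|p|·cos θ` in µm.
5. **Synthetic plexus generator** — ground truth for all of the above: an
   artery and a vein trunk bridged by a jittered capillary lattice with
   blind-ended sprouts, rasterized to a mask, perfused, and populated with
   cells whose orientation is drawn from a von Mises distribution centred
   against the local flow with concentration
   `κ(τ) = κ_max / (1 + exp(−(τ − τ0)/s))` — a smooth shear threshold whose
   parameters the downstream analysis has to recover.

## Worked example

`examples/04_polarity_statistics.py` builds a synthetic scene, joins the
cells to the flow field and runs the statistics layer:

```
319/319 cells matched to a vessel within 20 um
artery          n=  20 mean  263.0 deg +/-   nan (not polarized, Rayleigh p=0.6)
capillary       n= 265 mean  181.7 deg +/-  10.9 (polarized, Rayleigh p=4.5e-22)
sprouting_front n=  14 mean   26.4 deg +/-   nan (not polarized, Rayleigh p=0.2)
vein            n=  20 mean   21.3 deg +/-   nan (not polarized, Rayleigh p=0.91)
anti-aligned fraction by WSS decile: [0.23 0.24 0.23 0.24 0.26 0.42 0.47 0.69 0.85 0.91]
shear at which half the cells polarize against flow: 4.32 Pa
scalar-product regression, against-flow branch: gradient -6.88 um (r=-0.83, n=218)
```

Reading this: capillary cells point on average at 181.7° to the flow —
anti-parallel — and the Rayleigh test confirms the bed is significantly
polarized, while the low-shear trunks and the unperfused sprouting front
are indistinguishable from uniform. The anti-aligned fraction climbs from
the chance level 0.25 in the low-WSS deciles to >0.9 at high shear and
crosses 50% at 4.3 Pa, close to the 5 Pa threshold the generator used. The
−6.9 µm regression gradient is the mean projection of the ~7 µm polarity
vectors onto the flow axis for cells polarized against it.

The other examples cover scene generation, network extraction, the flow
solver, and recovery of the generating threshold across scenes
(`examples/05_threshold_recovery.py` prints crossing shears 1.04 / 2.84 /
4.82 Pa for τ0 = 2 / 4 / 6 Pa).

A thin CLI mirrors the stages:

```sh
vesselpol simulate --out scene --seed 2
vesselpol run-all scene/mask.tif scene/cells.csv --out analysis
```

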