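# Methods

## The measurement problem

An endothelial cell's nucleus-to-Golgi axis ("axial polarity") anticipates
its migration direction. In a remodelling plexus, cells exposed to wall
shear stress above a threshold polarize against the flow and migrate out of
low-flow segments, which then regress. The pipeline quantifies this
flow/polarity coupling for planar vascular networks: it reconstructs the
vessel network from a binary lumen mask, simulates steady flow to obtain a
WSS magnitude and direction at every cell position, and summarises the
flow-relative orientation distribution per vascular bed and per WSS stratum.

## Network extraction

- **Skeletonization.** scikit-image's `skeletonize` (topological thinning).
  Any algorithm meeting the contract — 1-pixel-wide, 8-connected, preserving
  the number of connected components — would do; the choice is recorded in
  the extraction metadata.
- **Radii.** The maximum-inscribed-circle radius at a centreline pixel is
  the Euclidean distance transform of the foreground evaluated there, scaled
  by the pixel size. On rasterized ground truth the per-edge median error is
  below one pixel (the estimator carries a positive bias of ~0.5 px because
  the distance is measured to background pixel *centres*; this stays within
  the one-pixel contract and is left uncorrected rather than tuned).
- **Graph building.** Skeleton pixels with ≠2 neighbours (after discarding
  diagonal links that duplicate an orthogonal 2-step path) become nodes;
  maximal chains of degree-2 pixels become edges carrying ordered polylines
  and per-point radii. Two clean-ups make recovered topology match the
  generating geometry: (1) junction nodes joined by a chain shorter than
  `junction_merge_factor` (default 2) × the local radius are contracted into
  one branch point — an oblique X-crossing thins into two adjacent Y's, and
  junction pixel clusters would otherwise inflate branch-point counts;
  (2) background holes below `min_hole_area_px` (default 16 px) are filled
  before thinning, because rasterization quantization can leave 1–2 px
  holes at junctions around which thinning wraps a spurious loop. Both
  thresholds sit an order of magnitude below real structures (mesh holes are
  thousands of px; distinct junctions are a mesh spacing apart).
- **Spur pruning.** Terminal edges shorter than twice the largest inscribed
  radius are removed iteratively (with degree-2 node merging), which
  deletes thinning whiskers at wide-vessel walls; edges labelled as
  sprouting front are protected. The operation is idempotent.
- **Coordinates.** Pixel indices are 0-based, x = column, y = row; physical
  positions are pixel centres, `(index + 0.5) · pixel_size` µm.

## Hemodynamics

The paper-scale 3D lattice-Boltzmann CFD stage is replaced by a 1D
Poiseuille/Kirchhoff network model — a deliberate reduction, recorded in all
output metadata. The polarity analysis consumes only a per-position WSS
magnitude and a flow direction along the vessel axis, which the network
model provides; wall-resolved shear distributions do not survive the
reduction and are out of scope.

- Conductance of a segment with varying radius:
  `G = [∫ 8μ/(πR(s)⁴) ds]⁻¹`, trapezoid rule over the polyline (duplicate
  breakpoints encode radius steps exactly as series resistances).
- Flow conservation at every non-boundary node gives a sparse SPD system
  solved with `scipy.sparse`; blind ends (sprout tips, unlabelled
  terminals) need no explicit condition — zero flow falls out of the nodal
  formulation.
- WSS: `τ(s) = 4μ|Q|/(πR(s)³)` pointwise; the per-edge scalar is the
  arc-length-weighted mean. Directions are unit tangents oriented from high
  to low pressure.
- **Units** are µm / s / Pa / Pa·s throughout, so conductances come out in
  µm³/(s·Pa) with no conversion factors inside any operation.
- **Viscosity**: constant μ = 3.5 mPa·s (whole blood, Newtonian) by
  default; the Pries et al. in vitro law μ(D, hematocrit) is available as a
  config switch and changes only the conductances and τ.
- **Boundary conditions.** Artery root (the proximal terminal of the artery
  trunk) at the inlet pressure, vein root at 0 Pa. On unlabelled graphs the
  two widest terminal nodes stand in, with a logged warning. The default
  arteriovenous pressure drop is 2000 Pa (~15 mmHg): with capillary radii of
  ~3.5 µm and segment lengths of ~50 µm, Poiseuille wall shear along a
  series path is ≈ R·ΔP_segment/(2L), so physiological capillary WSS of
  1–10 Pa requires a drop of O(10³) Pa across the plexus. A drop of tens of
  Pa would put every capillary below 0.2 Pa and make threshold analyses in
  the 2–7 Pa range meaningless.
- Cells are matched to the nearest centreline point within
  `max_sampling_dist_um` (default 20 µm, about one cell body beyond the
  largest vessel radius); ties break deterministically to the lower edge id.
  Cells with no vessel in range keep their polarity fields but are excluded
  from angle statistics, explicitly counted, never silently dropped.

## Polarity conventions

- Polarity vector **p** = Golgi − nucleus; coincident points are a reported
  per-row error, not a crash.
- Angle θ = CCW angle from the flow direction to **p**, folded to [0°,
  360°); 0° = with flow, 180° = against. "Anti-aligned" means θ within a
  ±45° window of 180°, so a uniform orientation distribution gives an
  anti-aligned fraction of 90/360 = 0.25 — the chance floor all enrichment
  is measured against.
- Scalar product s = |p|·τ·cos θ (µm·Pa), negative for cells polarized
  against the flow. Regressing s on τ within each sign class gives a
  gradient equal to the mean projection |p|·cos θ (µm) of that class; a more
  negative against-flow gradient means stronger polarization per unit shear.

## Circular statistics

- **Mean and confidence arc.** Mean direction from the resultant vector;
  the 95% arc half-width uses the large-sample circular standard error
  `se² = (1−ρ₂)/(2nR̄²)` (Fisher's circular dispersion). The arc is reported
  only when the Rayleigh test (via pingouin) rejects uniformity — with no
  preferred direction a mean arc is meaningless.
- **Two-sample Kuiper test.** V = max(D⁺) + max(D⁻) between the circular
  ECDFs, computed as the peak-to-trough span of the cumulative difference
  walk over the pooled sorted sample; because the walk closes to zero
  around the circle, V is invariant to a common rotation of both samples.
  p-values by label permutation (default 9,999 draws, seeded) or by
  Stephens' asymptotic tail formula with effective size n_a·n_b/(n_a+n_b).
  Since V lives on a lattice, exact ties between permuted and observed
  values are common and make the plain permutation p conservative
  (empirically ~0.035 at nominal 0.05); ties are therefore half-weighted
  (mid-p) on top of the add-one rule, which restores the empirical type-I
  error to ~0.045 without anti-conservative behaviour.
- **Binned anti-alignment.** Default bins are deciles of the observed WSS
  distribution (fixed edges available via config for cross-run
  comparability); per-bin Wilson intervals; bins are [lo, hi) with the last
  closed. The threshold readout is the smallest WSS at which the piecewise
  linear interpolation of fraction vs bin midpoint reaches the target
  fraction (default 0.5). Note the crossing sits on the rising flank of the
  response sigmoid, so it is systematically below the generator's τ0; what
  the pipeline guarantees (and tests) is strict monotonicity in τ0, which is
  what genotype comparisons rest on.
- **Regression.** Ordinary least squares (`scipy.stats.linregress`) per
  sign subset; subsets with n < 3 are marked unavailable; zero scalar
  products belong to neither subset.

## Synthetic generator

The generator emulates a retinal-style plexus: one artery trunk (left) and
one vein trunk (right), a capillary lattice between them with node jitter
(default σ = 4 µm), random edge dropout (default 0.15; draws that sever the
artery–vein connection are rejected and resampled, stranded capillary
islands are discarded), and blind-ended sprouts on the distal margin. A
lattice-with-dropout was chosen over space-filling growth because it
preserves the artery→capillary→vein pressure path the flow solver needs
with far less machinery. Default geometry: 600×600 µm at 1 µm/px, trunk
radii 12/15 µm, capillary radii 3.5 ± 0.5 µm, 60 µm mesh spacing. Trunk
free ends overhang the first/last lattice row by one mesh spacing so that
genuine vessel ends are well above the spur-pruning scale.

The polarity response is the working model of shear-threshold polarization:
orientation ~ von Mises centred at (local flow direction + 180°) with
concentration `κ(τ) = κ_max/(1+exp(−(τ−τ0)/s))`. The logistic is the
minimal smooth thresholding family (the biology specifies only "a
threshold"); von Mises noise is the standard circular analogue of Gaussian
noise with κ as the single noise knob. Defaults: τ0 = 5 Pa (between the
~4 Pa and ~7 Pa crossing shears that distinguish sensitized from wild-type
endothelium), s = 1 Pa, κ_max = 4 (asymptotic anti-aligned fraction ≈0.95).
Polarity magnitudes are log-normal with mean 7 µm, sd 2 µm — the scale of a
nucleus–Golgi offset; magnitude affects only scalar products, not angles.
Cell nuclei sit at evenly spaced interior positions along centrelines at
a linear density of 4 per 100 µm by default (one EC nucleus every ~25 µm).

What the generator does **not** emulate: segmentation noise and manual
masking artifacts, 3D vessel topology, pericytes, pulsatility, red-cell
phase separation, junction-localised flow disturbance, or time-lapse
remodelling. Passing tests therefore demonstrate correctness of the
measurement and statistics chain on idealized geometry, not robustness to
real imaging noise.

## Problem sizes used in tests and verification

Topology-recovery runs use ten 600×600 µm dropout-free plexuses (~150
edges each). The uniform-null check uses a 2000×2000 µm plexus at 8 cells
per 100 µm (~10,300 cells) — analysed without rasterization, since the null
concerns the statistics layer. Threshold-recovery scenes are 1000×1000 µm
at 7 cells per 100 µm (~2,100 cells) with a 4000 Pa inlet so the cell-level
WSS distribution spans ~0–15 Pa and brackets all three generating
thresholds {2, 4, 6} Pa. Kuiper calibration uses 2,000 uniform pairs of
n = 100 each at 499 permutations (p-resolution 0.002 at the 0.05 level);
single comparisons default to 9,999 permutations.

## Known limitations

- Absolute WSS values depend on the assumed boundary pressures and
  viscosity model; only relational statistics (ordering across beds,
  genotypes, or thresholds) are meaningful, matching how the readouts are
  used.
- The planar graph reduction cannot represent vessels crossing without
  touching; masks of overlapping 3D layers will fuse them into junctions.
- The threshold readout requires the observed WSS range to bracket the
  crossing; on low-perfusion networks it correctly returns "not reached"
  rather than extrapolating.
- Junction-adjacent cells are assigned the nearest single edge's flow
  direction; no blending across branches is attempted.
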