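# Methods

`cortexcount` implements direct 3D counting of cortical cellular
composition: every nucleus inside an unbiased counting brick is segmented,
classified as neuron, glia or vascular, and tabulated per cortical layer.
Because no raw image data are publicly deposited for this kind of study,
the package ships a forward simulator whose output is the test bed for
every downstream stage. This note records the models, the parameters that
matter, and the design decisions that were genuinely open.

## The synthetic cortical column

A simulated column is a multichannel voxel grid ordered `(channel, z, y,
x)`: `z` is the optical axis (a 50 µm section sampled at 1 µm steps —
typical confocal acquisition of free-floating sections), `y` the cortical
depth from the pia, `x` the tangential width. In-plane voxel sizes default
to 0.69 µm (human-like 20× acquisition) or 0.83 µm (mouse-like 40×).

**Cell placement.** Each layer is a slab of configurable thickness,
density and class composition `(p_neuron, p_glia, p_vascular)`. Neurons
and glia follow a hard-core point process (random sequential placement):
a Poisson-distributed total at the layer's density, uniform positions,
rejected when closer than `max(min_separation_um, 0.95·(r_i + r_j))` to an
existing nucleus. Nuclei are ellipsoids with Gaussian-jittered semi-axes
(neurons 5 µm, glia 3 µm mean long semi-axis; mild 0.85–1.0 axis ratios;
random orientation). An explicit `touching_fraction` can inject deliberately
touching pairs for segmentation stress tests.

**Vasculature.** Vessels are polylines running pia→white-matter with a
gentle lateral random walk and a 3.5 µm tube radius, positioned uniformly
over a slightly padded volume so vascular density carries no interior bias
relative to the other classes. Three placement rules reproduce the
phenotype that matters for classification:

* vascular nuclei are filiform (semi-axes ≈ 5 × 2 × 2 µm, enforced aspect
  ≥ 2.5), sit on the tube wall, and are oriented along the local tangent;
* each layer's vascular quota is concentrated on as few vessels as wall
  capacity allows (target ≈ 9.5 µm axial spacing), and the occupied-vessel
  order is shared across layers, so nuclei form the dense, continuous
  chains seen along real penetrating vessels rather than a uniform dusting;
* the tube displaces tissue: non-vascular nuclei keep a 3 µm clearance
  from the lumen, as real somata are displaced by the vessel wall.

The last two rules were added after simulator-gated evaluation showed that
without them the stacks are *unrealistically hard*: uniformly scattered
single vascular nuclei have no cylindrical signature for any geometric
detector, and glia placed inside vessel walls are indistinguishable from
endothelium by colocalization.

**Rendering.** Channels are additive intensity kernels — flat inside the
nucleus surface with a 0.5 µm Gaussian falloff — blurred by a Gaussian PSF
(default σ = 0.75/0.5/0.5 µm in z/y/x) and degraded by Poisson-Gaussian
noise controlled by a single `snr` scalar (default 10): foreground
amplitude maps to `snr²` expected photon counts, background to 10% of it,
rescaled into a fixed unsigned-16-bit range (foreground ≈ 10,000 counts).
The nuclear channel renders all cells, the neuron-marker channel only
neurons (emulating a neuron-specific nuclear antigen), the vessel-marker
channel the vessel tubes (emulating an endothelial surface label).

**Presets.** `human-ba21` (7 layers I–VI with IIIa/IIIb, two channels —
the human protocol acquires no vessel channel, forcing geometric vascular
detection) and `mouse-s1hl` (6 layers, three channels). Layer compositions
are the published per-layer proportions for the two regions; the mouse
glia/vascular split is derived from the published per-layer ratio tables.
Absolute per-layer densities are *not* published; the mouse preset uses the
study-wide average (≈3.3·10⁵ cells/mm³ from total cells over total
volume) and the human preset a placeholder of 3.0·10⁵ cells/mm³, chosen so
a single simulated column carries enough cells for proportion estimates.
Layer thickness fractions are likewise plausible placeholders. Simulated
composition and ratios are therefore comparable to the published tables;
absolute densities are not.

**What the simulator does not emulate:** depth-dependent attenuation and
spherical aberration, lipofuscin autofluorescence, tile stitching seams,
fixation-quality differences, and non-ellipsoidal nuclear shapes. Passing
recovery tests therefore demonstrate correctness of the counting and
classification machinery under controlled conditions, not robustness to
every real acquisition artifact.

## Segmentation

The nuclear channel is smoothed (σ = 0.7 µm), thresholded globally (Otsu,
floored at background + 3 robust spreads so a pure-noise stack yields no
foreground; a fixed `background + k·spread` policy is available for
low-contrast data), hole-filled, and split by watershed on the negated
Euclidean distance transform computed with *physical* sampling so
anisotropic voxels are handled correctly. Seeds are local maxima of the
smoothed distance map (σ = 0.7 µm) under a tight 3×3×3 footprint, thinned
greedily at a physical 4 µm radius (deeper peak wins, ties by raster
order). Components outside 30–2,000 µm³ are discarded.

Two seeding choices deviate from the obvious defaults and were fixed by
gating against the simulator: seed-map smoothing at σ = 1 µm merged
touching glia pairs separated mainly along z (glia recall 0.96 → 0.99 at
σ = 0.7), and any isotropic voxel-space peak spacing over-suppresses along
the coarse z axis — hence the physical-unit thinning.

Background estimation is median/MAD of voxels outside a coarse foreground
mask, with a separation check that rejects the mask when the "foreground"
is not actually brighter than background by ≥ 4 spreads (Otsu always
splits *something*, even pure noise). On stacks above ~4M voxels the
statistics are computed on a stride-2 subsample.

Per-label measurement: centroid and volume in physical units; principal
semi-axes `a_i = sqrt(5·λ_i)` from the eigenvalues of the voxel-center
covariance (exact for a solid ellipsoid); the long-axis eigenvector feeds
the geometric vascular detector. Labels under 4 voxels are flagged
degenerate with aspect ratio 1.

## The counting brick

A rectangular prism with one acceptance and one exclusion face per axis
(low faces exclusion by default). A nucleus is counted iff its support
intersects the brick and touches no exclusion face; at corners exclusion
wins — the property that makes adjacent bricks sharing faces count every
object exactly once. "Touching a plane" is evaluated on the bounded face
rectangle: a nucleus beyond the brick crossing only the plane's extension
is outside, not excluded. For segmented nuclei the decision uses the voxel
mask with a half-open convention (a voxel owns its low edge); box supports
(used by the Monte-Carlo oracle and as a bbox fallback) use closed
intervals, under which "counted" reduces per axis to the low corner lying
in `(lo, hi]` — the measure-theoretic form that makes the expected count
exactly λ·V for any object size.

## Classification

Precedence neuron > vascular > glia; every counted nucleus gets exactly
one class, so the partition conserves counts.

* **Neuron:** marker contrast `(mean − background) / spread ≥ k`, default
  k = 4. At the default SNR the two populations are separated by tens of
  spreads, so the result is insensitive to k over a wide range.
* **Vascular, marker mode:** nucleus support within 2 µm of the
  Otsu-thresholded vessel-tube mask (one distance transform amortized over
  all nuclei).
* **Vascular, geometry mode** (no vessel channel): a graph over elongated
  non-neuronal nuclei (aspect ≥ 1.8, degenerate shapes excluded); two
  nuclei link when their centroids are ≤ 18 µm apart, long axes mutually
  aligned within 30°, and the link either collinear with the axes within
  30° or offset from the shared axis by ≤ 8 µm perpendicular distance (the
  cylinder criterion — nuclei on opposite walls of one vessel). Connected
  components with ≥ 2 members are vascular. None of these parameters is
  quantified by the visual criterion they operationalize; they were tuned
  once on two simulator seeds and frozen, and all are exposed.
* **Glia:** the non-neuronal remainder — matching how such studies define
  glia operationally (no glial marker is acquired).

## Composition tables and statistics

Layer assignment is by centroid depth into half-open intervals
`[b_i, b_{i+1})` (a cell exactly on a boundary belongs to the deeper
layer); cells beyond the white-matter boundary are flagged and excluded.
Tables carry counts, proportions, nNNR = (glia+vascular)/neurons and
GNR = glia/neurons at full precision, with a display convention of two
decimals for proportions and one for ratios. Ratios are flagged undefined
when there are no neurons, and GNR when no glia/vascular split exists.

Aggregation follows the dual convention of the field's tables: per-layer
rows are mean ± SD across replicate columns; the pooled all-layers row is
the *accumulated* value recomputed from summed counts (a
`mean_of_columns` policy is available because the two differ whenever
columns differ in size).

Group comparison replaces a generalized linear mixed model with machinery
implemented from first principles: a two-proportion z-test on pooled
counts (validated in-suite against statsmodels and a brute-force
permutation oracle), a percentile bootstrap over replicate columns for the
CI of the proportion difference, and Holm correction across per-layer
comparisons. This reproduces direction and significance of group
differences, not mixed-model p-values; with that caveat the published
species contrast (mouse neuron share ≫ human) is overwhelming at the
printed counts (p < 10⁻¹⁰).

## Problem sizes and determinism

Default test columns are 50 µm × full layer stack × 120–350 µm
(≈0.5–13M voxels, 600–2,400 cells), sized so the full suite runs in a few
minutes on one CPU; the acceptance script pools four ~3,100-cell layer II
blocks (≈8,600 counted nuclei). All randomness flows from explicit
`numpy.random.Generator` seeds; a fixed seed reproduces cell lists
bitwise and rendered stacks up to platform float determinism, and pipeline
CSV outputs byte-for-byte.

## Known limitations

* Geometric vascular detection needs the chain phenotype: a field with
  genuinely isolated vascular nuclei (recall floor) or elongated
  non-vascular debris aligned by chance (precision floor) will degrade it.
* Layer assignment by centroid misplaces nuclei straddling a boundary by
  at most one layer; with ~35–100 µm layers and ≤6 µm nuclei this moves
  well under 1% of cells per boundary.
* The brick's unbiasedness argument assumes the nucleus population is
  homogeneous in a neighborhood of the brick; a brick flush against a
  stack border violates it, which is why the pipeline insets the brick by
  6 µm (≥ the largest nucleus radius) by default.
* Published per-case laminar means ± SD for these regions cannot be
  recomputed here: the raw images behind them are not publicly deposited.
  That territory is covered indirectly by the simulation-recovery
  properties.
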