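# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `neuromosaic`. Units are μm for lengths, μm² for pixel
areas, mm² and cells/mm² for reported areas and densities.

## Point-process models

The synthetic module provides the three regimes the statistics must
distinguish, each deterministic under its seed (compound generators split a
single user seed through `numpy.random.SeedSequence`):

* **CSR** — homogeneous Poisson: count ~ Poisson(λ|W|), locations i.i.d.
  uniform. Null model for all envelopes; mean NND 1/(2√λ), NND CV
  √((4−π)/π) ≈ 0.5227.
* **Matérn II** — CSR proposals with i.i.d. uniform marks; a point dies if
  any neighbour within the inhibition radius h carries an older mark. No
  surviving pair is closer than h, and the retained intensity has the
  closed form (1 − exp(−λπh²))/(πh²), used as a simulation oracle. Type II
  was chosen over type I precisely because this closed form exists. A zero
  radius degenerates to CSR.
* **Thomas** — Poisson parents, Poisson(μ) offspring per parent displaced
  by isotropic Gaussians of sd σ. Parents are simulated in a window dilated
  by 4σ so the restriction to the observation window is a true stationary
  Thomas process; children falling outside the window are discarded. This
  makes E[count] = κμ|W| exact and the closed form
  g(r) = 1 + exp(−r²/4σ²)/(4πκσ²) usable as an oracle; without the
  dilation, edge-deficient parents bias ĝ near the boundary.

Layered sampling draws an independent CSR population inside each annotated
layer, so programmed laminar fractions are proportional to intensity ×
layer area. There is no L1 compartment anywhere: the analyzed layer set
starts at L2/3 (a pooled 3-layer mode L2-4/L5/L6 serves perinatal material
where the L2/3–L4 border cannot be drawn).

## Scene rendering

Somata are spheres of radius R (default 6 μm, i.e. a 12-μm cell body)
whose in-plane section in a slice at axial distance dz is a disk of radius
√(R² − dz²); soma depths are uniform over the stack's axial range. Slices
are blurred in-plane by a Gaussian PSF (default σ = 1 μm), put on a
constant background, and given i.i.d. Gaussian read noise, so
SNR = (peak − background)/noise_sd. Clutter emulating fine neurite
staining is stamped as straight segments 5–20 μm long, 1 μm wide (a fine
axonal caliber; the width must stay below half the soma radius), at
background + 0.5 × signal amplitude, spanning the slab. Wider or brighter
clutter stops being "fine staining": after any local contrast
equalization it becomes indistinguishable from somata, which contradicts
what the clutter term is meant to emulate.

What the generator does **not** emulate: staining variability between
cells, bleed-through, tissue deformation, out-of-focus haze, or dense
neuropil texture. Passing recovery tests therefore demonstrate estimator
and chain correctness under controlled conditions, not segmentation
performance on arbitrary real material — on real images the manual-QC
review file (editable detections CSV) remains the backstop.

## Segmentation chain

`median_projection → dog_filter → clahe → auto_threshold →
watershed_split → particle_filter`, fully deterministic.

* **Projection**: per-pixel median of 4 consecutive slices (default the
  middle 4), i.e. an 8-μm optical section at 2-μm steps; objects present
  in fewer than half the slices are suppressed. With deep stacks and
  uniform soma depths, cells outside the projected slab are invisible by
  construction; recovery tests therefore use 4-slice stacks whose slab
  covers all ground truth.
* **DoG**: blur(σ₁) − blur(2σ₁), with σ₁ defaulting to ~0.8 × the
  smallest expected soma radius. The band-pass passes soma-scale blobs and
  attenuates both thin neurites and slow illumination gradients.
* **CLAHE**: skimage backend; the clip parameter follows the slope-limit
  convention (multiple of the mean histogram bin, mapped to the backend's
  normalized limit as clip/256). Default clip 1.5, tile 128 px. The low
  clip is deliberate: at slope ≈ 3 and above the equalization renormalizes
  faint clutter in soma-free tiles up to soma brightness, after which no
  global threshold can separate the two classes; at 1.5 the soma/clutter
  contrast the DoG produces survives equalization. The recovery tests
  exercise the shipped defaults across an SNR ladder and intensity
  scalings.
* **Threshold**: global Otsu by default. The iterative-intermeans
  (ISODATA) variant is available but is knife-edge sensitive to the shape
  of the equalized histogram on these images, so the between-class-variance
  criterion is the shipped default.
* **Watershed**: Euclidean distance transform, markers at local maxima
  separated by ≥ 0.7 × the minimum expected soma radius; the union of
  labels always equals the input mask.
* **Particle selection**: area within [40, 400] μm² and circularity
  4πA/P² within [0.5, 1.0]. The raw circularity of a small digitized disk
  can exceed 1 (perimeter underestimation); since values above 1 are
  physically impossible they are clipped to 1 before bounds checking,
  while the raw value is reported. A contrast floor rejects particles
  whose mean DoG response is below 3 × the robust noise scale
  (1.4826 × MAD) of the DoG image: a global automatic threshold on a
  signal-free image still produces particles from the upper noise tail,
  and only a noise-anchored floor removes them without touching real
  somata (which sit at ≥ 4σ even at SNR 2).

Coordinates use pixel centres, origin top-left, y increasing with cortical
depth, converted to μm at the segmentation boundary. Multiplying the input
by a positive constant leaves detections unchanged (the DoG is linear, the
normalization before CLAHE removes scale, and the threshold and the noise
floor co-scale).

## Geometry

Thickness follows the matched-points procedure: points at 1-μm arc-length
intervals along the deeper boundary, the same number spread evenly along
the shallower one, and the median of index-matched distances. For straight
parallel boundaries of equal length this equals the perpendicular gap
exactly; the construction is rigid-motion invariant to well under 0.1 μm.
An all-pairs variant exists behind a flag for sensitivity analysis only —
its median far exceeds any anatomical thickness because it includes long
diagonals, which is why the matched reading was adopted.

Layer assignment interpolates each boundary's depth at the point's lateral
position; a point between boundaries i and i+1 belongs to layer i, and a
point exactly on a boundary belongs to the layer above it (toward the
pia) — an arbitrary but documented and deterministic tie-break. Areas are
exact polygon areas (shoelace, via shapely) of the inter-boundary regions
clipped to the ROI, so per-layer areas partition the ROI area to numerical
precision and per-layer counts partition the total count exactly.

## Spatial statistics

**NND** is the Euclidean distance from each source-type point to its
nearest target-type point (self excluded when types match); the statistic
is asymmetric across types and is reported per ordered pair. **No edge
correction is applied by default.** This matches common practice for the
measurement but carries a real bias: on a 1×1 mm window at 100 cells/mm²
the uncorrected mean NND sits ≈ 4–5% above 1/(2√λ), because boundary cells
cannot see neighbours outside the window. A reduced-sample (border-margin)
option discards source points within a configurable margin of the
boundary; with a margin of ~2/√λ the closed forms are recovered to well
under 1%, and the closed-form recovery tests use that estimator on a
2×2 mm window. CV uses the sample (n−1) standard deviation.

**Double positives**: cross-type pairs closer than the measured soma
radius are merged one-to-one, greedy nearest-first (deterministic
tie-break by index), into a double-labelled point at the first member's
coordinates. Greedy matching was verified against a definitional
exhaustive oracle on small configurations.

**PCF**: for ordered pairs (within-type pairs counted in both orders),

ĝ(r) = Σᵢⱼ κ_h(r − dᵢⱼ) wᵢⱼ / (2πr λ̂_A λ̂_B |W|),

with κ_h the Epanechnikov kernel of half-width h, λ̂ = count/area, and
translation edge-correction weights wᵢⱼ = |W|/|W ∩ W_shifted| (closed form
for rectangular windows, polygon intersection otherwise; Ripley's
isotropic circle-fraction correction is available, and "none" for toroidal
or pre-corrected data). Default bandwidth is Stoyan's rule h = 0.15/√λ̂
(15 μm at 100 cells/mm²); the default r grid is 1-μm steps up to a quarter
of the window extent, and grids beyond half the extent are trimmed with a
warning. Using λ̂² rather than n(n−1)/|W|² leaves a small (~1/n) downward
bias, visible as mean ĝ ≈ 0.99 in CSR calibration — well inside the
calibration band and kept for fidelity to the stated estimator. Estimates
from fewer than 10 points per type are flagged unstable, not suppressed.
Pair accumulation is chunked in a fixed order, so for small patterns the
vectorised path is bit-identical to a direct O(n²) transcription of the
definition (asserted in tests at n ≤ 50).

An optional constant offset re-expresses the r axis as distance from the
cell-body edge by subtracting a supplied soma radius; the estimate itself
is unchanged.

**Envelopes**: n_sim ≥ 39 null patterns with the observed counts, types
and window (cross-type null: independent CSR redraws by default, or label
permutation over fixed locations). Pointwise bands are the 2.5/97.5
percentiles across simulations — correct for statements about a single
distance. For statements about the curve *everywhere* ("inside the band at
all r"), pointwise bands cannot have the right coverage — kernel smoothing
makes excursions band-wide, so a null curve exits a pointwise band
somewhere on the grid far more often than 5% of the time — so a
simultaneous option calibrates the studentized maximum deviation over the
grid to the 95% level of the null curves, and the tests verify its all-r
coverage by simulation. The cross-type independence check uses the
simultaneous envelope; the inhibition check (a pointwise dip below the
band over the hard-core range) uses the pointwise one.

**Averaging**: unweighted pointwise means, applied twice — technical
replicate ROIs within an animal, then animals within a group — so an
animal with one ROI counts as much as an animal with three. Scalar metrics
aggregate the same way; ROIs where a metric was incomputable (e.g. too few
cells of a type) are averaged over the available ROIs with the
contributing count logged. The per-animal table is the unit intended for
external hypothesis testing; the package deliberately emits tidy CSVs
rather than re-implementing the routine tests.

## Blinding and provenance

File names map to random hex codes, bijectively and reproducibly under a
seed; codes are re-rolled if they would contain any group name as a
substring. Every pipeline run can write a manifest with the resolved
configuration, seed and software version.

## Problem sizes used in the checks

Calibration and detection checks run at desk scale, chosen to keep Monte-
Carlo error comfortably below the asserted tolerances: 100 simulated
patterns for PCF calibration and envelope checks (λ = 100 cells/mm²,
1×1 mm windows), 200 replicates per intensity for NND closed forms
(2×2 mm windows), 50-soma rendered scenes at 1 μm/px with ~200 clutter
segments for segmentation recovery, and 20 replicates of a 2-group ×
3-mouse × 3-ROI study for the end-to-end laminar contrast.

## Known limitations

* The PCF assumes a homogeneous intensity across the ROI; cortical ROIs
  have laminar intensity gradients, which bias ĝ upward at distances
  comparable to the laminar scale. The estimate is reported as-is (no
  inhomogeneous correction), matching standard practice for these fields
  of view.
* NND without border correction is biased upward near window edges (see
  above); the default is kept for comparability and the corrected option
  documented.
* Segmentation operates on a single 2-D projection; overlapping somata in
  z and densely packed cells touching in-plane beyond what the watershed
  can split are under-counted.
* The renderer's clutter and noise are stationary; real staining
  variability can defeat a single global threshold even after CLAHE, which
  is why detections remain reviewable via the editable CSV.
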