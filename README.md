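# neuromosaic

Laminar quantification and spatial point-pattern statistics for labelled
neurons in cortical sections.

Locally projecting neurons — cortical interneurons such as the
parvalbumin- (PV) and somatostatin- (SST) expressing subclasses — act
through short-range connections, so *where* their cell bodies sit governs
what they can do. Quantifying their arrangement takes three steps, and this
package implements all of them as a reusable, scriptable pipeline:

1. **Detection** — convert fluorescence z-stacks into cell centroid
   coordinates: median intensity projection of 4 consecutive optical slices
   (an 8-μm optical section), difference-of-Gaussians band-pass
   (σ₂ = 2σ₁), contrast-limited adaptive histogram equalization, global
   automatic thresholding, distance-transform watershed, and particle
   selection on size and circularity (4πA/P²).
2. **Laminar registration** — assign each cell to a cortical layer
   (L2/3–L6; L1 is excluded because PV and SST cells are absent there)
   from manually drawn boundary polylines, and compute layer areas,
   thicknesses (median of matched 1-μm-interval boundary-to-boundary
   distances), densities (cells/mm²) and laminar fractions.
3. **Spatial statistics** — nearest-neighbour distances (NND) within and
   across types, the coefficient of variation CV = sd/mean of the NND as a
   regularity index, double-positive merging (cross-type pairs closer than
   the soma radius), and the kernel-smoothed pair correlation function

   g(r) = observed pair density at separation r / λ² (CSR expectation),

   estimated with an Epanechnikov kernel and translation edge correction.
   g(r) = 1 under complete spatial randomness, < 1 for spatial inhibition,
   > 1 for clustering; Monte-Carlo CSR envelopes (pointwise or
   simultaneous) provide the randomness reference. Estimates average
   ROIs → animal → group, so each animal carries equal weight.

A first-class synthetic-data module generates point processes with known
structure — homogeneous Poisson (CSR), Matérn type-II hard-core
(inhibition) and Thomas cluster processes — inside layered annotations, and
renders them into noisy fluorescence-like image stacks with ground truth,
so every stage of the pipeline is testable against closed forms.

## Worked example

Simulate a hard-core ("mutually repelling") cell population, test it
against randomness, and quantify a programmed laminar profile:

```python
import numpy as np
from neuromosaic import (
    rectangle_window, SimulationSpec, simulate_matern_ii, nnd, csr_envelope,
    make_layered_annotation, sample_layered_pattern, laminar_summary, CSR_NND_CV,
)

win = rectangle_window(1000, 1000)  # 1 mm² field, μm coordinates
pv = simulate_matern_ii(SimulationSpec(
    "matern_ii", intensity=200.0, window=win, seed=7, inhibition_radius=30.0))
print(pv.n)                         # 159 cells retained after thinning

res = nnd(pv)
print(res.mean, res.cv)             # 51.1 μm, CV 0.332  (CSR reference: 0.523)

est = csr_envelope(pv, n_sim=99, seed=1, r=np.arange(2.0, 101.0, 2.0))
# ĝ(10)=0.000, ĝ(20)=0.028, ĝ(40)=1.007, ĝ(80)=0.959
# ĝ below the 95% CSR envelope everywhere below the 30-μm core: True
```

The CV well below the Poisson value 0.523 and ĝ(r) ≈ 0 below 30 μm (then
returning to 1) both read out the programmed spatial inhibition — the same
signature that distinguishes regular within-type spacing from cross-type
randomness in real material.

```python
ann = make_layered_annotation([300, 200, 350, 350], width=1000, waviness=15, seed=0)
pat = sample_layered_pattern(ann, [40.0, 60.0, 150.0, 60.0], seed=11)
print(laminar_summary(pat.points, ann).table)
#  layer  count  area_mm2  density  fraction  thickness_um
#   L2/3     14      0.30   46.667     0.156       300.267
#     L4     15      0.20   75.000     0.167       199.929
#     L5     44      0.35  125.714     0.489       351.457
#     L6     17      0.35   48.571     0.189       349.846
#  total     90      1.20   75.000     1.000      1196.531
```

Counts partition exactly, fractions sum to 1, densities recover the
programmed intensities up to Poisson noise, and the L5 majority mirrors the
laminar profile typical of these cell classes.

## Command line

```bash
neuromosaic simulate --process csr --intensity 100 --seed 1 --out pattern.csv
neuromosaic segment stack.tif --out cells.csv          # TIFF + JSON sidecar
neuromosaic analyze cells.csv annotation.json --out-prefix roi1
neuromosaic blind manifest.csv --seed 7 --out-manifest coded.csv --out-map key.json
neuromosaic aggregate per_roi.csv --out-prefix study    # ROIs → mouse → group
```

Patterns travel as CSV (`x_um, y_um, type, layer`), annotations as JSON
(ROI polygon + named boundary polylines), images as multi-page TIFF with a
JSON calibration sidecar.

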