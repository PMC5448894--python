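# filatrace

Automatic quantification of actin stress fibers in 2-D fluorescence
micrographs, plus cell-shape morphometry and a synthetic-scene generator
with exact ground truth.

Cells reorganise their actin cytoskeleton in response to substrate
topography (contact guidance). Assessing that response quantitatively
requires turning a phalloidin-stained confocal image into numbers: how
many filaments, how long, and how strongly oriented. `filatrace`
implements an automatic three-step pipeline for this task, intended for
cell biologists and biomaterials researchers who want reproducible,
parameter-audited filament statistics instead of manual tracing.

## Method

**1. Preprocessing.** Intensities are min-max normalised, denoised by
ROF total-variation regularisation (weight λ), and freed of irregular
background illumination by a morphological white top-hat
(image − opening with a flat disk of radius *r* ≫ filament half-width).

**2. Feature detection (predictor–corrector).** Bright filaments are
intensity ridges, where the digital Laplacian Δu = u(i±1,j) + u(i,j±1) −
4u(i,j) is strongly negative. The *predictor* thresholds the ridge
strength −Δu at a quantile *q* of its positive values; the *corrector*
validates, for every 8-adjacent pair of candidate pixels, the straight
segment between them by the mean concavity of the bilinearly
interpolated relief perpendicular to it: at *m* points along the
segment, c = u(−h) − 2u(0) + u(+h) is averaged and the segment is
accepted when mean c ≤ −κ. Redundancy is avoided by successively
reducing the candidate set by pixels already represented, and endpoints
are refined to subpixel positions by parabolic peak interpolation.

**3. Quantification.** Accepted segments are fused into a *feature
graph* — nodes are endpoints, bends and branching points; edges are
maximal straight parts. Superpositions are disambiguated by decomposing
the edge set into *edge trails* (each edge used exactly once) under the
single-filament model: no bend enclosing less than 135°, and minimal
in-trail curvature (total turning Σ(180° − enclosed angle)) among all
feasible decompositions, with the fewest possible trails. Each trail is
one filament. Reported per image:

* filament number, total / average / maximum filament length (µm);
* length-weighted axial orientation statistics of the straight parts:
  angles are doubled (axial data), the weighted resultant
  R = |Σ wᵢ e^{2iθᵢ}| / Σ wᵢ gives the von Mises fit µ (preferred axis)
  and κ = A₁⁻¹(R) (concentration), and the **orientation dispersion**
  d = (1 − R) · 28.6479° — 0° means exactly one preferred orientation,
  28.65° a uniform distribution of oriented length.

Cell-shape morphometry is included: area A, perimeter P (marching-squares
contour) and the form factor 4πA/P², which is 1 for a perfectly round
cell and decreases toward 0 with elongation.

## Worked example

Render a synthetic scene of 4 filaments with exact ground truth, then
quantify it at a calibration of 0.2 µm/pixel:

```sh
$ filatrace synth --n-filaments 4 --seed 42 --out demo
rendered 4 filaments, total 296.46 um -> demo

$ filatrace quantify demo/scene.tif --pixel-size 0.2 --out demo_out
    image  filament_number  total_length_um  average_length_um  max_length_um    mu_deg    kappa        R  dispersion_deg
scene.tif                4        59.864192          14.966048       15.90592 73.306923 0.435829 0.212907       22.548564
```

All 4 filaments are recovered; the total length of 59.86 µm compares to
the ground-truth 296.46 px × 0.2 µm/px = 59.29 µm (1% error). The weak
resultant R = 0.21 and dispersion 22.5° (close to the uniform limit
28.65°) say the four randomly oriented filaments share no preferred
axis. `demo_out/` also contains the metrics CSV, a graph overlay PNG and
the mirrored polar histogram with the von Mises fit.

Recovery can be scored automatically against ground truth:

```sh
$ filatrace bench --scenes 5 --seed 3 --out bench
...
exact filament-count recovery: 80% of scenes; mean |total length error| 3.5%
```

`filatrace morpho masks.png` reports per-cell area, perimeter and form
factor for binary masks; `filatrace aggregate metrics.csv --group-column
group` summarises groups as mean ± sample SD.

The library API mirrors the CLI: `filatrace.quantify(image, RunConfig())`
returns metrics, orientation statistics, the feature graph and the
trails; `filatrace.render_scene(SceneSpec(...))` produces images with
ground truth.

## Acceptance script

`scripts/acceptance.py` recomputes the analytic orientation-dispersion
anchors from scratch by running the package's orientation statistics on
constructed part sets (perfect alignment, and axially uniform angles)
and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
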