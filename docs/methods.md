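# Methods

## Cone-growth model

A pile poured from a point source is idealized as a right circular cone
whose flank makes the static angle of repose α (degrees from the
horizontal) with the base.  The radius–height relation is r = h / tan α —
steep materials build narrow piles — which gives V = π h³ / (3 tan²α) and,
inverted, h = (3/π)^{1/3} tan^{2/3}(α) V^{1/3}.  With constant volumetric
feed (V ∝ t) the height, and any image observable proportional to it,
follows y = a + b tᶜ with c = 1/3.  The exponent is therefore a shape
descriptor of flow: c near 1/3 indicates free conical growth, larger c a
more cylindrical, stacking pile.  `geometry_coefficients` exposes the
unit-scale proportionality factor b_geom = (3/π)^{1/3} tan^{2/3}(α); the
pixel-per-volume calibration of a particular rig multiplies it and is left
to the caller.

The Brown–Richards orifice rate Q = K·A·√(2gh)·ρ_t supplies a physically
motivated default feed rate for simulations; no other orifice correlation
is implemented.

All angles are degrees at the API surface and radians internally,
converted only at the boundary.

## Imaging procedure

Frames are binarized into bright (particle) and dark (background) pixels.
The default method is Otsu's global threshold — the rig's black background
with forward illumination yields strongly bimodal histograms — with a
fixed-threshold override.  When a whole stack is processed
(`slice_area_series`), a single threshold is derived from the final,
fullest frame and applied throughout: illumination is constant over a
recording and early frames of an off-center band are entirely dark, where
a per-frame histogram split is undefined.

Each frame is cut into `n_slices` equal vertical bands (default 32;
160 px wide frames give 5-px bands).  The flow curve is the bright-pixel
count of one fixed band per frame, at times k/fps (default 25 fps).  The
default band starts from the slice just left of center and moves a further
1/8 of the frame width toward lower columns (32 slices → index 11): the
central bands are occupied by the falling feed jet, while bands too far
out receive material late.  The index is a configuration knob; the exact
slice used in the original rig is not documented, so this default is the
package's own choice, validated on simulated stacks where the jet band is
rendered explicitly.

Static angle of repose: the surface height of the final pile is taken per
column (topmost bright pixel, measured up from the bottom row), split at
the apex, and each flank is fitted by least squares.  The top 10% of the
pile height is excluded (apex rounding) as are columns with fewer than
2 px of material (base spreading); the result is the mean absolute slope
angle of the two flanks.  On rendered wedges at 128 × 160 this recovers
the input angle well within 0.5° for α ∈ [25°, 45°].

Flow time is the time of the first frame from which the curve stays within
0.5% of its final value for at least 25 consecutive frames (1 s at 25 fps)
through the end of the recording; a curve that never settles raises an
error rather than returning a guess.

The Crofton perimeter uses the standard 4-direction intercept weights
(as implemented in scikit-image).  Discretization makes it slightly
direction-dependent: digital disks are estimated within ~1% at r = 50 px
(error shrinking with radius), while axis-aligned rectangles are the worst
case at just under 6% low.  Sphericity ψ = 4πA/P² therefore occasionally
exceeds 1 on pixelated near-circles; such values are clamped to 1 with a
warning.  Classification: pellet if ψ > 0.91, granule if ψ ≤ 0.90; the
undefined gap (0.90, 0.91] is resolved as granule with a warning rather
than an error.

## Power-law fitting and avalanche statistics

`PowerLawRegressor` minimizes Σ(y_k − a − b t_k^c)² with
`scipy.optimize.least_squares`, an analytic Jacobian, and box bounds
c ∈ (0.05, 1.5).  Initialization: a₀ = first area, c₀ = 1/3 (the
geometric limit), b₀ = (y_last − y_first)/t_last^{1/3}; on
non-convergence a multi-start over c₀ ∈ {0.25, 1/3, 0.5} keeps the best
residual sum.  t = 0 contributes (y₀ − a)², i.e. 0^c = 0.  Standard
errors come from the Jacobian at the optimum with variance RSS/(n − 3).
The pipeline default fits from the first frame with nonzero area: before
material reaches the band the model does not apply, and for recordings
with a measured flow time the fit window can be truncated there.

AUFC is the trapezoidal integral of area against **frame index**, not
seconds — the same frame-unit convention used for avalanche wavelengths
(1 frame = 0.04 s at 25 fps) — which keeps reported magnitudes on the
conventional scale for ~500-frame recordings.

Avalanches are counted on the detrended residual: a local maximum with
prominence ≥ 2 px (configurable) followed by a relaxation drop, peaks at
least 5 frames apart.  Amplitude is the peak-to-trough drop before the
next peak; wavelength is the frame gap between successive peaks (the mean
is defined only with ≥ 2 events).  Peak-to-peak spacing was chosen over
zero-crossing spacing; both thresholds are explicit parameters because no
standard operational definition exists for counting avalanches on such
curves.  The series is padded with its minimum so a leading plateau that
steps down counts as one event.

## Simulator

The simulator provides ground truth at every stage, with all randomness
driven by an explicit seed (bit-for-bit reproducible).

*Flow curves*: trend a + b tᶜ with the triple taken from the cone geometry
(or prescribed directly), plus an optional stick–slip sawtooth — the flank
steepens linearly, then sheds a wedge, dropping the curve by a fixed
amplitude at slip times whose periods are shifted-Poisson distributed with
an enforced minimum gap — plus optional Gaussian pixel noise.  This is the
simplest caricature of self-organized critical slipping, not a
particle-level (DEM or cellular-automaton) model: amplitudes are constant
per run and the trend is exact between slips.

*Pile stacks*: binary {0, 255} triangular silhouettes, apex under the
nozzle column, flank slope α, no anti-aliasing, so slice areas are exactly
countable; an optional bright central jet band exercises the slice-choice
logic.  Default geometry is the rig's 128 × 160 px at 25 fps.  The default
feed rate (5 × 10⁴ px³/s of cone volume) grows the pile to roughly 60–85%
of the frame height over a 12–20 s run, as on the physical rig where the
charge fills most of the field of view; a pile exceeding the frame raises
an error.  The pile footprint may be clipped by the frame edges (also true
of the rig); the ground-truth silhouette area accounts for the clipped
tails.  What the renders do **not** emulate: partial-intensity edges,
illumination gradients, camera noise beyond additive Gaussian on the
curve, inter-particle texture, and 3-D perspective — so passing tests
demonstrate correctness of the measurement chain, not robustness to real
video artifacts.

*Particles*: disks, ellipses, and radially perturbed blobs (random
harmonics 2–7 of relative amplitude `roughness`), with the continuous
outline's sphericity (shoelace area, polyline perimeter) returned as
ground truth alongside the rasterized mask.

*Design responses*: y = Σ coeff·term(coded factors) + N(0, σ) for any
linear/2FI/quadratic term set.

## Design of experiments

The packaged 24-run design crosses three numeric factors with a two-level
categorical factor.  Each categorical block is a 2^{3−1} half-fraction
with defining relation I = −x1·x2·x3, six axial runs, and two center
points; `build_ccd` constructs this layout by default (a full-factorial
option exists).  Coding is (actual − center)/step with particle size
725 ± 375 μm and moisture 2 ± 1%; the glidant ratio is tabulated already
coded; axial actuals are taken verbatim (so the size axial codes to
±1.414, the others to ±1.4).

Models are OLS on the coded model matrix: linear, 2FI (all pairwise
interactions), or quadratic (adding squares of numeric factors only — the
square of a ±1 categorical column is aliased with the intercept and is
excluded).  Per-term two-sided t-tests use the residual degrees of
freedom with no multiple-testing correction; the design is orthogonal, so
sequential and partial sums of squares coincide.  Predicted R² is
PRESS-based via the leave-one-out closed form e_i/(1 − h_ii); it is
negative for the intercept parameter *a* of the study data, meaning the
response mean outpredicts the model.  `reduce_model` performs backward
elimination (drop the largest p-value above α = 0.05, refit, repeat),
preserving hierarchy: a main effect stays while any of its interactions
or its square remains.

Because the categorical column is orthogonal to every other model column,
its coefficient equals half the difference of the two group means in any
of these model forms; the test suite verifies this against direct group
arithmetic for every packaged response.

Published intercepts are reported but not asserted: the printed intercept
of the avalanche-wavelength model (21.15) differs from the packaged-table
column mean (21.08), indicating estimation details (run weighting or
rounding) in the original analysis software that the printed data do not
determine.  Slope coefficients reproduce to the printed precision.  The
published correlation table is reproduced for the fitting parameters and
empirical measurements; its avalanche-amplitude row, however, is
internally inconsistent with the published per-run amplitude column
(differences up to 0.41 in r), and pairs involving the exponent c drift by
~0.01–0.03 because c is printed to two decimals.  The corresponding
acceptance test records this discrepancy rather than hiding it.

## Problem sizes

Test and demonstration runs use 300–500-frame recordings at 25 fps,
128 × 160 px renders, 200-replicate recovery studies, and the 24-run
design — sizes chosen to match the study conditions while keeping the
full suite fast on a laptop-class single core.

## Known limitations

- No video container decoding: frames must be pre-extracted PNG/TIFF.
- All areas are in pixels; no mm-per-pixel calibration is applied.
- The avalanche count/amplitude definitions are the package's
  operationalization; absolute counts from other software will differ
  even on identical curves.
- The proportionality constant linking b to the geometry is
  rig-dependent; only the unit-scale factor is computed.
- Non-conical pile shapes and 3-D reconstruction are out of scope.
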