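# Methods

This note records the measurement model implemented by `pupilkit`, the
parameter choices that matter, and the limits of what the synthetic
fixtures can demonstrate.

## The pupil measurement model

Each frame is an 8-bit grayscale image in which the pupil is the darkest
extended object (IR retro-illumination imaging; black-on-white phantoms
reproduce the same contrast regime). The per-frame estimate is the
*equivalent ellipse* of the pupil boundary, obtained by five stages:

1. **Median smoothing, 5×5.** Rank filtering suppresses impulsive sensor
   noise without displacing step edges. Borders are edge-replicated. The
   default path is a sliding-histogram (Huang) implementation compiled
   with numba when available; it is bit-identical to
   `scipy.ndimage.median_filter(mode="nearest")`, which is the fallback,
   and the equivalence is asserted in the test suite.
2. **Global threshold at the mean intensity**, computed from the 256-bin
   histogram. Pixels strictly below the mean are pupil candidates. With a
   small dark pupil in a bright field the mean sits far above the pupil
   mode, so the classification is stable from frame to frame; bright
   corneal reflections inside the pupil fall above the threshold and
   become holes at this stage.
3. **Closing, hole filling, largest component.** Closing with a Euclidean
   disk (radius 5 px at the native 1024² scale, scaled proportionally for
   smaller frames) bridges notches the reflection spot can cut into the
   pupil rim; hole filling makes enclosed reflection holes solid; the
   largest connected component discards stray dark specks. The disk
   radius trades off bridging power against shape distortion: radius 5
   bridges a radius-8 interior spot's rim contact while leaving a 119-px
   pupil's convex outline untouched (closing is the identity on convex
   regions). Implementation detail: the closing is computed by two
   distance transforms on a bounding-box crop with a `radius + 1` margin,
   which is exactly the footprint-based closing (closing is local), just
   cheaper.
4. **Inner boundary.** Component pixels with a 4-neighbor outside the
   component; their centers `(j + 0.5, i + 0.5)` are the boundary
   coordinates. Pixel `(i, j)` has center `(x, y) = (j + 0.5, i + 0.5)`;
   this convention is used identically by rendering and extraction.
5. **Direct least-squares ellipse fit.** The conic
   `Ax² + Bxy + Cy² + Dx + Ey + F = 0` minimizing the algebraic residual
   under the ellipse constraint `4AC − B² = 1`, solved by the stabilized
   block decomposition of the scatter matrix on mean-centered data. The
   fit is deterministic, needs no initialization, and is exact (to
   numerical precision, verified at 1e-6) on noiseless samples of an
   analytic ellipse. A geometric-distance minimizer exists only as a test
   oracle; on low-noise boundaries the two agree within 0.2 px.

A failure at any stage (empty mask, too few boundary points, degenerate
conic) produces an *invalid* result with a reason, never an exception, so
blinks and occlusions pass through sequence processing as flagged gaps.

### The fencepost: why a 119-px phantom measures 118 px

Rasterization marks a pixel dark iff its center is inside the analytic
shape, and the boundary is the set of dark pixel centers. The extreme
centers of a diameter-`d` disk therefore span `d − 1` pixel units, and
the least-squares ellipse through the whole boundary ring lands within a
few hundredths of a pixel of `d − 1`. Every noise-free validation phantom
consequently fits to its axis minus one pixel (119→118, 160→159, …,
321→320), a relative deviation of at most 1/119 ≈ 0.84 % < 1 %. Axes are
rounded to integer pixels only at the reporting layer; internal values
stay continuous.

## Time series

- **Demultiplexing** trusts eye labels (from filenames or metadata) or an
  explicit even/odd phase; eye identity is never inferred from image
  content. Per-eye rates are capped at 75 Hz, the acquisition limit at
  full resolution.
- **Blink repair.** Samples flagged invalid by segmentation, plus valid
  samples whose major axis deviates from the centered moving average
  (window 1 s by default) by more than 3 local SDs, are replaced by the
  mean of the nearest valid neighbors on each side within the window
  (one-sided at the edges; nearest-valid fallback for wider gaps). The
  local SD is floored at 0.01 px so a flat trace cannot flag numerical
  dust. The operation is idempotent and is the identity on clean traces.
  The window length and the 3-SD criterion are this package's defaults,
  chosen so that 200-ms blinks at 75 Hz (≈15 samples) are repaired with
  RMSE below 2 % of the baseline diameter against simulator ground
  truth; they are deliberately configurable.
- **Unit conversion** multiplies axes and centers by the mm-per-pixel
  calibration ratio. Because floating multiply/divide is not exactly
  invertible, a converted trace carries its pre-conversion table and the
  inverse restores it bit-identically.

## Stimulus generation

Waveforms are sampled at `t_k = k/rate` over `[0, duration)`, dark before
onset, and bounded by `[0, luminance]` with luminance validated against
the 1–100 cd/m² hardware range. The sinusoid is a raised cosine (starts
dark, mean = luminance/2 over whole periods); triangle and rectangle are
standard 50 %-duty forms; ramps are linear over the active span; the
pseudorandom shape — not further specified by stimulator hardware
conventions — is implemented as a seeded staircase with uniform levels
and a configurable hold interval (default 0.5 s), documented as an
interpretation. Frame triggers fire at `k/rate` on the half-open
recording interval, and stimulus on/off events snap to the first trigger
at or after their requested time, since the control pulse rides the
trigger's rising edge; an onset of 2.003 s at 75 Hz therefore fires at
frame 151 (2.0133… s). Alternating-eye programs expand into disjoint
left/right half-period segments, so left and right stimulus events never
overlap.

## The acquisition noise model

`AcquisitionModel` replaces print-and-capture with: Gaussian blur
(σ = 0.5 px), subpixel translational jitter (SD 0.3 px/axis), a slow
sinusoidal illumination drift (4 intensity levels peak-to-peak per
sequence), additive Gaussian noise (SD 2 levels), clipping to [0, 255].
All randomness flows from one seed; sequences are bit-reproducible.

The blur scale is the one parameter that interacts with the threshold
rule, and it was fixed analytically. Mean-intensity thresholding cuts a
blurred step edge not at its midpoint but where the profile crosses the
image mean: for a dark fraction `f`, at `Φ⁻¹(1 − f)·σ` *outside* the true
edge. For the smallest calibration phantom (271 px in 1024², f ≈ 0.055)
that is ≈1.6σ per side, i.e. a diameter inflation of ≈3.2σ px. Against
the −1 px rasterization fencepost, σ = 1.0 would bias the measured size
by ≈ +0.8 %, breaching the protocol's 0.5 % accuracy budget; σ = 0.5
keeps the worst-case bias ≈ +0.36 % with the bound respected for all six
sizes. The default is therefore 0.5 px.

Because these numbers characterize direct rendering plus this noise
model, the validation results are properties of the *software pipeline*,
not of any optical train: a physical instrument adds contrast loss,
print texture, and optical distortion that this model does not attempt.

## Validation protocol

- **Software test**: the 16 noise-free phantoms (six circles 119–321 px,
  five ellipses each way), each also in a reflection-spot variant that
  must yield identical rounded axes. Any invalid fit fails the test.
- **Repeatability experiment**: per phantom, 5 runs × 100 frames through
  the noise model (run `r` seeded `seed + r`; phantom `i` offset by
  `1000·i` from the top-level seed). Per frame the size statistic is the
  mean of the fitted major and minor axes; per run its mean ± SD; across
  runs the mean of means ± SD of means. **Accuracy** is
  `|overall mean − true| / true × 100`; **repeatability** is
  `SD of run means / overall mean × 100` (the pooled per-frame SD is
  exposed as an alternative statistic). Runs with >10 % invalid frames
  flag the entry. Under the default model all six phantoms come in below
  0.5 % accuracy and far below 4 % repeatability.
- **Linear resolution**: `true_mm / measured_px` per printed phantom;
  the six ratios (3.01/271 … 7.70/693) agree within 2 % at ≈0.0111
  mm/px.

## The PLR simulator

Per eye, diameter relaxes toward `baseline·(1 − gain·u_eff)` where
`u_eff = u_own + consensual_gain·u_fellow` and `u = log10(1 + L)` of the
latency-delayed luminance; the update is the exact exponential step for
piecewise-constant drive, with τ = 0.4 s while constricting and 1.2 s
while redilating. Defaults: baseline 300 px (≈3.3 mm at the instrument's
≈90 px/mm), gain 0.15 per decade, latency 0.25 s, consensual gain 0.9 —
round physiological magnitudes chosen once for plausible-looking
pupillograms. Hippus is Gaussian noise FFT-band-limited to 0.05–0.5 Hz,
scaled to a target SD and shared between the eyes. Rendering draws the
pupil dark (10) on a faint iris (235) against a bright field (255); the
iris is deliberately low-contrast so that mean thresholding isolates the
pupil as the only dark object, which is the contrast regime the
instrument's IR illumination is set up to produce. Blinks render as a
uniform bright lid.

This model is a test fixture, not physiology: no ipRGC/melanopsin
sustained component, no chromatic mechanisms, no amplitude saturation,
no gaze or head movement. End-to-end tests on its output (recovery of a
scripted pulse response with correlation >0.99 after blink repair,
max error <1 px noiseless) therefore demonstrate the *pipeline's*
correctness on known geometry, not performance on human recordings.

## Problem sizes and numerical choices

The repeatability protocol runs at full scale (six phantoms × 5 × 100
frames at 1024²); simulator-based end-to-end tests use 256² frames at
25 Hz, where the closing radius scales to 1 px and the fencepost behaves
identically. Reported axes round half away from zero only in validation
reports. Orientation is normalized to (−π/2, π/2]; for near-circular
fits it is numerically arbitrary, and screen-axis attribution in the
software test assigns the major axis to x when |θ| ≤ π/4. Degenerate
inputs (fewer than 5 boundary points, collinear sets, non-elliptical
conics) yield invalid results with reasons rather than raising.

## Known limitations

- Mean-intensity thresholding assumes the pupil dominates the dark tail;
  heavy eyelashes, mascara or deep shadows would join the dark class and
  can defeat the largest-component rule. The curvature- or
  gradient-based artifact rejection found in other systems is out of
  scope.
- The acquisition model has no optical PSF, print texture, perspective
  or distortion terms; accuracy numbers transfer to hardware only after
  a physical calibration.
- Blink repair interpolates; it cannot recover genuine dynamics hidden
  under long occlusions, and traces that are mostly invalid raise rather
  than guess.
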