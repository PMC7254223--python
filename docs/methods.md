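# Methods

## Snap processing

Each frame is reduced to a particle count and mean cluster size by a white
top-hat transform (frame minus its grayscale opening), thresholding, and
8-connected component labeling.

**Structuring element.** A binary disk whose diameter is the "TopHat
width" parameter: pixels within radius `(width − 1) / 2` of the center, so
width 1 is a single pixel and width 3 the 5-pixel plus. This matches the
scikit-image disk convention and the odd widths used in practice (13, 15).
Grayscale (flat) morphology is used, not binary, because the top-hat
subtraction operates on intensities. The opening is anti-extensive and
idempotent; both properties are enforced by tests against a brute-force
sliding-min/max oracle with border clipping (equivalent to ±∞ padding),
which is exactly scikit-image's border behavior.

**Mask order.** The circular contact mask is intersected with the
*binary* image after thresholding, not multiplied into the raw frame
before the morphology. Zeroing the frame outside the circle first would
create an intensity step at the rim; the opening collapses to zero within
one SE radius of such a step, so the top-hat would return the entire
background level there and the threshold stage would emit a spurious
bright ring — a single giant "particle" hugging the rim in every frame.
Intersecting at the binary stage confines detections to the contact
without manufacturing rim artifacts. `apply_contact_mask` (zero outside
the disk) is still provided for visualization and as the suppression
primitive.

**Threshold.** Comparison is `≥ τ` (values strictly below the threshold
are suppressed). Raising τ cannot increase the particle count when
features are unimodal and separated, which is the regime the pipeline
operates in; for arbitrary images a rising threshold can split one
component into several, so the monotonicity test uses well-separated
blobs.

**Size metric.** "Average size" is the mean equivalent diameter
`2·√(area/π) · pixel_scale` in μm; per-particle pixel areas are retained.
Components touching the mask rim are kept — the mask already bounds the
region, and no border rule is imposed.

## Friction processing

The friction sensor is preloaded, so the raw channel carries a constant
offset. It is estimated as the mean over the pre-motion static segment
(≥ 10 samples required) and subtracted; the correction is idempotent.
CoF is the rectified ratio `|friction| / normal` — reciprocating motion
flips the friction sign each stroke while the reported CoF is unsigned.
Samples with normal force at or below ε (1% of the configured load, or of
the median normal force when no load is given) are trimmed. The CoF trace
is computed over the motion span only: the endpoint windows are windows of
the CoF *trend during sliding*, and including the static segment (CoF ≈ 0
after offsetting) would corrupt the first window.

Smoothing is a centered moving average (default 51 samples, odd; the
window shrinks at the edges). The endpoint statistic is computed on both
the raw and the smoothed trace and both are recorded; the smoothed value
is the reported one. The percentage is normalized by the first-window
mean — the initial state is the natural baseline — and the direction
("increase"/"decrease") follows the sign of last-minus-first; a zero
change reports 0%-increase.

## Cycle analytics and calibration

One cycle is one stroke-long pass, so the cycle period is
`stroke / velocity` (2 s under the default 20 mm / 10 mm/s conditions, and
`stroke × n_cycles` is the planned total distance, 1200 mm for 60 cycles).
Per cycle, the sample nearest the temporal midpoint `(k + 0.5)·period`
(earlier sample on ties) represents the cycle, avoiding stroke-turnaround
artifacts. The six-cycle statistic applies the endpoint deviation to these
mid-cycle samples with a window of six cycles.

**Slope normalization.** Comparing the "tangent direction" of a particle
count trend with a fluorescence-intensity trend requires a scale-free
slope. The OLS slope is divided by the fitted value at the first
timestamp (the OLS intercept), giving fraction-of-baseline per second.
This is exact on linear data — `y = b(1 − 0.1 t/T)` yields `−0.1/T` for
any `b` — and strictly scale-invariant, unlike dividing by an early-window
mean, which is only approximately the baseline on a decaying series.

**Calibration.** The sweep shares top-hat computations across thresholds
of the same width for speed. Settings whose percent-decrease direction
contradicts the sign of the intensity slope are eliminated (a sign test:
no numeric cutoff is defined for the knockout line); among survivors the
setting minimizing `|normalized count slope − normalized intensity slope|`
is chosen, ties broken toward smaller width, then smaller threshold. The
selection provably equals exhaustive minimization and is tested against an
independent re-implementation. The default grid (widths 9–19, thresholds
2–6) brackets the published working points 15/4 and 13/4; the intensity
reference is the mask-mean (the choice between mean and summed intensity,
mask or full frame, is not fixed by the source instrument; mask-mean is
recorded in the output metadata).

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes,
not the optics. A frame is the clipped, uint16-rounded sum of a flat
background (default 40 native units), spatially correlated "pore" noise
confined to the contact disk (σ = 2, Gaussian correlation length 3 px),
and isotropic 2-D Gaussian clusters (peak amplitude 30 → SNR 15, diameter
6 ± 1 px, Gaussian σ = diameter/4), all scaled by a global photobleaching
factor `exp(−λt)` (λ = 2.5·10⁻³ s⁻¹). Cluster positions are drawn
uniformly in the disk with a minimum pairwise spacing of 3 diameters
(rejection sampling; an overdense request fails loudly); counts follow a
linear (default) or exponential schedule from N₀ = 40 to `f_end·N₀`
(default 0.75) with stochastic rounding. Positions are redrawn each frame
— the generator does not model temporal persistence of clusters, particle
tracking across frames is out of scope. Frame geometry is 256 × 214 px at
1 Hz for 120 s: one-tenth the camera resolution per axis, with frames
landing on cycle midpoints, keeping a full stack desk-fast (seconds) while
preserving the cycle structure of the default conditions (60 × 2 s).

The force log holds the normal load (10 N) with sensor noise
(σ = 0.01 N); friction is `sign(stroke) · μ(t) · load` plus a preload
offset (2.3 N) and noise, after a 5 s static segment. μ(t) ramps from
0.02 to 0.0323 with 10% plateaus at each end, so the 1000-sample endpoint
windows (10 s at 100 Hz) sit on the planted levels and the planted change
is exactly 61.5%.

The static-loading generator ramps the load linearly 0 → 10 N over 12 s
(then holds 18 s) while the planted count falls 120 → 40 and the planted
mean diameter rises 5 → 9 px. This scene is denser than the sliding
fixture, so spacing is relaxed to 1.5 diameters and occasional blob
merging is expected; only trend *signs* are asserted on it.

**What passing tests show.** Recovery on these fixtures demonstrates the
correctness of the measurement chain under the stated noise model. Real
recordings add effects the generator omits — non-uniform illumination,
cluster motion and persistence, out-of-focus light, detector nonlinearity,
threshold units tied to the camera scale — which is why calibration
against the intensity trend is per-recording, and why the published
headline deviations (from unpublished laboratory recordings) are format
references rather than reproduction targets.

## Numerical choices and degenerate inputs

- Threshold units are native camera units; on the synthetic intensity
  scale the working point equivalent to the published setting is
  TopHat 15 / Threshold 10 (half the nominal cluster amplitude, above the
  top-hat noise floor of roughly 5σ).
- Empty frames yield count 0 and an undefined (NaN) mean size; the mean
  size trend skips NaN frames in downstream sign tests.
- `percent_change_endpoints` refuses series shorter than two windows and
  a zero first-window baseline; `percent_decrease_cycles` requires at
  least twelve cycles.
- Cycle assignment is `floor(t / period)`; a period shorter than the
  sampling interval is rejected.
- Timestamps prefer metadata embedded in the TIFF description (written by
  this package); otherwise they are synthesized as `index / frame_rate`.
- CSV round-trips use 17-significant-digit formatting and round-trip
  float parsing, making force-log and result tables bit-exact.
- Seeds: every generator consumes a `numpy.random.default_rng(seed)`;
  sub-generators (force log, static loading) derive `seed + 1`, `seed + 2`.

## Known limitations

- No sub-pixel localization, blob-shape classification, deconvolution or
  image-based photobleaching correction.
- The calibration assumes the intensity trend is monotone enough for a
  sign and a linear slope to be meaningful; heavily non-monotone
  recordings would need a different reference.
- Hertz mean pressure is a generic sphere-on-flat utility; cartilage
  moduli vary strongly between specimens and are inputs, not outputs.
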