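# Methods

This note documents the quantitative procedures implemented in
`synaptodyn`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## Data model

The unit of analysis is a two-channel imaging session: one imaged cell,
60 minutes (240 frames at 15 s, or 360 at 10 s), with per-frame *surface*
observations per channel — centroid (µm), area (µm²), the mean raw
fluorescence of **both** channels measured within the surface outline, and
a detected flag. Surfaces linked over time form tracks. Tracker-bridged
frames (`detected = false`, up to 8 consecutive) carry linearly
interpolated position **and area** but no intensities: position and area
are needed so cross-channel distance remains defined through gaps, while
interpolated intensities would manufacture signal. Tracks spanning less
than 60 s are discarded before analysis.

The bundled greedy nearest-neighbour linker (2 µm frame-to-frame limit,
distance budget scaled by gap length, ties broken by distance then track
id) exists to close the rendering→detection→linking loop in tests. It is a
deterministic surrogate, not a reimplementation of the commercial
autoregressive tracker, and real analyses are expected to ingest exported
track tables instead.

## Registration

Mobility measurements are meaningless if the tissue itself drifts or
deforms. The correction is translation first, deformation second:

1. **Rigid pre-alignment.** Every frame is aligned to frame 0 by
   integer-pixel translation estimated with whole-image phase
   cross-correlation. Feature-based rigid alignment would also work; for
   the small drifts involved, translation is sufficient and deterministic.
2. **Chunked TPS unwarp.** Landmark pairs are picked between the *last*
   frame (maximal accumulated deformation) and the first-frame reference.
   Because deformation accrues roughly linearly, moving landmarks at frame
   f are interpolated as `identity + f/(n−1)·(final − identity)`. The
   movie is split into 30-frame chunks; each chunk is warped by the exact
   TPS (`U(r) = r² log r`, affine part plus radial weights satisfying
   Σw = 0, Σw·p = 0) fitted at its end-frame landmarks, with bilinear
   intensity resampling and zero fill outside the canvas. Fitting each
   chunk against the fixed first-frame reference keeps errors from
   compounding across chunks.

The per-chunk transform is constant within a chunk, so the residual error
scale is the within-chunk landmark drift — with default chunking and
drifts of a couple of pixels per hour this is a fraction of a pixel, which
the round-trip test bounds at < 0.5 px RMSE on rendered spots. Zero
regularization is the default (exact landmark matching); a ridge parameter
is available for noisy landmarks. Collinear or duplicate landmarks are
rejected rather than silently regularized.

## Stability

`stability = (detected frames) / (f_n − f₀ + 1)` over the track's spanned
interval. The inclusive denominator is deliberate: it is the only
convention under which a track detected in every spanned frame scores
exactly 1 regardless of duration, which is the statistic's defining
property (it measures signal consistency, not lifetime). Bridged frames
count toward the span but never the numerator. The 8-frame gap allowance
upstream matters here: without it, unstable puncta would fragment into
short gapless tracks and the metric would saturate at 1.

## Photobleaching and normalization

A single-exponential model `F(t) = A·e^(−kt) + C` (t in minutes, k ≥ 0) is
fitted by nonlinear least squares to the across-puncta mean intensity of
the **control arm only** (each surface contributes its mean intensity per
detected frame; the across-surface mean is the fitted series). This
assumes bleaching is a property of the fluorophore and illumination, not
the treatment, so the same correction
`F_corr(t) = F_meas(t) · F(t₀)/F(t)` applies to both arms — and to a
channel's intensity wherever it is read out, including within
opposite-channel surfaces. Initialization uses the series endpoints and a
log-linear slope; a series that does not decay end-to-end is flagged
`no_bleach` and returned as a flat model rather than a spurious fit.
A fitted model that predicts F(t) ≤ 0 anywhere in a session's horizon is
rejected as invalid for that horizon.

Normalized time courses divide by the mean of the first 3 minutes
(12 frames at 15 s), computed per track, so changes read as fold of
baseline. Fluorescence features (F_end − F₀, F_end/F₀, F_max/F₀) use
detected frames only and are flagged undefined when F₀ ≤ 0. By default
they are computed on bleach-corrected intensities, switchable to raw.

## Colocalization events

Masks are not available in track exports, so contact is defined on
disk-equivalent surfaces: `gap = max(0, ‖c_a − c_b‖ − r_a − r_b)` with
`r = √(area/π)`, and *colocalized ⇔ gap ≤ ε* with ε = 0 by default (the
contact convention; configurable). A new colocalization event at frame f
for a (focal, partner) cross-channel pair requires:

- non-colocalization with that partner throughout the preceding 10 min
  (the stricter of two published phrasings — the alternative
  previous-frame-only rule is available via `strict_history=False`);
- the focal track existed before f (it *became* colocalized);
- contact in ≥ 95% of the following 10 min of frames, with the focal
  track present throughout (disappearance voids the event);
- f at least 10 min before the session end.

One event per pair is emitted, at the first qualifying frame. The event
site is the midpoint of the two centres at f (the natural symmetric
choice). The partner is re-identified as the opposite-channel track whose
centre at f lies within 1 µm of the site (nearest centre, then smaller
track id); *existing* means its first detected frame is ≥10 min before f,
otherwise *new*. Event-window kinematics (displacement from session start
to the site, mean centre-to-site distance over the 10 min before/after,
mean velocity before) use centre distance, the measurable quantity for
point tracks. Both analysis directions (focal = presynaptic or focal =
scaffold channel) are supported.

## Statistics

**Binning.** Per-frame rows are serially correlated; the effective sample
size is set by binning. The bin width is the smallest of
{1, 2, 4, 8, 12, 20, 40} frames (round numbers in minutes at 15 s) at
which the lag-1 Pearson autocorrelation of the *binned control-arm mean
series* drops below 0.3; if none qualifies — as happens when the mean
series carries a strong trend — the largest candidate is used with a
warning. Lag 1 is the standard semi-independence criterion; the candidate
set spans 0.25–10 min.

**Mixed model.** Binned responses (within-track means, bin-midpoint time
in minutes) are fitted with
`response ~ (treatment + time + covariates)**3` fixed effects and random
intercepts for image and for track within image (variance component),
via REML. The headline statistic is the Wald test of the
treatment × time interaction — a treatment-dependent rate change. The
optimizer falls back from L-BFGS to Powell, and to an image-level-only
intercept structure when the nested structure is singular (flagged in the
result). Mobility analyses are restricted to t ∈ [10, 60] min.

**Follow-ups.** Significant interactions trigger quintile stratification
by a baseline metric (first-3-min mean; ties broken by track id,
near-equal group sizes). Recruitment flagging selects tracks whose
baseline-normalized colocalized series peaks at ≥1.5×. Slope comparison
between arms is classic ANCOVA: per-group OLS slopes with 95% CIs plus
the group × x interaction F-test (an exact common-slope fit is reported
as p = 1 rather than a 0/0 artifact). Distribution stages are scipy's
two-sample KS, χ² on shared histogram bins, Fisher's exact on count
pairs, and Mann–Whitney U. No multiplicity correction is applied across
figure-level tests; each p stands alone. Regression-based outlier removal
is not implemented; an optional, clearly non-equivalent >5-MAD flag is
available and off by default.

## Synthetic generator

The generator emits sessions with the statistical structure the analysis
assumes, not a biophysical simulation:

- **Motion** is a confined random walk — Gaussian steps reflected inside a
  per-puncta tether disk. Defaults: 90% immobile (step SD 0.05 µm/frame,
  tether 0.35 µm), 10% mobile (0.12 µm/frame, tether 6 µm). These were
  chosen so that ~90% of puncta displace <2 µm over an hour (the observed
  immobile majority) and so that displacement-from-origin fluctuations
  decorrelate within minutes once a walk fills its tether — the regime in
  which a track-level random intercept is an adequate covariance model,
  which is what keeps the mixed-model test calibrated.
- **Treatment** multiplies the mobile-population step SD of the
  presynaptic channel by 2 from 20 min onward (a step change, the simplest
  generator consistent with an onset-timed mobility increase).
- **Detection dropout** is i.i.d. per frame (default 5%), with track
  endpoints kept detected so spans are well defined.
- **Intensities** are per-track baselines × bleach factor
  (A = 100, k = 0.02/min, C = 50 for channel A; 80/0.015/60 for B) ×
  optional recruitment ramp, with 2% multiplicative Gaussian noise.
- **Planted events** live on a reserved canvas strip so background puncta
  cannot contaminate them: a stationary partner, a focal puncta that
  approaches at 0.6 µm/min and docks with slight overlap exactly at the
  planted frame. "New" partners first appear 5 min before their event,
  "existing" partners at t = 0, making the classifier's rule exactly
  recoverable; 75% of planted events are "new". Transient 2-min crossings
  are planted as negative controls. Infeasible plants (inside the final
  10 min) are rejected at scenario validation.
- **Recruitment** ramps the opposite-channel (receptor) intensity of a
  chosen fraction of scaffolds (defaults 4% control, 11.5% treated)
  linearly from 10 min to 2× by session end, restricted to the bottom
  quintile of baseline receptor signal.

All randomness flows from `(seed, arm, image_index)` through NumPy
SeedSequence spawning; identical scenarios are byte-identical on disk.
The small preset (3 images/arm, ~50 presynaptic tracks/arm, 30 min)
exists so the full suite stays fast; paper-scale recovery checks use the
default preset (10 images/arm, ~350 tracks/arm).

What passing tests show — and do not. Recovery on this generator
demonstrates that each stage computes its definition correctly and that
the statistical pipeline is calibrated and powered *under the generator's
assumptions* (Gaussian confined motion, i.i.d. dropout, exponential
bleaching, disk-equivalent contact). Real data add segmentation error,
shape changes, split/merge events, anisotropic motion along neurites and
non-exponential bleaching components, none of which the generator
emulates; conclusions about real recordings still require the usual
diagnostics (residual inspection, sensitivity to ε and window choices).

## Numerical choices and degenerate inputs

- TPS systems are solved exactly; collinear/duplicate landmarks raise
  rather than regularize silently. TPS inversion (test harness) is a
  fixed-point iteration valid for near-identity deformations.
- The bleach fit bounds k ≥ 0 and A ≥ 0; degenerate (non-decaying) series
  short-circuit to a flagged flat model.
- Constant responses short-circuit the mixed model to an all-zero fit;
  constant series count as autocorrelation 1 in bin selection (so they
  never qualify a width).
- Quintile ties and linker ties are broken by track id for determinism.
- CSV round-trips use shortest-repr floats with round-trip parsing, so
  write → read → write is byte-stable.

## Problem sizes used in validation

The test suite validates the mixed model with 200 null replicates on the
small preset (type-I error within ±2 Monte Carlo SE of 0.05) and 20
paper-scale replicates of the mobility-onset scenario (≥80% detection
with positive interaction sign); bleach-rate recovery uses 100 seeded
240-frame series at 2% noise (median |k̂−k|/k < 5%); the unwarp round
trip uses a 120-frame rendered stack with a 1.5 px planted deformation.
These sizes were chosen to give stable Monte Carlo estimates at desk
scale.
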