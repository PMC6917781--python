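# Methods

This note documents the models, algorithms and numerical choices behind
`wormchip`, and what the synthetic validation studies do and do not
demonstrate about real microscope data.

## The platform and its phenotypes

Mother worms are loaded at the L4 stage into 1540 µm × 2385 µm culture
chambers (imaged in brightfield at 30-min intervals, 3.2 µm/px at the 4×
path) and their first embryo progenies are confined one-per-trap in a
serpentine of 25 trap–incubator units (imaged for 12 h at 10-min
intervals, brightfield + fluorescence, 0.8 µm/px at the 20× path). The
pixel calibrations are declared configuration values, not measured
constants; all downstream arithmetic uses the configured value.

Phenotypes, per stage:

* **Mothers** — total/normalized segmented area over time, 4-parameter
  logistic growth fit, first-egg time, eggs at first laying and one hour
  later, egg release rate (eggs·h⁻¹·worm⁻¹ over the two hours after the
  first laying event; when the series ends earlier, the count increment
  is still divided by the full 2 h, matching the platform's reporting).
* **Embryos** — viability, twitching onset, hatching, the
  twitching-to-hatching duration `D`, and the hatch-aligned normalized
  reporter intensity `I_norm(t)` with t = 0 at hatching.
* **L1 progeny** — spline length, mid-body diameter, mean/max
  fluorescence normalized by worm-free background circles.
* **Statistics** — mean ± SD per condition × dose, integer-rounded
  percent change versus control, one-way ANOVA for scalar phenotypes and
  mixed (condition between × time within) repeated-measures ANOVA for
  traces. ANOVA is delegated to scipy/pingouin; the bespoke content is
  the contrast/rounding convention and the design mapping. No
  multiple-testing correction is applied (per-panel tests); figure-style
  stars use thresholds 0.05/0.01/0.001/0.0001. Omnibus tests are
  complemented by Welch pairwise t-tests inside `percent_change`.

## Chamber segmentation

Background is the pixel-wise temporal median of the stack — robust to
worms present at t = 0, unlike first-frame subtraction, but it requires
objects to keep moving; a worm that dwells at one spot for more than
half the stack leaks into the background estimate (the synthetic tests
for background recovery therefore use stacks long enough for the
random-walk paths to decorrelate). Segmentation thresholds
|frame − background| with Otsu, then opens (disk r = 1), closes (disk
r = 2) and removes fragments below 50 px². The radii and the fragment
cutoff are pinned, configurable defaults chosen to pass ~20-px-wide
adult worms at the 4× scale while rejecting debris; eggs (~110 px² at
3.2 µm/px) are *larger* than the fragment cutoff, so egg-free frames are
required for exact area accounting (egg phenotypes are annotation-driven
and never derived from the area mask).

The logistic fit runs on the normalized (per-worm) trace with
least-squares (`scipy.optimize.curve_fit`), initialized from the data
range and the half-maximum crossing, rate bounded non-negative.
Non-convergence is reported as a flagged result, never silently; a trace
whose amplitude is below 0.1 % of its level is flagged degenerate with
rate 0 (a flat trace gives the midpoint no meaning).

## Trap localization

The chip geometry is known by design, so the localizer synthesizes its
matching template from the same `TrapGeometry` that describes the
device: one noise-free unit is rendered and cropped around the
trap–incubator intersection. Normalized cross-correlation peaks above
0.6 survive non-maximum suppression at half the unit pitch and are
ordered along the serpentine. On rendered serpentines this recovers all
25 units at 0-px error (the template *is* the unit); the declared
tolerance for real chips is ±2° of rotation/shear, beyond which a
rotated template bank would be needed (out of scope). Patches of
200×200 px (the platform's crop) are cut around the trap and incubator
centres; the analysis is patch-size agnostic.

## Embryo events

All embryo measurements run inside a mask pair derived from the
geometry: the egg footprint ellipse eroded by 1 px (so it never touches
PDMS walls, whose autofluorescence would corrupt the ratio), and the
identical footprint shifted by the configured distance into the
incubator lumen as the background reference. Using the *same shape* for
signal and background makes `I_norm` exactly invariant to any global
gain and robust to the (column-wise) illumination gradient, which is
identical in both windows.

* **Viability**: motion energy = mean |frame_t − frame_{t−1}| over the
  embryo mask. Noise floor = median of the first 3 transitions; alive
  requires > 3× floor in ≥ 2 consecutive transitions. With a zero floor
  (noise-free stacks) any positive energy counts. The factor, run length
  and floor window are pinned defaults.
* **Twitching** = first time of the sustained exceedance (the later
  frame of the first moving transition).
* **Hatching** = first frame whose dark-foreground occupancy of the
  embryo mask falls below 30 % of the running pre-hatch median,
  evaluated from the 4th frame on; the dark/bright split is one Otsu
  threshold over all mask pixels of the whole stack (bimodal as soon as
  both embryo-present and empty frames exist). Ties break to the earlier
  frame. If no frame qualifies the record is flagged *unhatched* and the
  duration is undefined.
* Timing resolution is one frame interval (10 min); no sub-frame
  interpolation is attempted, because the underlying observables
  (texture motion between frames, trap occupancy per frame) carry no
  sub-frame information. Detected events are therefore the true times
  rounded up to the next acquired frame; durations inherit a ≤ 1-frame
  quantization error per event.

Dead embryos produce no event times, by construction of the analysis
flow (events are only detected after a positive viability call).

## The synthetic scene generator

The generator emulates the device geometry and the statistical structure
of the biology, not its optics. Scenes are 16-bit grayscale; brightfield
backgrounds sit near 28 000 counts with PDMS walls near 8 000, a linear
illumination ramp (default 10 % across the width) forces real background
handling, and i.i.d. Gaussian read noise (default 300 counts ≈ 0.5 % of
range; fluorescence noise scaled by that channel's dynamic range) is
added after ground truth is computed, so truth is exactly invariant to
the noise level. Scene randomness and noise use independent seeded
streams; identical scene specs give bit-identical outputs.

* **Worms** are thickened sinusoids with Gaussian-blurred edges
  (dark-on-light, like brightfield adults). A worm's mask is built by
  taking exactly *A* pixels nearest its centreline, so the rendered
  pixel count equals the requested ground-truth area *exactly* — the
  anchor for all segmentation accuracy claims. Growth follows the
  4-parameter logistic; eggs are ~50×30 µm ellipses appearing at their
  scheduled lay times; worm overlap beyond 20 % of the union is flagged
  in truth rather than rejected.
* **Embryos** are eggshell ellipses (~50×30 µm) with a granular interior
  texture (SD 9 000 counts, 2-px correlation) that jitters by a nonzero
  integer offset of up to ±3 px every frame between twitching and
  hatching, and an empty trap afterwards. The texture contrast is set so
  that motion energy clears the 3× noise-floor criterion even at noise
  levels of 3 % of the dynamic range. The fluorescence interior follows
  a non-decreasing ramp in units of the background mean (baseline 1.0;
  plateau 1.6 for mother-treated arms at ≥ 30 µg/mL, where UPR^mt
  inheritance is induced, 1.1 otherwise — the platform's dose
  threshold).
* **L1 larvae** are round-capped sinusoidal tubes whose *tip-to-tip*
  centreline length is the stated length (the straight-segment span is
  reduced by one diameter to compensate the caps) and whose width is the
  stated diameter; truth includes centreline control points usable as an
  operator spline annotation.

What the generator does **not** emulate: point-spread optics and depth
of field, bacterial food texture and its dynamics, stage drift,
multi-embryo trap occupancy, worm-worm contact deformation, and gradual
(rather than switch-like) twitching onset. Passing tests therefore
demonstrate the correctness of the measurement logic under controlled
contrast and noise, not robustness to every real-world imaging artifact.

## Treatment presets and the contrast studies

The development-time presets pin the mean twitching-to-hatching duration
at 420 min for control/embryo-only arms and at +4/+6/+9/+7/+5 % for the
OMT-15/MET-15/MET-30/OMT-30/OMT-60 arms; continuous treatment at
60 µg/mL suppresses egg laying entirely, so that arm has no embryos and
the generator refuses to draw one. Twitching onset is uniform in
180–300 min after trapping and the between-embryo duration SD is 2 min —
deliberately small relative to the 10-min cadence so that a 30-embryo
arm identifies its preset mean through the quantized detector.

Arm-level draws use two standard variance-reduction devices, chosen at
design time from a power analysis of the detector's quantization model:

1. twitch onsets are Latin-hypercube-stratified in their *phase relative
   to the frame grid*, so each arm samples acquisition phase uniformly
   rather than by luck (frame-grid aliasing otherwise contributes an
   irreducible f(10−f) variance term to each detected duration, where f
   is the treated mean's offset from the grid);
2. durations are quantile-stratified normal draws.

Neither changes the marginal distributions; they make a 30 + 30 synthetic
experiment a low-noise estimator of its own preset contrast, which is
what the recovery studies are designed to measure. With this design the
end-to-end pipeline recovers each preset's rounded percent in ≥ 99 % of
replicates; with plain i.i.d. draws the per-replicate hit rate would be
0.89–0.96 and the 20-replicate studies would be dominated by sampling
noise rather than by pipeline behaviour.

Study sizes (30 embryos/arm, 20 replicates, 128-px patches, 80 frames)
keep one full five-contrast recovery run at a few minutes on a single
CPU; the patch scale only crops the field of view and does not touch the
embryo or mask geometry.

## Numerical conventions

* Pixel coordinates are 0-based (row, col), origin top-left; times in
  minutes; 16-bit unsigned grayscale.
* Timestamps travel in sidecar configs, never in TIFF metadata
  (microscope dialects vary; sidecars are testable).
* Percent contrasts round half away from zero to integers (the
  platform's reporting convention).
* Sample SD (ddof = 1), defined as 0 for singleton groups.
* Background circles for L1 normalization: 5 circles of radius 15 px,
  rejection-sampled outside a 10-px dilation of the worm with a seeded
  generator; an error is raised after 100 failed draws.
* The mid-body diameter fraction (0.5) stands in for the vulva position,
  which is not visually resolvable at L1; it is configurable.

## Known limitations

* The temporal-median background fails for stationary worms (see above).
* Egg detection from images is not attempted; egg counts come from
  operator annotations or generator truth. An automated detector would
  need contrast models this generator does not provide.
* The localizer assumes chip rotation within ±2°.
* Hatching defined by trap-occupancy drop assumes the L1 actually exits
  the trap; an L1 lingering inside would delay the call.
* The mixed repeated-measures ANOVA excludes subjects with incomplete
  time series listwise (the exclusion count is logged and reported).
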