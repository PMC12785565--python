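# Methods

## CoP reconstruction from sensor conductances

The sock-side CoP estimate is the conductance-weighted centroid of the six
sensor positions, CoP = Σ Uᵢeᵢ / Σ Uᵢ. Three properties drive the
implementation and its tests:

- **Hull containment.** Nonnegative weights keep the estimate inside the
  convex hull of the sensor positions; this is asserted on bulk random
  frames and is also why the synthetic trajectory generator clips its
  output to an excursion box contained in the hull.
- **Scale invariance.** The formula is homogeneous of degree zero in the
  conductances, so conductance units never matter (the kΩ→mS reciprocal
  conversion is provided for completeness only) and no per-sensor pressure
  calibration is attempted — the estimate is a *relative* CoP in the
  sock's own frame, not an absolute plantar position.
- **No-contact frames.** A frame with zero total conductance carries no
  information; it is flagged invalid (placed at the geometry centroid)
  rather than raising, because real recordings contain swing-phase and
  leg-lift intervals. Flags propagate through resampling, which refuses to
  interpolate across invalid gaps longer than `max_gap_s` (default 0.2 s).

The sensor coordinates are configurable; the printed defaults, whose
centroid is exactly the origin, are immutable. The sign convention
(positive X toward sensors 0/2/4) is used for both feet, with an optional
`mirror_x` flag for an anatomical left-foot frame — the choice does not
affect any agreement statistic because both modalities share the
convention.

## Preprocessing

The two instruments differ in rate (sock up to 200 Hz, platform 125 Hz),
clock origin, and coordinate origin (the platform reports absolute
positions that depend on foot placement). The pipeline therefore:

1. **Resamples** both CoP series by linear interpolation onto a uniform
   grid at the platform's native 125 Hz — the slower instrument's rate, so
   no information is invented. Grid points are anchored to absolute
   multiples of the sampling interval, which puts both series on a common
   phase and makes integer-sample lag alignment an exact array shift.
   Resampling never extrapolates beyond the valid input range.
2. **Aligns** the pair with one shared lag (the instruments have a single
   clock offset, not one per axis), found by exhaustive integer-sample
   cross-correlation within ±`max_lag_s` (default 5 s) on the axis where
   the platform has the larger variance. Ties break toward zero lag; a
   zero-variance segment is an error ("flat signal"), not a silent zero.
   Exhaustive search is O(lags × N) but deterministic and free of the
   phase ambiguities of FFT correlation on short, periodic signals.
3. **Mean-centers** each cropped waveform over its full overlap duration.
   This removes the platform's placement offset and the sock's
   placement-dependent bias in one stroke, and makes the CCC's location
   shift v² vanish (asserted numerically to 1e−15), so the Fisher variance
   reduces to its first term.

A leg-lift calibration marker (~3 s of near-zero summed conductance at the
start of a set) is detected as a maximal interval below 0.1× the trial
median lasting ≥ 2 s; it is used as a sanity check on synchronization, not
for per-sensor calibration.

## Agreement statistics

Conventions, chosen once and covered by oracle tests:

- All standard deviations use the sample (N−1) estimator.
- RMSE is reported absolutely (mm) and relative to Δq, the span between
  the 2.5th and 97.5th percentiles of the **platform** waveform (the
  reference instrument defines the scale of motion); both the quantile
  pair and the reference side are configurable. A flat reference yields
  `rmse_rel = NaN` with the absolute value intact.
- Bland–Altman limits use the fixed z-quantile 1.96 at the conventional
  95% level (exact normal quantiles at other levels). The fraction of
  differences strictly outside the limits is reported; for Gaussian
  differences it converges to ~5%.
- The CCC is computed from the moment decomposition ρ·χ,
  χ = 2/(v² + ω + 1/ω), which equals the covariance form
  2·cov/(sₛ² + sₚ² + (μₛ−μₚ)²) identically; the test suite checks the two
  routes against each other to 1e−10 on 1000 random pairs. Values within
  1e−12 of ±1 (identical inputs up to rounding) are snapped to ±1, and the
  CI degenerates to a point there; ρ = 0 leaves the CI undefined (NaN).
- The Fisher-transform variance of λ = atanh(CCC) is taken with
  coefficients 2 and ½ on its second and third terms. In this pipeline the
  distinction from other published variants is immaterial: inputs are
  mean-centered, v = 0, and only the first term survives — equal to
  1/(n−2) when additionally ω = 1.
- n in the CI is the number of time points in the pair. CoP samples are
  autocorrelated, so this n overstates the effective sample size and the
  CIs are anti-conservative; they are reported for comparability, not
  inference.
- Classification: the strict scheme labels [0.90, 0.95) "moderate" and
  everything below 0.90 "poor"; the loose scheme's published table leaves
  [0.30, 0.40) unlabeled, and this package maps the whole range below 0.40
  to "poor", consistent with the usual "poor correlation (CCC < 0.4)"
  convention.
- `segment_ccc` re-centers user-specified segments separately before
  scoring each — the analysis tool for baseline-shift (side-step) trials,
  where a mid-trial foot reposition shifts the platform's absolute
  baseline but not the sock's.

## Synthetic data

The generator produces the *conditions* the analysis assumes, not a
biomechanical simulation.

**Trajectory.** Anteroposterior excursion = offset + amplitude ×
sin(2π f t) at the metronome frequency (f = 1 Hz at 60 bpm); mediolateral
sway at 0.2–0.25 Hz; plus 4th-order-Butterworth band-limited noise
(cutoff 3 Hz, sd 2 mm). Default amplitudes keep X within ±20 mm and Y
within ±40 mm (unilateral squat) or [−50, +60] mm (bilateral squat with
heel raise) — the excursion ranges such exercises occupy — with a hard
clip at those bounds as the containment guarantee. Each set is preceded by
a 3 s zero-load marker window. Unilateral sets last
repetitions × 60/tempo s (10 s by default); bilateral sets 30 s.

**Sensor forward model.** True CoP → six pressures by barycentric weights
over the triangle of a deterministic fan triangulation of the sensor hull
containing the point (remaining sensors zero). This inverse of the
weighted-centroid map is under-determined; the barycentric scheme was
chosen because it is exactly consistent — the noiseless round trip
truth → pressures → conductances → CoP reproduces the truth to machine
precision, which anchors the whole simulation. A smoother Gaussian-weight
scheme (load on all sensors, inexact round trip) is available via
`scheme="gaussian"` for realism studies. Pressures become conductances as
`baseline + min(sensitivity·p, saturation) + noise`, clipped at zero, with
per-application uniform sensitivity draws in 0.5–3.0 μS/kPa and Gaussian
placement jitter (sd 2 mm) — both redrawn each time the sock is put on.
Defaults: baseline 0.5 μS, saturation 400 μS (rarely engaged; lower it to
reproduce range compression), noise sd 0.5 μS, total load 100 kPa held
constant over the stance. Pressures are distributed at the *applied*
(jittered, participant-scaled) sensor positions while reconstruction
always uses the printed nominal geometry — that asymmetry is precisely how
placement and morphology errors enter the reconstructed waveform.

**Platform model.** Truth + per-trial placement offset (uniform within
±30 mm per axis) + Gaussian noise (sd 1 mm), sampled at 125 Hz on a clock
lagging the sock's by a per-trial uniform draw within ±1 s. An optional
side-step event adds a second offset from its onset onward.

**Study design.** 10 participants × {unilateral squat right/left,
bilateral squat right/left foot} × 2 sock applications = 80 trials, each
yielding an X and a Y pair: 160 waveform pairs per modality. A
per-participant anthropometric scale factor (uniform 0.92–1.08) scales the
true sensor geometry. Each trial consumes an independent child of the
study seed, so datasets are byte-reproducible and order-insensitive.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nonlinear and hysteretic sensor response, creep
and fabric relaxation, load redistribution across the foot during the
squat (total pressure is constant), platform quantization, shared-origin
anatomical frames, and inter-repetition learning effects. Instrument
noise levels are not published for either device; the defaults were chosen
once to give plausible metric ranges, not to reproduce any empirical
table. Bilateral 30 s sets at 125 Hz give ~3750-point waveforms, longer
than the 1146–2104 points typical of field recordings after cropping;
this affects CI widths, nothing else.

## Problem sizes

The test suite and the acceptance script run the full 160-pair default and
ideal studies (a few seconds each), 1000-pair statistic cross-checks,
10⁴-sample coverage checks, and 200-trial alignment-recovery sweeps —
sizes at which every Monte-Carlo band asserted is comfortably stable
across seeds.

## Known limitations

- The CCC CIs treat time points as independent (see above).
- Alignment assumes a single global clock offset; drifting clocks or
  time-warped movement would need dynamic alignment, which is out of
  scope.
- The relative RMSE depends on the quantile pair; (2.5, 97.5) is the
  default and (5, 95) a common alternative — results quote the pair used.
- The pipeline scores each waveform pair independently; repeated-measures
  extensions (within-participant correlation of pairs) are not
  implemented.
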