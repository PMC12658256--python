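# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that shape the outputs.

## Synthetic data model

The generators produce every modality the analysis consumes, with exact
ground truth, under the conditions of a swim-tunnel / crowding study on
adult European sea bass: a ~28.3-cm, ~391-g fish; 75-fps silhouette
video; 200-Hz ECG in 7.5-s segments every 10 min; 10-Hz tri-axial
acceleration averaged per minute in milli-g; %-saturation oxygen
declines in a 127-L tunnel with a 7.157 mg O₂ L⁻¹ saturation ceiling;
and a crowding session with four inductions on the hour (10:00–13:00).
All randomness flows from a single integer seed per call; identical
(spec, seed) pairs are bitwise reproducible.

**Swimmer.** The midline is a travelling sine y(s, t) = A(s)·sin(2π(f·t
− s/λ)) with the amplitude envelope A(s) linear from the head-yaw
amplitude at the snout (default 2 px) to the tail-beat amplitude at the
tail tip (default 20 px ≈ 0.07 SL), and wavelength λ equal to one body
length. The outline is a symmetric width profile — half-elliptic head
rising to 0.12 SL at 0.3 SL, linear taper to a narrow peduncle — swept
along the midline, rasterized dark (pixel value 30) on a light
background (230), tunnel axis horizontal. Opercular pumping is an
additive Gaussian-bump width modulation centred at 0.25 SL (default
3 px at 4.5 Hz, deliberately away from the tail-beat frequency). The
reported truth amplitude for the tail landmark is the envelope at
0.8 SL, i.e. the half-peak-to-peak amplitude of a sinusoid — the
convention used for all amplitudes in this package. Frames whose
silhouette would cross the border raise an error naming the frame.

**ECG.** Each QRS complex is a triangular R spike (20-ms half-width,
0.75 of the span) followed 30 ms later by a triangular S trough (0.25
of the span), on a flat baseline with additive Gaussian noise; the
R−S span is the amplitude truth. Beats are periodic at the specified
rate with a random (or fixed) phase; beats at segment boundaries are
kept with clipped templates.

**Accelerometer.** Raw samples are gravity (1000 mg along a unit
orientation) plus a sinusoidal dynamic component plus noise. The
default dynamic frequency is 1.5 Hz: at 10-Hz sampling this covers a
uniform 20-point phase grid every 2 s, so the discrete per-minute mean
of |A·sin| matches the continuous 2A/π to < 1 %, and the 2-s gravity
moving average of the analysis stage nulls it exactly. The stored truth
is the per-minute mean magnitude of the noiseless dynamic component.

**Oxygen.** The %-saturation trace declines linearly at the rate
implied by inverting MO₂ = ΔO₂%·(DO_max·L/100)/t for the combined
fish + background rate, plus probe noise (default SD 0.05 %-sat);
parameters implying negative saturation raise an error.

**Crowding session.** Heart rate follows a step-and-partial-decay
model: at each event an increment is added, chosen so that the value at
the event equals the target peak despite residual elevation from
earlier events, and decays with a 90-min time constant — heart rate
therefore accumulates and does not return to basal between events. The
default peaks (83.91, 89.9, 96.9, 104 bpm over a 61.94-bpm basal) are
calibration values, not claims; the third peak is not independently
constrained and is interpolated between its neighbours. ACC and AMP
spike at each event and decay with a 2-min constant, so recovery-phase
values sit at baseline; the fourth ACC peak is attenuated (37.66 mg vs
52–57 mg), reproducing a freezing-type response. Each individual
carries a Gaussian random intercept (SD 4 bpm on the heart-rate scale,
scaled down for the other channels). The protocol's hold durations
(0/1/5/5 min) are carried as metadata only: the response model treats
every induction as an instantaneous spike because the emulated
per-event values are single measurements, not within-hold time courses.

## Kinematics

Detection selects dark objects below a luminance threshold (default
128/255) and filters candidates by filled area and major/minor-axis
ratio; zero survivors and multiple survivors are distinct, explicit
errors. Default filter ranges are derived from the generator's expected
geometry ±30 %. The midline is extracted by scanning the filled
silhouette column-wise along the tunnel axis (centre and extent of each
vertical pixel run), resampled to equal arc-length spacing; the head is
the end with the larger mean width over the anterior 20 % of arc
length. This column-scan axis is valid for the near-horizontal posture
of a station-holding tunnel fish and recovers generated midlines to
≈ 0.2 px RMSE; it is not a general skeletonization.

The tail-landmark excursion is the signed perpendicular distance of the
0.8-arc-length point from the reference axis through the head, fitted
by least squares to the anterior 20 % of midline points. By default the
axis is averaged over the trial: a station-holding fish yaws its head
with the body wave, and projecting on the instantaneous axis,
extrapolated ~0.8 SL to the tail, inflates the apparent excursion
severalfold (measured: >2× on default-parameter videos). The
`axis="per_frame"` option restores the instantaneous axis for
free-swimming sequences where the heading drifts.

The spectrogram uses a Hann window of 0.85 s rounded to a whole frame
count (64 frames at 75 fps, ~1.17-Hz native resolution), shifted one
frame at a time. Each window is mean-subtracted; the dominant non-DC
bin is refined by parabolic interpolation on log-magnitude, and the
amplitude is scaled by 2/Σw so a pure sinusoid of amplitude A returns
A (≈ 1–3 % residual scalloping). Windows whose peak falls below an
amplitude floor (default 10⁻⁶) report zero frequency and amplitude.
Trial-level TBF/TBA/HWF/HWA are means of the per-frame tracks, in px or
converted to cm by the pixel scale.

## Respirometry

ΔO₂% is the fitted least-squares linear decline over the (optionally
windowed) measurement, which resists probe noise better than an
endpoint difference; its standard error is propagated to MO₂. The
printed-form MO₂ is in mg O₂ h⁻¹; mass-specific values divide by body
mass in kg, and both are exposed. Background (blank-tunnel) rates are
subtracted; a negative corrected rate is flagged, not clamped. COT
equals mass-specific MO₂ divided by speed in km/h. The COT–speed curve
is quadratic by default (degree overridable); U_opt = −b/2a requires a
convex fit (a > 0, otherwise a NoMinimum error) and estimates outside
the tested 0.2–1.0 m/s ladder are flagged as extrapolated. Temperature-
dependent oxygen solubility is out of scope: DO_max is a constant.

## Biologger signals

The QRS detector replaces manual annotation: 5–40 Hz second-order
Butterworth band-pass (zero-phase), squared energy smoothed over 50 ms,
candidate peaks at a 200-ms refractory spacing, and an adaptive
threshold from two-means clustering of candidate peak heights. An
inter-beat-interval repair pass drops the weaker beat of any pair
closer than 0.55× the median interval and fills gaps of 1.6–2.6×
the median with the best sub-threshold candidate. Beats are refined to
the raw R maximum; the S trough is located within ±60 ms. Per-beat
amplitudes use a consensus R/S offset across beats, which keeps the
extreme-value bias of per-beat argmax/argmin searches small (the
dominant error source at 10 % noise). Quality flags: `rejected` for
flat or beat-free segments, `low_confidence` when the beat/noise
cluster separation falls below 2.

Heart rate is 60(n−1)/(tₙ−t₁) from the detected beat times — undefined
(flagged) below two beats. The segment AMP is the median per-beat R−S
span. External acceleration subtracts a 2-s per-axis moving average
(gravity estimate), takes the Euclidean norm of the residual, and
averages full 60-s windows; trailing partial windows are dropped with a
log entry. Baselines are the mean ± SE of the 20 most recent
pre-experiment points.

## Challenge statistics

Speed bins assign measurements to the 0.2–1.0 m/s hourly ladder; the
first 20 min of each step (flush + acclimation) are excluded from
respirometry alignment but retained for the cardiac/activity channels,
leaving six 10-min heart-rate measurements per speed. Speed-response
fits are polynomial or exponential (a·e^{bU}, log-linear initialised)
least squares; R² is reported signed by the direction of the fitted
trend, with an F-test against the constant model. The correlation
matrix reports pairwise Pearson r with sign retained, signed r², and
p-values; constant columns are flagged undefined rather than silently
dropped.

Pairwise group contrasts fit a random-intercept-per-individual mixed
model (REML, cell-means coding) and test all pairwise differences with
the studentized-range distribution at containment-style degrees of
freedom (n − k − (individuals − 1)). When the random intercept is
unidentifiable — fewer than two individuals, or one observation per
individual — or the fit is singular, the model falls back to fixed
effects with a warning; on a balanced one-way design this path is
exactly the classical Tukey HSD, which is the test oracle. Letter
groupings use the insert-and-absorb compact-letter algorithm.

Crowding phases partition every measurement: `basal` before the first
event, `stress_k` in the cadence step at event k, `recovery_k` in the
half-open window [event + cadence, event + 50 min], `final_rec` 2–4 h
after the last event, and an explicit `uncategorized` label for the
0–2 h gap after the last event, excluded from summaries.

The welfare classifier is a pure function of baseline-relative heart
rate (z-score), acceleration and QRS amplitude (ratios): thresholds
default to +1.5 baseline SD for heart rate and 2× baseline mean for the
other channels — the qualitative states require explicit cutoffs, so
they are configurable rather than hard-coded. The four corners map as
resting (low HR, low ACC), regular activity (low HR, high ACC),
reactive response (high HR, low ACC, low AMP) and proactive response
(high HR, high AMP); the remaining corner and borderline inputs resolve
to the nearest prototype in a tanh-squashed margin space, and every
output carries a continuum score in (0, 1]. Oxygen consumption is
deliberately not a classifier input — it is the inferred quantity the
cardiac/activity channels proxy.

## Problem sizes and runtime choices

The validation suite uses 8-s videos at 75 fps for the five tail-beat
frequencies, 40 ECG segments per heart rate, 200 simulated individuals
for the endurance recovery, 500 replicates for the null/power
calibration of the contrasts and 1000 for the correlation calibration —
sizes at which the binomial/Monte-Carlo error of each check is well
below its tolerance. The pipeline demo configuration defaults to a 2-s
video to keep end-to-end runs interactive.

## What passing tests do and do not show

The generators emulate the statistical structure of the recordings —
periodic kinematics, template ECG, spike-and-decay stress responses,
linear oxygen declines — not their full physiology: no swim-bladder or
fin silhouettes, shadows, reflections or occlusions in video; no ECG
morphology beyond the QRS, no arrhythmia or movement artefacts; no
respiratory quotient or temperature drift in the tunnel; single-fish
scenes only. Parameter recovery on these inputs validates the numerical
pipeline and its contracts, not detector robustness on raw field
recordings; the quality-flag machinery is the hook where real-data
filtering would attach.

## Known limitations

* The midline extractor assumes a near-horizontal fish; strongly curved
  or vertical postures need a true skeletonization.
* The mixed-model degrees of freedom are containment-style, slightly
  liberal for unbalanced designs (Satterthwaite/Kenward-Roger are not
  implemented).
* The welfare thresholds are defaults, not calibrated cutoffs; real
  deployments should fit them to baseline distributions per individual.
* The exponential speed-response fit assumes positive channel values
  for its log-linear initialisation and falls back to a generic start
  otherwise.
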