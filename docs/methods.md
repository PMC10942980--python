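# Methods

This note documents the models and algorithms the package implements, the
assumptions behind them, the parameter choices that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Coordinate conventions and metrics

The lab frame is right-handed with X the direction of progression, Z up,
Y mediolateral (left). Sagittal thigh and shank angles are measured
against vertical and are positive when the distal end is ahead of the
proximal end; the foot angle is measured against horizontal (heel→toe
elevation), positive for a rear-foot strike. Overstriding (OS) is the
forward horizontal distance from the greater-trochanter marker to the
lateral-malleolus marker at foot contact, normalized by leg length
(defined here as the static trochanter-to-lateral-malleolus distance, so
normalized OS is a pure function of the same two landmarks). Foot contact
(FC) and toe-off are the upward/downward crossings of a 20 N vertical GRF
threshold; peak braking force (PBF) is the largest posterior
anterior-posterior GRF during stance, in units of body weight measured
from the quiet-standing force level. Stride frequency is 60 / stride time
and duty cycle is contact time over stride time.

## Signal processing

Markers are low-pass filtered at 10 Hz and forces at 50 Hz, both with a
bidirectional (zero-phase) 4th-order Butterworth filter; zero phase
matters because events and FC-instant values are read off the filtered
series. Reflective padding of 3× the filter order is used at the edges.
Events are detected on the native 2000 Hz force grid with linear
interpolation of the threshold crossing; debounce windows (stance ≥ 0.1 s,
flight ≥ 0.05 s) absorb threshold chatter and are conservative for running
at 75–95 strides/min. Angle series are analyzed at the 200 Hz marker rate;
FC-instant values are linear interpolations to the force-derived FC times,
avoiding ±2.5 ms quantization.

## IMU sagittal angles and drift management

The manufacturer-fused sensor-to-global quaternions are taken as the
orientation input (no re-fusion from raw gyro/accel); gravity is the
global −Z of that fused frame. Two calibrations are implemented.

*Standing-pose calibration.* The mean orientation over a quiet standing
window (quaternion barycenter via the largest-eigenvector method, ≥ 0.5 s
with gyro norm < 10°/s) defines the segment reference, so the standing
angle is exactly zero (thigh/shank vertical, foot flat — the foot's
zero-to-horizontal reference comes from the same standing pose). The
sagittal angle is then the mediolateral-first Euler angle of the
referenced rotation (decomposition R = R_y(a)·R_x·R_z about the fixed lab
axes, θ = −a). Any heading error composed onto the orientation leaks into
this angle — with 30° of accumulated heading rotation and a 20° segment
pitch the leakage is ≈ 2.5° — which is why a second scheme exists.

*Per-frame global-frame redefinition.* Assuming hinge-like joints (all
relevant segment rotation about a mediolateral joint axis known in the
sensor frame from the standing calibration), at every frame the global
frame is rebuilt: the joint axis is mapped to the global frame, projected
onto the horizontal plane to form the mediolateral axis, the vertical axis
opposes gravity, and the third completes the triad. The sagittal angle is
the same mediolateral-first Euler angle in this rebuilt frame. Because the
frame follows the current heading of the joint axis, *any* rotation about
gravity — a static heading offset or accumulating drift — cancels exactly
for planar motion (machine precision in the validation experiments). The
price is the hinge assumption: a 3° out-of-plane tilt produces bounded
cross-talk below 1°. The axis reconstruction degenerates if the joint axis
comes within 5° of vertical, which running never approaches. The sign of
the joint axis is resolved functionally by correlating against the known
forward leg swing of the calibration maneuver.

The pipeline uses the standing-pose method for the short treadmill trials
(as a mocap-comparable baseline) and the per-frame method for the longer
overground trial where drift accrues.

## Synchronization

IMUs start recording after motion capture (delays of roughly 90–180 ms),
shared by the three sensors, which are started together. The delay is
estimated by maximizing the normalized cross-correlation between mocap and
IMU segment-angle series over the calibration maneuver, resampled to a
common 200 Hz grid, with parabolic interpolation of the peak for
sub-sample resolution. Two implementation details matter in the presence
of low-frequency soft-tissue wobble: the series are first-differenced
before correlating (whitening the wobble and sharpening the peak around
the step's edges), and the estimates of the three segments are averaged
(the default; a single-segment option exists). The correlation window ends
before any running content can enter either stream's window for delays up
to the 0.25 s search bound, because partial-window contamination by
nonstationary content biases normalized cross-correlation. A negative
correlation peak flags a sign-convention mismatch and triggers a flip.

## Mixed models

Per-stride outcomes on the same runner are not independent, so each model
is a random-intercept linear mixed model, `y_ij = x_ij'β + α_i + ε_ij`
with participant i and stride j, fit by REML. All model inputs (dependent
and predictors) are z-scored, pooled within condition across participants
— pooling preserves the between-participant variance for the random
intercept to absorb, which is what produces the large ICCs typical of
such data. Estimation profiles the likelihood down to one dimension in
the variance ratio λ = σ²_b/σ²_e: given λ the GLS coefficients and σ²_e
are closed-form (compound-symmetric blocks), and the REML criterion
`(n−p)·log σ̂²_e + Σ log(1+λn_i) + log|XᵀV⁻¹X|` is minimized by a coarse
log-grid bracket followed by bounded scalar search (tolerance 1e−13 in
log λ), with the λ = 0 boundary checked explicitly. This makes the fit
deterministic, makes boundary fits collapse exactly to OLS, and makes a
single-group dataset provably identical to OLS (the REML correction
cancels the group-variance term when the intercept is in the design).

Inference is Wald-normal: 95% CIs are β̂ ± 1.96·SE and p-values use the
z distribution rather than Satterthwaite degrees of freedom; with ≥ 10
groups and dozens of strides per group the difference is negligible, but
it is a known source of small p-value discrepancies versus lmer-style
output. ICC = σ²_b/(σ²_b+σ²_e). Marginal and conditional R² follow the
variance-ratio form: σ²_f is the empirical variance (ddof = 1) of the
fitted fixed-effect predictor, marginal R² = σ²_f/(σ²_f+σ²_b+σ²_e), and
conditional R² adds σ²_b to the numerator. Participant intercepts are
reported as BLUPs, λ·S_i/(1+λn_i) for group residual sum S_i.

The implementation is cross-checked two independent ways in the test
suite: against `statsmodels` MixedLM on simulated data, and against a
from-scratch Laird–Ware EM algorithm for REML (in
`overstride.validation`) on a printed 3-group fixture, agreeing to 1e−6.

## Synthetic study generator

The generator emulates the study design so that every stage has ground
truth: n = 10 runners (leg length 0.89 ± 0.04 m, mass 71.8 ± 15.3 kg),
five 30 s treadmill trials at 3.0 m/s paced at 75/80/85/90/95 strides/min
in which FC angles — and hence overstriding — decrease with stride
frequency, one comfortable-speed overground trial (2.9 ± 0.27 m/s,
self-selected 81 ± 3.5 strides/min; 60 s by default, configurable to the
study's 300 s), and a standing static trial.

The skeleton is planar: per-stride FC-angle targets (per-SF means, ±2°
participant offsets, ~1° stride noise with a shared stride factor) anchor
smooth two-to-three-harmonic within-stride waveforms, offset-blended so
the series passes through each FC target exactly and stays continuous.
Markers follow by forward kinematics from a hip trajectory (stationary
hip for treadmill, advancing hip for overground), so
`OS = L_t·sin θ_t + L_s·sin θ_s` holds identically; stride periods are
rounded to whole 200 Hz frames so true FC instants lie on the marker grid
and the identity survives interpolation to machine precision. The per-SF
angle means were chosen so the per-participant OS range across treadmill
conditions is ≈ 6 cm and the PBF range ≈ 0.18 BW, the magnitudes such
stride-frequency protocols elicit.

Vertical GRF stance bumps are sine-squared pulses (peak ≈ 2.5 BW) on a
slightly widened support computed so the 20 N crossings fall exactly at
the true FC/TO instants with a finite crossing slope; the
anterior-posterior channel has a braking lobe whose peak equals the
stride's generative braking force followed by a propulsive lobe. PBF is
generated from a linear model on the standardized FC angles,
`PBF_std = 0.35·z(θ_t) + 0.35·z(θ_s) + 0.15·z(θ_f) + α_i + ε`, with
participant intercepts σ_b = 0.9 and residual σ_e = 0.3 (standardized
units, ICC 0.9), mapped to body weights (base 0.35 BW, 0.125 BW per
standardized unit, floor 0.05 BW). These coefficients are a calibration
chosen to place the fitted marginal/conditional R² in realistic regimes,
not measured truths.

IMU streams corrupt the true planar segment rotation with: a constant
per-segment mounting misalignment (5° scale); low-frequency soft-tissue
wobble (low-passed at 3 Hz, 2° RMS about the sagittal axis, 1° off-axis)
plus 0.3° white orientation noise — calibrated so mocap-vs-IMU FC-angle
RMSE lands in the 2–5° range reported for sensors of this class; heading
drift about gravity at a per-trial rate (σ = 0.05°/s) that starts
accumulating after the standing window; and a per-trial start delay drawn
uniformly from 90–180 ms. A calibration maneuver (fast ~0.3 s step, then
a ~2 s forward/backward swing) precedes every trial for synchronization.
Marker noise is 0.5 mm, and a per-participant trochanter marker-placement
offset (σ = 1 cm along X) creates genuine participant-level OS offsets for
the random intercept to absorb.

What the generator does *not* emulate: three-dimensional (frontal/
transverse) kinematics, physiological force-profile variability beyond
the parametric lobes, soft-tissue artifact structure beyond band-limited
wobble, clock-rate mismatch between devices, and IMU-based (force-free)
event detection. Passing tests therefore demonstrate algorithmic
correctness under the stated planar/hinge assumptions and realistic noise
magnitudes — not performance on real runners.

## Numerical choices and degenerate inputs

Quaternion sign continuity is enforced (dot(q_t, q_{t−1}) ≥ 0) before
averaging or interpolation, and q/−q are treated as the same orientation.
Zero-variance inputs are rejected by name (z-scoring, lag estimation);
zero-length segment vectors report the offending frame; FC instants
outside an IMU stream's support are flagged NaN and the stride excluded
rather than aborting the trial. Treadmill-like marker data (no net
displacement) makes the progression-direction estimator fail loudly and
the pipeline falls back to the lab +X convention. The REML optimizer is
deterministic; a boundary fit (σ²_b = 0) is a valid result with ICC 0 and
a warning.

## Validation experiment sizes

The experiments in `overstride.validation` (run by `scripts/acceptance.py`
and the acceptance tests) use: a 1-participant noiseless study for the
geometric identity (~50 strides); one 25 s trial with 30° of accumulated
drift for the drift contrast; 100 short-trial replicates for delay
recovery; ~165 strides for event/PBF recovery; 100 replicates of 10
groups × 75 strides for estimator recovery; and one full default-
configuration study (~1550 retained strides) for the structural checks.
These sizes keep the complete validation run around half a minute on one
CPU while leaving wide margins on every tolerance. R² recovery is checked
on the ratio of mean variance components rather than the mean of
per-replicate ratios, because the latter carries an O(1/n_groups) Jensen
bias that is a property of a 10-participant design, not of the estimator.

## Known limitations

Wald-normal p-values (no Satterthwaite correction); no random slopes or
crossed random effects; single (left) leg only; no IMU-only event
detection; the per-frame calibration's exact drift cancellation degrades
gracefully but nonlinearly as motion departs the sagittal plane; and the
generator's coupling of braking force to landing angles is linear by
construction, so it cannot probe nonlinear angle–force relationships.
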