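# Methods

This note records the models implemented by the toolkit, the defaults it
ships, the numerical choices that are not visible from the API, and what
the synthetic validation does and does not demonstrate.

## Signal chain

**Calibration.** Accelerometer constant errors (bias, per-axis scale,
cross-axial coupling, axis misalignment) are fit by iterative least
squares on static poses: because gravity has known magnitude, corrected
pose means must lie on the unit sphere.  The gain matrix is parameterized
upper-triangular, which removes the rotation gauge freedom of a full 3×3
matrix — norms are rotation-invariant, so only nine gain+bias parameters
are identifiable, and at least nine distinct poses are required.  The
solver stops when the parameter change falls below 1e-8 or after 100
iterations.  Gyroscope bias is the per-axis mean of a stationary segment
(per-axis variance must stay below 1e-3 rad²/s²; anything larger raises a
not-stationary error).

**Orientation.** A gradient-descent complementary filter: the quaternion
is propagated by the first-order derivative `q̇ = ½ q ⊗ (0, ω)`, corrected
along the normalized gradient of the gravity-direction objective
`f(q) = R(q)ᵀe_z − â`, and renormalized every step.  Conventions:
Hamilton quaternions, scalar first, `q` rotates device-frame vectors into
the world frame.  The tilt angle is `ρ = arccos(1 − 2(q_x² + q_y²))`,
clamped into [−1, 1] before the arccos; it is the same number whether one
reads `q* g q` as gravity in the device frame or the device vertical in
the world frame.  Defaults: correction gain β = 0.1 (the widely used
default for this filter family; the downstream detectors are
threshold-trained, which absorbs moderate gain sensitivity), integral
drift-feedback gain 0 (off — the drift-correction description in the
source method is underspecified, so it is provided as an optional
integral term and disabled by default).  The filter is initialized
tilt-consistent with the first accelerometer sample, yaw zero.  The
accelerometer correction is skipped when the acceleration norm is below
0.01 g (free fall carries no gravity direction).  With gain 0 the filter
reduces exactly to gyro integration; the test suite checks this against
closed-form rigid-body rotations.

**Feature signals.** `A = ‖a‖` (g), `W = ‖ω‖` (rad/s), tilt ρ (rad), and
ρ̇ by central finite difference (one-sided at the boundaries; second-order
accuracy, no phase lag).

## Extreme-value signals

The detection variable of each feature is a two-pass, stride-1,
causal-forward construction sharing one window size τ: the statistic
(mean, or log10 of the unbiased variance) over `[t, t+τ)`, then the
min/max over a same-length window of the statistic series.  Each pass
consumes `window − 1` samples, so only full windows contribute;
milliseconds convert to samples by round-half-up.  Variances are floored
at 1e-12 (g² or rad²/s²) before the log so perfect synthetic stillness
stays finite.  Dense (stride-1) evaluation makes the later fusion-stage
maxima and means exact rather than hop-dependent.

## Statistical models

Per-feature extreme values of state-positive scenarios are modelled by a
normal `N(μ, σ²)` or Gumbel `G(u, β)` law (type-I extreme-value,
max-stable form; minimum-extreme features are modelled on their raw
values, not negated).  Fits are maximum likelihood: the normal uses the
divisor-n standard deviation so the family comparison is between
*maximized* likelihoods; the Gumbel solves the profile fixed-point
equation `β = x̄ − Σxᵢe^(−xᵢ/β)/Σe^(−xᵢ/β)` by Brent root finding
(tolerance 1e-10, bracket [sd/10, sd·10] expanded geometrically, sample
shifted by its minimum so the exponentials cannot overflow), then
`u = −β ln(n⁻¹Σe^(−xᵢ/β))`.  Family selection uses the log ratio of
maximized likelihoods: positive selects the normal, zero or negative the
Gumbel.  The statistic itself is exposed (`rml_statistic`) so marginal
calls are visible, but the decision rule is applied strictly.

For fusion, densities are normalized by their analytic maxima
(`1/(σ√2π)`, `1/(βe)`), giving weights in (0, 1] that equal 1 exactly at
the mode.

## Detectors and fusion

- Fall: product over 4 features (min/max windowed-mean A, max
  windowed-mean W, max windowed-mean ρ̇) of the *maximum* weight over the
  fusion window; fires where the likelihood strictly exceeds γ_F.
- Immobility: product over 3 log-variance minima features of the *mean*
  weight over the fusion window (the state is sustained); strict > γ_I.
- Down: the tilt extreme-value signal thresholded directly at γ_D rad;
  no statistical model.  Training places γ_D at the 1st percentile of
  state-positive tilt peaks (detection-rate target 0.99) because absolute
  tilt is confounded by terrain, posture and mounting, which makes a
  miss-rate constraint more defensible than a fitted density.
- Pairwise states `y_ab(t) = ⋁y_a[t, t+τ_ab] ∧ ⋁y_b[t, t+τ_ab]` with
  closed windows; the order of the two states inside the window is
  deliberately ignored — only co-occurrence matters, which avoids having
  to segment state onsets and offsets.  MDS is the inclusive OR of F-D,
  F-I and I-D.  The triple combination needs no detector of its own:
  any window containing all three states already fires all three
  pairwise signals (property-tested).
- A recording is classified MDS iff the decision signal fires at least
  once (scenario-level evaluation, matching how reference corpora are
  labelled).

Windows at the end of a recording are truncated, not padded, and
intervals touching the tail are flagged in the interval output.  All
detection inequalities are strict, so likelihood exactly at threshold
does not fire.

Shipped defaults (reference configuration from waist-mounted corpus
training): feature windows 730 / 125 / 405 / 300 ms (fall), 4500 ms
(immobility and down); fusion windows 1475 ms (F) and 2650 ms (I);
pairwise windows τ_FD = 4800 ms, τ_FI = 7500 ms, τ_ID = 3850 ms;
thresholds γ_F = 0.0254, γ_I = 0.038, γ_D = 0.87 rad (≈50°, the
conventional upright-versus-fallen tilt boundary in posture-based fall
detection).  Thresholds and models should be retrained for any new sensor
placement; the defaults are a starting point, not a calibration.

## Training and evaluation

Thresholds are chosen by maximizing the scenario-level Matthews
correlation over a grid of candidate γ (midpoints between sorted unique
per-recording likelihood peaks, plus one sentinel beyond each extreme so
the all-positive/all-negative decisions are always available); MCC ties
resolve to the smallest γ, and MCC is defined as 0 whenever a confusion
factor vanishes.  Window-size search is per-feature marginal by default
(for each candidate τ the extreme-value signal is recomputed, models
refit and the threshold re-optimized); an exhaustive joint search over
four fall windows was judged not worth its cost for the marginal gains
observed.  Cross-validation is stratified by scenario label with a fixed
shuffling seed (default 42); error bars are mean ± SD across folds.

## The synthetic corpus

The simulator emulates the scenario taxonomy of worker activities with
piecewise-smooth kinematic templates: a tilt trajectory drives a
consistent gravity vector in the device frame (so reconstructed tilt
matches the template), the gyroscope x-axis carries its derivative, and
structured oscillations plus white noise (defaults 0.004 g and
0.01 rad/s RMS per axis — still-segment noise floors of a consumer MEMS
IMU) supply the activity signature.  Falls contain free fall (norm dip
to 0.2–0.35 g), an impact spike (peak 3.5–6.5 g) and a tilt transition
from <20° to >70° within one second; still segments keep windowed
log10 acceleration variance below −4.4 g².  Default recordings are 20 s
at 200 Hz (100 Hz preset available), long enough for the 4.5 s + 4.5 s
immobility windows plus the 2.65 s fusion window to see a full still
plateau.

The validation corpus is 100 ADL + 100 MDS recordings.  The ADL mix
(walk 20, bend 15, sit 15, jump 15, stand-still 10, crawl 10,
fall-with-recovery 15) deliberately contains each single-state confuser:
upright stillness (I without D), crawling (D without I) and a recovered
fall (F alone).  The MDS mix (fall ending lying 35, fall ending slumped
upright 30, slow collapse 35) covers every combinatorial pathway,
including the fall-free I-D collapse.  Every class appears at least ten
times so label-stratified 10-fold CV is well posed.

**What passing does and does not show.**  The simulator produces the
*signatures* the detectors are built for, with seeded variability, so the
end-to-end results demonstrate that the pipeline is internally coherent:
models fit on training folds transfer to held-out recordings, fusion
suppresses the single-state false alarms present in the corpus, and every
MDS pathway is exercised.  It does not reproduce the messiness of real
human movement — inter-subject variability, compound activities, sensor
mounting slop, long-tailed impact dynamics — so the synthetic rates
overstate what recorded corpora yield; rates reported in the fall-detection
literature for large recorded corpora (≈99 % accuracy, ≈1 % false alarms)
are not claimed here.  One concrete
simulator artefact: during stillness the tilt-rate variance is dominated
by estimator noise of the 200 Hz finite-difference (≈10^−2.3 rad²/s²)
rather than the ≈10^−3.9 seen in waist-mounted recordings; since models
are refit per training fold this is internally consistent, but the
immobility model localities are not transferable to real data.

## Degenerate inputs and edge rules

Constant samples raise a zero-scale error rather than fitting a
degenerate density; training states whose positive class is absent are
left untrained (the bank stores `None`) and detection proceeds through
the remaining MDS pathways; PD/PFA raise when the corresponding class is
empty; empty recordings are rejected at I/O.  Raw-count parsing validates
the signed bit range strictly and reports the offending line number.
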