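# Methods

This note documents the models, numerical choices and known limitations of
`gaitval`: what the synthetic cohort emulates, how the two measurement
routes work, what the agreement statistics compute, and what a passing test
suite does and does not demonstrate about real gait data.

## 1. The synthetic gait model

### Construction

Walking is built **foot-first**. Each leg's foot pose over one gait cycle is
prescribed analytically with *exact* contact phases:

* **foot flat** from heel strike to heel-off (at 49% of stance by default);
* **heel rise** rotating about the toe contact point up to the toe-off
  pitch (48° ± 2° across subjects), with the pitch *velocity* carried
  across toe-off — the foot keeps plantarflexing into early swing, which is
  what keeps the hip-extension peak smooth;
* **swing** as a beta(2.6, 3.4)-CDF forward reach (peak foot speed before
  mid-swing, long decelerating tail) with a toe-clearance arc that decays
  quickly, so the foot skims the ground through terminal swing; the last
  30% of swing blends the ankle onto a constant-radius arc around the hip
  (a pendular reach with the knee near extension).

The pelvis translates at the subject's mean velocity and rides a
circularly-smoothed version of the two legs' reachability envelope (an
inverted-pendulum vault, highest at single-support midstance), held a small
margin below the envelope so the two-link inverse kinematics never reaches
its square-root singularity at full knee extension. A ≤ 2 cm mediolateral
sway and an oscillating anterior pelvic tilt (2 cycles per stride) make the
motion "planar-plus": sagittal-dominant, but with enough off-plane motion
that central-projection effects are non-trivial.

Hip, knee and ankle angles follow from two-link inverse kinematics of the
rigid thigh–shank chain; all pose functions are C2-continuous at the phase
junctions and the residual junction curvature is removed by a circular
Gaussian smoothing of the tabulated foot pose (σ = 2.5% of the cycle).
Band-limiting matters: the production measurement filter (6 Hz, see §3)
must not remove real range of motion, so the simulated curves may not carry
spectral content a physiological curve would not have. Each subject's
resulting angle cycles are summarized as 4-harmonic Fourier series in
`SubjectParams.angle_waveforms`.

Two deliberately *sharp* features are kept for event detectability, both
placed where the angle pipeline cannot see them:

* a **heel-pad impact transient** — a one-period 10 Hz vertical ripple of
  the heel *marker* (pad compliance, not a skeletal rotation) ending 6 ms
  before ground contact, so the acceleration maximum the heel-strike
  detector keys on lands on the contact instant. It lives between the 6 Hz
  angle filter (which removes it) and the 12 Hz event filter (which keeps
  it). During that 100 ms window the heel marker deviates from the rigid
  foot by up to ~12 mm; every other marker pair is exactly rigid at zero
  noise.
* a **soft toe peel-off** (lift exponent 1.4): brisk enough for
  velocity-threshold toe-off detection, slow enough that the detected
  toe-off slightly lags the true one — the lag real video-based detectors
  show, and the mechanism behind the later-than-force-plate 2D toe-off.

### Cohort marginals

Subjects are drawn so the cohort reproduces a young healthy population:
walking velocity 1.42 (0.10) m/s (Froude-coupled to height, with the
stated marginal preserved), stride time 1.02 (0.06) s, toe-off at
59.0 (0.8)% of the cycle, height 1.75 (0.08) m, BMI 21.1 (1.4) kg/m².
Cadence and stride length are derived so that
velocity = stride_length × cadence / 120 holds exactly. Verified over 600
subjects: mean velocity 1.424 m/s, mean stride time 1.024 s.

Cycle ranges of motion were tuned once, at design time, toward healthy
sagittal magnitudes (hip ≈ 44°, knee ≈ 60°, ankle ≈ 35°, pelvis ≈ 3.3°).
The achieved cohort means are hip ≈ 56°, knee ≈ 41°, ankle ≈ 39°,
pelvis ≈ 3.3°: the knee falls short because its midstance extension plateau
sits at ~16° flexion rather than ~5° — the price of keeping the
near-extension inverse kinematics smooth enough for the band-limit above —
and the hip is correspondingly high. This is a known limitation; it does
not affect any directional comparison between the 2D and 3D routes, which
is what the cohort exists to support.

### Noise channels, and what each one drives

* `soft_tissue_amplitude` (default 8 mm) — cycle-locked skin/shoe artifact:
  a per-marker sinusoid with subject-fixed phase and direction, plus two
  **angle-proportional drag terms**: the trochanter marker lags hip flexion
  (skin over the greater trochanter), and the heel marker under-rotates
  with foot pitch (shoe heel-counter slip). These two drags are the modelled
  mechanism behind the 2D route's *lower* hip and ankle ranges of motion:
  they afflict exactly the markers the relative-angle route measures from,
  while the 3D route's joint centres come from pelvis markers and
  medial-offset constructions that bypass them.
* `tracking_jitter_sd` (1.5 mm) — white per-frame noise on the 3D stream
  and, converted through the plane scale, on the 2D pixels.
* `grf_noise_sd` (4 N) — additive force-plate noise against the 20 N
  threshold.
* `day_effect_sd` (0.02) — lognormal day-to-day multiplier on cadence and
  stride length; the reason test–retest agreement trails inter-rater
  agreement.
* `trial_gait_sd` (0.015) — lognormal trial-to-trial multiplier on cadence
  and stride length: natural stride variability, the floor under every
  within-session SD.
* Rater placement: a systematic per-(rater, marker) bias (SD 5 mm, fixed
  across subjects and sessions), per-application jitter (3 mm), and
  tape/caliper anthropometric error (3 mm). Offsets are expressed in each
  marker's segment frame, so they shift angle curves by near-constant
  offsets — which is why ranges of motion are comparatively robust to
  marker placement while absolute angles are not.

Zero noise with an identity rater gives a bit-identical, exactly rigid
recording per seed.

### Ground reaction force

Each leg's vertical GRF is the classic double bump (loading and push-off
peaks ≈ 1.1 body weight, midstance valley ≈ 0.8), zero outside stance,
with edges steep enough that the 20 N threshold is crossed within ±2 ms of
the true events at 1000 Hz. Plate 1 carries the left leg, plate 2 the
right, with every stance of the recording on its plate — an instrumented
walkway rather than two single-strike plates — so consecutive same-side
heel strikes are force-derivable.

## 2. The camera model

A pinhole camera per side (640 × 480 px, 3.36 m × 1.58 m field at 2.5 m:
0.525 cm/px horizontally, 0.329 cm/px vertically; optical axis 0.70 m above
the floor) with central projection and no lens distortion. Metric
calibration uses a one-metre square imaged in a plane offset 0.10 m from
the walkway midline toward the camera — the near-side marker plane — which
minimizes the `D/d` scale error for the markers the 2D analysis actually
tracks; heel markers sit slightly inside that plane, leaving the small
systematic stride-length shortfall (~1–2%) single-camera systems show.
The contralateral leg is occluded in a real sagittal video, so the 2D route
refuses to compute step length and step time (a capability error, not an
approximation).

## 3. The two measurement routes

Both routes low-pass their trajectories with a zero-lag (forward–backward)
2nd-order 6 Hz Butterworth filter — zero-lag so event timing is not
phase-shifted, at the cost of squaring the magnitude response; single-pass
mode is selectable via `FilterSpec(zero_lag=False)`. The 3D reference
deliberately uses the same filter rather than a generalized-cross-validated
quintic spline: at this scale the difference is negligible and one filter
keeps the routes comparable.

Event detection runs on more lightly smoothed trajectories (12 Hz), because
the 6 Hz filter visibly spreads the contact transients:

* **heel strike (2D)** — within each window where the heel's forward
  velocity drops below 20% of its mean, the event is the acceleration
  maximum in the window's first 0.25 s (touchdown sits at the window start;
  heel-off, which also accelerates the marker, sits at its end);
* **toe-off (2D)** — after the stance minimum of the second-toe marker's
  height, the first *sustained* (two-sample) crossing of its vertical
  velocity above 0.35 m/s, localized to sub-frame precision by linear
  interpolation. The spec'd starting point for this threshold was 0.1 m/s;
  at that value the event-filter's backward spread makes detection land
  *before* the true toe-off, inverting the known 2D-late bias, so the
  shipped default is the recalibrated 0.35 m/s;
* **3D events** — the 20 N force threshold; runs shorter than 100 ms are
  discarded; partial contacts at the recording edges yield no event.

Angles: the 2D route measures relative segment angles (pelvis PSIS→ASIS,
thigh trochanter→knee, shank knee→ankle, foot heel→toe), flexion /
dorsiflexion / anterior tilt positive, neutral standing = 0°; hip flexion
is pelvis-referenced by default (lab-vertical reference selectable). The
3D route builds joint centres from a quiet-standing calibration — hip from
fixed fractions of the measured inter-ASIS distance in the pelvis technical
frame (a transparent geometric surrogate validated against simulator
truth), knee/ankle from the lateral markers plus half the measured width
along the leg-plane normal (fixed-point refined) — and measures
centre-to-centre angles with the static pose as the neutral reference.
Curves are time-normalized to 101 samples per cycle; ranges of motion are
max − min of the normalized curve. Parameters are extracted per trial and
then averaged over the session's valid trials (parameter-then-average, not
curve-averaging). The analysed cycle is the one containing the force
contact nearest mid-walkway (3D) or the cycle centred in the camera field
(2D); the first and last 0.25 s of each trial are excluded. Step length is
strike-to-strike: each heel is read at its own strike instant.

## 4. Agreement statistics

All coefficients derive from one two-way crossed ANOVA decomposition
(subjects × conditions, one observation per cell), so
SS_total = SS_subjects + SS_conditions + SS_error holds to rounding.
ICC(2,k) and ICC(3,k) — absolute agreement, average measures — share the
estimator (MSR − MSE)/(MSR + (MSC − MSE)/n); the labels encode whether
conditions are a random sample of raters or fixed. The p-value is the F
test of between-subject variance; the 95% CI uses the single-measure
F-bounds stepped up by Spearman–Brown (the intervals standard statistical
software prints for these options, cross-checked against `pingouin` in the
test suite). SEM = SD·√(1−ICC) with SD = √(SS_total/(n−1));
MDC95 = SEM·1.96·√2. The repeated-measures condition effect is
η² = SS_conditions/SS_total with its F test. Paired method agreement
reports Δ = mean(a−b), Cohen's d for paired data (Δ/SD of differences),
the paired t-test, and Bland–Altman bias ± 1.96·SD of differences.
Zero-variance degenerate cases surface as flags or typed errors, never as
silent zeros. The 2-SD outlier screen excludes a subject whose *any*
screened outcome deviates more than two sample SDs (subject included) from
the sample mean, applied once, never iterated; with fewer than three
subjects it is disabled with a warning. ICC acceptability labels use 0.7
(validity), 0.75 (reliability) and 0.9 (individual decisions).

## 5. Study orchestration

`run_study` simulates the complete design per seed: for each subject, three
raters apply the markers on day 1 in randomized order, the retest rater
returns after a uniform 1–18-day washout with lognormal day effects on
cadence and stride; each session has its own static calibration and its
placement shared by all six trials; both routes are extracted per trial and
side and averaged per session. The concurrent-validity table compares the
two routes on the retest rater's day-1 session; inter-rater reliability
uses the three day-1 3D sessions; test–retest uses the retest rater's two
days. Camera-dropout flags invalidate parameters whose markers leave the
image during the analysed cycle, reproducing the reduced per-cell n
real camera placements produce. Outputs are byte-reproducible per seed.

## 6. Validation strategy, and what it shows

* **Oracle equivalence** — the ICC/η²/SEM implementation equals a naive
  double-loop sums-of-squares oracle to 1e-10 and matches `pingouin`.
* **Parameter recovery** — on a zero-noise cohort, both routes recover
  every spatio-temporal parameter within 1%, every RoM within 0.5°,
  toe-off within 1 percentage point, and kinematic events within one frame
  at 100 Hz. Recovery is measured with a transparent 20 Hz validation
  filter so it isolates the *algorithms*; the production 6 Hz zero-lag
  filter additionally attenuates RoM by roughly 0.3–1.5° depending on
  subject and joint (a real property of 6 Hz filtering of gait curves, not
  an implementation defect), characterized in its own test.
* **Directional reproduction** — seed-averaged over ≥ 20 study replicates:
  2D toe-off later than force-plate toe-off; 2D hip and ankle RoM lower
  than 3D; spatio-temporal validity ICCs above RoM validity ICCs;
  test–retest ICC not above inter-rater ICC while day effects are on. The
  synthetic cohort makes no attempt to reproduce any published table's
  numerical cell values — those depend on unmeasured real-world noise
  magnitudes — it reproduces the formulas exactly and the patterns
  directionally.

What passing tests do **not** show: that real soft-tissue artifact is
angle-proportional with these gains, that real raters have 5 mm systematic
biases, or that real knee flexion plateaus at 16°. The simulator is an
instrument for studying the *measurement chain*, calibrated to printed
population marginals; its noise magnitudes are stated assumptions surfaced
in configuration, not estimates of any particular laboratory.

## 7. Numerical and degenerate-input choices

* Differentiation: central differences, one-sided at the ends.
* Normalization: linear interpolation onto a 101-point 0–100% grid;
  reversed or out-of-range cycle boundaries are errors.
* Coincident markers flag the frame (NaN) rather than aborting the trial.
* Filtering requires at least 3 × order samples and a cutoff below Nyquist.
* The IK clamps hip–ankle distance at 0.999999 × leg length as a last-resort
  guard; the pelvis-height fit keeps the motion away from it by design.
* Ties in the heel-strike acceleration argmax resolve to the earliest frame.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; subject-fixed properties (skin-artifact phases, rater
  biases) derive from stable hashes so they survive process boundaries.
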