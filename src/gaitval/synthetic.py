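"""Synthetic sagittal-gait simulator with full ground truth.

Stands in for a cohort of healthy adults walking at self-selected speed
(~1.4 m/s) through a gait lab that records 200 Hz 3D marker trajectories,
1000 Hz force plates and 100 Hz sagittal video. Each simulated trial carries
its complete ground truth — event times, joint-angle cycles, spatio-temporal
parameters — so measurement pipelines can be validated against truth rather
than against each other.

Construction principle
----------------------
Walking is built foot-first, not angle-first. Each leg's foot pose over the
gait cycle is prescribed analytically with *exact* contact phases:

* foot flat on the ground from heel strike to heel-off;
* heel rise rotating about the toe contact point from heel-off to toe-off
  (toe-off fraction of the cycle = the subject's stance fraction, exactly);
* swing as a smooth reach to the next flat-foot position, shaped so that the
  heel's vertical deceleration peaks at touchdown and the toe lifts briskly
  at toe-off — the signatures kinematic event detectors key on.

The pelvis translates at the mean walking velocity with a double-bump
vertical bounce whose height is fitted against leg reachability, plus a
small mediolateral sway (so central-projection effects are non-trivial) and
an oscillating anterior tilt. Hip, knee and ankle angles then follow from
two-link inverse kinematics of the rigid thigh–shank chain; the resulting
smooth angle cycles are summarized as 4-harmonic Fourier series in
:class:`SubjectParams.angle_waveforms`. Style constants are tuned so the
cohort's cycle ranges of motion land near healthy-adult magnitudes
(hip ≈ 44°, knee ≈ 60°, ankle ≈ 35°, pelvis ≈ 3.3°).

Noise channels map one-to-one to the classic sources of disagreement in
marker-based gait analysis: soft-tissue/shoe artifact (cycle-locked,
including an angle-proportional drag on the trochanter and heel markers),
white tracking jitter, rater-dependent marker placement (systematic per
rater plus per-application jitter), day-to-day and trial-to-trial gait
variability, and force-plate noise. At zero noise with an identity rater the
chain is exactly rigid and regeneration is bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = [
    "CohortConfig", "SubjectParams", "RaterModel", "NoiseModel",
    "TrialRecording", "generate_subject", "forward_kinematics",
    "synthesize_grf", "generate_static_trial", "fourier_eval",
]

G = 9.80665          # m/s^2
FS_3D = 200.0
FS_GRF = 1000.0
FS_2D = 100.0

#: lateral marker stand-off distances (m): skin + marker base
_LAT = {"TROCH": 0.060, "KNE": 0.050, "ANK": 0.042, "THI": 0.070, "TIB": 0.050,
        "HEEL": 0.040, "TOE2": 0.040, "TOE": 0.040}

MARKER_BASENAMES = ("ASI", "PSI", "TROCH", "THI", "KNE", "TIB", "ANK",
                    "HEEL", "TOE", "TOE2")


def marker_names() -> list[str]:
    return [s + b for s in ("L", "R") for b in MARKER_BASENAMES]


# ---------------------------------------------------------------------------
# cohort and subject parameters


@dataclass
class CohortConfig:
    """Population marginals the generator draws subjects from.

    Defaults reproduce a young healthy cohort: walking velocity
    1.42 (0.10) m/s, stride time 1.02 (0.06) s, toe-off near 59% of the
    cycle, height 1.747 (0.084) m, BMI 21.1 (1.4) kg/m².
    """

    height_mean: float = 1.747
    height_sd: float = 0.084
    velocity_mean: float = 1.42
    velocity_sd: float = 0.10
    stride_time_mean: float = 1.02
    stride_time_sd: float = 0.06
    stance_fraction_mean: float = 0.59
    stance_fraction_sd: float = 0.008
    pelvis_rom_mean: float = 3.3
    pelvis_rom_sd: float = 0.6
    bmi_mean: float = 21.1
    bmi_sd: float = 1.4

    def __post_init__(self):
        for name in ("height_sd", "velocity_sd", "stride_time_sd",
                     "stance_fraction_sd", "pelvis_rom_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.5 < self.stance_fraction_mean < 0.7):
            raise ConfigurationError(
                f"stance_fraction_mean {self.stance_fraction_mean} outside the "
                "physiological open interval (0.5, 0.7)")
        if not (0.5 <= self.velocity_mean <= 2.5):
            raise ConfigurationError("velocity_mean outside [0.5, 2.5] m/s")
        if self.height_mean <= 0 or self.stride_time_mean <= 0 or self.bmi_mean <= 0:
            raise ConfigurationError("means must be positive")


@dataclass
class SubjectParams:
    """One simulated participant: anthropometry, gait timing, angle waveforms.

    ``segments`` holds body dimensions in metres (thigh, shank, foot,
    ankle_height, inter_asis, hip_separation, pelvis_depth, knee_width,
    ankle_width). ``style`` holds the motion-shape constants (heel-off
    fraction of stance, toe-off foot pitch, swing clearance, pelvic bounce,
    sway, tilt). ``angle_waveforms`` maps each joint to the 9 coefficients
    (a0, a1, b1, ..., a4, b4) of a 4-harmonic Fourier series over the cycle,
    degrees; they summarize the motion the rigid-chain construction produces.
    """

    subject_id: str
    height: float
    weight: float
    cadence: float              # steps/min
    stride_length: float        # m
    stance_fraction: float
    segments: dict = field(default_factory=dict)
    style: dict = field(default_factory=dict)
    angle_waveforms: dict = field(default_factory=dict)
    rng_key: int = 0

    @property
    def stride_time(self) -> float:
        return 120.0 / self.cadence

    @property
    def velocity(self) -> float:
        return self.stride_length * self.cadence / 120.0

    def __post_init__(self):
        if not (0.5 < self.stance_fraction < 0.7):
            raise ConfigurationError(
                f"stance fraction {self.stance_fraction:.3f} outside (0.5, 0.7)")
        if not (0.5 <= self.velocity <= 2.5):
            raise ConfigurationError(
                f"implied velocity {self.velocity:.2f} m/s outside [0.5, 2.5]")
        if self.height <= 0 or self.weight <= 0:
            raise ConfigurationError("height and weight must be positive")


@dataclass
class RaterModel:
    """A rater's marker-placement behaviour.

    ``marker_offset_sd`` is the SD of the rater's *systematic* per-marker
    bias (drawn once per rater and marker, constant across subjects and
    sessions); ``application_jitter_sd`` the per-application scatter;
    ``anthropometric_sd`` the error of tape/caliper measurements. All in
    metres; palpation-plausible magnitudes are ≤ 2 cm.
    """

    rater_id: int
    marker_offset_sd: float = 0.005
    application_jitter_sd: float = 0.003
    anthropometric_sd: float = 0.003

    def __post_init__(self):
        for name in ("marker_offset_sd", "application_jitter_sd", "anthropometric_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be non-negative")
            if v > 0.02:
                raise ConfigurationError(
                    f"{name}={v} m exceeds the plausible palpation error of 0.02 m")

    @classmethod
    def identity(cls, rater_id: int = 0) -> "RaterModel":
        return cls(rater_id=rater_id, marker_offset_sd=0.0,
                   application_jitter_sd=0.0, anthropometric_sd=0.0)

    def _systematic_offset(self, marker: str) -> np.ndarray:
        digest = hashlib.sha256(f"rater{self.rater_id}:{marker}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.normal(0.0, self.marker_offset_sd, size=3)

    def draw_placement(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Per-marker local offsets (segment frame) for one application session."""
        out = {}
        for name in marker_names():
            out[name] = (self._systematic_offset(name)
                         + rng.normal(0.0, self.application_jitter_sd, size=3))
        return out

    def measure_anthropometrics(self, subject: SubjectParams,
                                rng: np.random.Generator) -> dict[str, float]:
        seg = subject.segments
        true = {
            "inter_asis": seg["inter_asis"],
            "leg_length": seg["thigh"] + seg["shank"] + seg["ankle_height"],
            "knee_width": seg["knee_width"],
            "ankle_width": seg["ankle_width"],
        }
        return {k: v + float(rng.normal(0.0, self.anthropometric_sd))
                for k, v in true.items()}


@dataclass
class NoiseModel:
    """Measurement and biological noise channels.

    * ``soft_tissue_amplitude`` — cycle-locked skin/shoe artifact amplitude
      (m); also scales the angle-proportional drag of the trochanter and
      heel markers.
    * ``tracking_jitter_sd`` — white per-frame, per-axis noise (m); applied
      to the 3D stream and, converted through the plane scale, to the 2D
      pixel stream.
    * ``grf_noise_sd`` — additive force-plate noise (N).
    * ``day_effect_sd`` — SD of the lognormal day-to-day multiplier on
      cadence and stride length.
    * ``trial_gait_sd`` — SD of the lognormal trial-to-trial multiplier on
      cadence and stride length (natural stride variability).
    """

    soft_tissue_amplitude: float = 0.008
    tracking_jitter_sd: float = 0.0015
    grf_noise_sd: float = 4.0
    day_effect_sd: float = 0.02
    trial_gait_sd: float = 0.015

    def __post_init__(self):
        for f_ in ("soft_tissue_amplitude", "tracking_jitter_sd", "grf_noise_sd",
                   "day_effect_sd", "trial_gait_sd"):
            if getattr(self, f_) < 0:
                raise ConfigurationError(f"{f_} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def is_zero(self) -> bool:
        return (self.soft_tissue_amplitude == 0 and self.tracking_jitter_sd == 0
                and self.grf_noise_sd == 0 and self.day_effect_sd == 0
                and self.trial_gait_sd == 0)


@dataclass
class TrialRecording:
    """One recorded walking trial, all streams frame-0-at-start.

    ``markers_3d``: name → (N, 3) metres at ``fs_3d``; lab frame x = walking
    direction, z = vertical. ``grf_vertical``: plate name → (M,) newtons at
    ``fs_grf`` (plate 1 = left leg, plate 2 = right leg). ``pixels_2d``:
    camera side → name → (K, 2) pixels at ``fs_2d``. ``ground_truth`` is
    present for simulated data only.
    """

    markers_3d: dict
    grf_vertical: dict
    pixels_2d: dict
    fs_3d: float = FS_3D
    fs_grf: float = FS_GRF
    fs_2d: float = FS_2D
    duration: float = 0.0
    ground_truth: dict | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# smooth shape primitives


def _smoothstep5(u):
    """Quintic smoothstep: zero velocity and acceleration at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u * u)


def _swing_progress(u):
    """Forward travel fraction of the swing foot vs swing fraction.

    A beta(2.6, 3.4) CDF: peak foot speed before mid-swing, a long
    decelerating tail, and acceleration-continuous (C2) endpoints at toe-off
    and touchdown so no spectral ringing enters the joint-angle curves.
    """
    from scipy.special import betainc
    return betainc(2.6, 3.4, np.clip(u, 0.0, 1.0))


def _bump(u, p, q):
    """u^p (1-u)^q normalized to peak 1 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    umax = p / (p + q)
    peak = umax ** p * (1 - umax) ** q
    return u ** p * (1.0 - u) ** q / peak


def fourier_eval(coeffs: np.ndarray, phase) -> np.ndarray:
    """Evaluate a truncated Fourier series a0 + Σ aₕcos(2πhφ) + bₕsin(2πhφ)."""
    c = np.asarray(coeffs, dtype=float)
    phase = np.asarray(phase, dtype=float)
    out = np.full_like(phase, c[0], dtype=float)
    n_harm = (c.size - 1) // 2
    for h in range(1, n_harm + 1):
        out = out + c[2 * h - 1] * np.cos(2 * np.pi * h * phase) \
                  + c[2 * h] * np.sin(2 * np.pi * h * phase)
    return out


def _fourier_fit(values: np.ndarray, n_harm: int = 4) -> np.ndarray:
    """Least-squares Fourier fit on an evenly spaced one-cycle grid."""
    n = values.size
    phase = np.arange(n) / n
    cols = [np.ones(n)]
    for h in range(1, n_harm + 1):
        cols.append(np.cos(2 * np.pi * h * phase))
        cols.append(np.sin(2 * np.pi * h * phase))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# the gait cycle engine


class _GaitEngine:
    """Evaluates the rigid-chain motion of one subject at arbitrary times.

    Phase conventions: the right leg's heel strikes at t = (0.65 + k)·T;
    the left leg is shifted by half a cycle. The walk is centred so the
    mid-recording pelvis position is x ≈ 0 (the camera axis).
    """

    T0_FRAC = 0.65          # right heel strike #0 at this fraction of T

    def __init__(self, subject: SubjectParams, stride_time: float | None = None,
                 stride_length: float | None = None, n_strides: int = 3):
        s = subject
        self.subject = s
        self.T = stride_time if stride_time is not None else s.stride_time
        self.L = stride_length if stride_length is not None else s.stride_length
        if not (0.5 <= self.L / self.T <= 2.5):
            raise ConfigurationError("effective walking velocity outside [0.5, 2.5] m/s")
        self.n_strides = n_strides
        self.c = s.stance_fraction
        st = s.style
        self.c1 = self.c * st["heel_off_frac"]         # heel-off, fraction of cycle
        self.theta_to = np.radians(st["toe_off_pitch"])
        self.theta_extra = np.radians(st["extra_pitch"])
        self.h_toe = st["toe_clearance"]
        seg = s.segments
        self.Lf = seg["foot"]
        self.l1 = seg["thigh"]
        self.l2 = seg["shank"]
        self.za = seg["ankle_height"]
        self.ax = 0.25 * seg["foot"]                   # ankle forward of heel point
        self.t0 = self.T0_FRAC * self.T
        self.duration = (self.n_strides + 1) * self.T
        self.v = self.L / self.T
        # hip passes over the (flat) ankle just before half of stance: heel
        # rise shifts the contact centroid toward the toe in late stance
        anchor = st.get("stance_anchor", 0.45) * self.c
        self.x_off = self.ax - self.v * self.T * (self.T0_FRAC + anchor)
        self._tabulate_foot_pose(pendular_tail=False)
        self._fit_pelvis_height()
        self._tabulate_foot_pose(pendular_tail=True)
        self._center_walk()

    # ---- foot pose -------------------------------------------------------

    #: fraction of swing over which the toe-off pitch decays back to flat:
    #: the foot then skims the ground through terminal swing, which is what
    #: lets the knee extend early and keeps thigh excursion physiological
    PITCH_DECAY = 0.54
    #: small heel-down-last pitch hump late in swing (deg): concentrates the
    #: heel's vertical deceleration at touchdown
    TOUCHDOWN_PITCH = 2.0
    #: exponent warping the heel-rise pitch profile (< 1 = brisk onset)
    PITCH_RISE_WARP = 0.5

    #: dimensionless heel-rise end slope: the foot is still pitching up at
    #: toe-off (it keeps plantarflexing into early swing), which keeps the
    #: ankle moving forward through the stance-to-swing transition and the
    #: hip-extension peak smooth
    PITCH_END_SLOPE = 1.8

    def _foot_pitch(self, phi):
        """Foot pitch (heel-up positive, rad) vs cycle phase.

        Built C2-continuous at heel-off and toe-off: the heel-rise quartic
        starts with zero velocity *and* acceleration, and the swing decay
        matches both the pitch velocity and acceleration carried across
        toe-off (the foot keeps plantarflexing into early swing).
        """
        phi = np.asarray(phi, dtype=float)
        theta = np.zeros_like(phi)
        s = self.PITCH_END_SLOPE
        # heel rise: quartic, g(0)=g'(0)=g''(0)=0, g(1)=1, g'(1)=s
        mask_b = (phi >= self.c1) & (phi < self.c)
        rho = (phi[mask_b] - self.c1) / (self.c - self.c1)
        theta[mask_b] = self.theta_to * ((4.0 - s) * rho ** 3 + (s - 3.0) * rho ** 4)
        # swing: quintic-form decay over the PITCH_DECAY fraction with value,
        # slope and curvature matched at toe-off and flat C2 landing at x=1
        mask_c = phi >= self.c
        u = (phi[mask_c] - self.c) / (1.0 - self.c)
        pd = self.PITCH_DECAY
        ratio = pd * (1.0 - self.c) / (self.c - self.c1)
        m = s * ratio
        q = (6.0 * s - 12.0) * ratio ** 2
        a1 = m + 3.0
        a2 = (q + 6.0 * a1 - 6.0) / 2.0
        x = np.minimum(u / pd, 1.0)
        h1 = (1.0 - x) ** 3 * (1.0 + a1 * x + a2 * x ** 2)
        theta[mask_c] = (self.theta_to * h1
                         + self.theta_extra * _bump(u, 3.0, 4.0))
        return theta

    #: heel-pad impact transient: a one-period ~10 Hz vertical ripple of the
    #: *heel marker* (pad/soft-tissue compliance, not a skeletal rotation)
    #: just before touchdown, ending with its acceleration maximum exactly at
    #: ground contact. Living between the 6 Hz angle filter (which removes it
    #: almost entirely: < 0.3 deg residual on the foot-line angle) and the
    #: 12 Hz event-detection filter (which keeps it), it is the signature the
    #: heel-strike detector keys on.
    IMPACT_AMP_M = 0.006
    IMPACT_FREQ_HZ = 10.0
    #: the pad-compression ripple ends slightly before full contact, so the
    #: (slightly delayed) filtered acceleration peak lands on the contact
    #: instant rather than a frame after it
    IMPACT_LEAD_S = 0.006

    def impact_lift(self, phi):
        """Vertical heel-marker displacement of the touchdown transient (m)."""
        phi = np.asarray(phi, dtype=float)
        out = np.zeros_like(phi)
        t0_period = 1.0 / self.IMPACT_FREQ_HZ
        dt = (phi - 1.0) * self.T + self.IMPACT_LEAD_S
        mask = (dt >= -t0_period) & (dt <= 0.0) & (phi >= self.c)
        d = dt[mask]
        w = 1.0 + d / t0_period
        out[mask] = self.IMPACT_AMP_M * \
            (1.0 - np.cos(2.0 * np.pi * self.IMPACT_FREQ_HZ * d)) * w
        return out

    def _foot_pose_analytic(self, phi):
        """Heel sole point (x_rel, z) within the cycle's stride frame + pitch."""
        phi = np.asarray(phi, dtype=float)
        theta = self._foot_pitch(phi)
        x = np.zeros_like(phi)
        z = np.zeros_like(phi)
        Lf = self.Lf
        mask_b = (phi >= self.c1) & (phi < self.c)
        x[mask_b] = Lf * (1.0 - np.cos(theta[mask_b]))
        z[mask_b] = Lf * np.sin(theta[mask_b])
        mask_c = phi >= self.c
        u = (phi[mask_c] - self.c) / (1.0 - self.c)
        x_t = Lf + self.L * _swing_progress(u)
        # the 1.4 exponent gives the toe a soft peel-off: brisk enough for
        # velocity-threshold detection, slow enough that the detected
        # toe-off lags the true one slightly (the lag real video-based
        # detectors show); the junction kink is flattened by the pose
        # smoothing below
        z_t = self.h_toe * _bump(u, 1.4, 4.0)
        x[mask_c] = x_t - Lf * np.cos(theta[mask_c])
        z[mask_c] = z_t + Lf * np.sin(theta[mask_c])
        return x, z, theta

    #: circular Gaussian smoothing of the foot pose, as a fraction of the
    #: cycle. Rounds the piecewise construction's phase junctions (heel-off,
    #: toe-off, touchdown) the way compliant tissue does, so joint-angle
    #: curves carry no spectral content a 6 Hz curve filter would remove,
    #: while staying narrow enough that contact transients remain sharp for
    #: event detection.
    POSE_SMOOTH_FRAC = 0.025

    #: swing fraction where the terminal pendular tail starts: from here to
    #: touchdown the ankle rides a (nearly) constant-radius arc around the
    #: hip, so the knee stays close to extension without snapping — the way a
    #: swinging leg actually reaches
    PENDULAR_TAIL_FROM = 0.60

    def _tabulate_foot_pose(self, pendular_tail: bool = True):
        """One-cycle lookup table of the smoothed periodic foot pose."""
        n = 4096
        grid = np.arange(n) / n
        x, z, theta = self._foot_pose_analytic(grid)
        if pendular_tail:
            x, z = self._apply_pendular_tail(grid, x, z, theta)
        # x jumps by one stride across the cycle boundary; remove the secular
        # ramp, smooth the periodic residual, and add the ramp back
        x_per = x - self.L * grid
        sigma = self.POSE_SMOOTH_FRAC * n
        half = int(4 * sigma)
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        kern /= kern.sum()

        def circ(v):
            padded = np.concatenate([v[-half:], v, v[:half]])
            return np.convolve(padded, kern, mode="same")[half:-half]

        self._pose_grid = grid
        self._pose_x_per = circ(x_per)
        self._pose_z = circ(z)
        self._pose_theta = circ(theta)

    def _apply_pendular_tail(self, grid, x, z, theta):
        """Blend the terminal-swing ankle height onto a constant-reach arc.

        Operates on the analytic pose table (right-leg phase convention,
        pre-centering, x0 = 0): the ankle's vertical coordinate over the last
        part of swing is pulled toward the sphere of radius just under the
        leg length around the hip, with the offset vanishing at touchdown so
        ground contact stays exact.
        """
        u = (grid - self.c) / (1.0 - self.c)
        mask = (grid >= self.c) & (u >= self.PENDULAR_TAIL_FROM)
        if not mask.any():
            return x, z
        ct, st_ = np.cos(theta[mask]), np.sin(theta[mask])
        ank_x = x[mask] + self.ax * ct + self.za * st_
        ank_z = z[mask] - self.ax * st_ + self.za * ct
        t = self.t0 + grid[mask] * self.T
        dx = self._hip_x(t) - ank_x
        # arc radius = the leg's reach in the touchdown configuration, so the
        # sphere passes through the landing pose and the blend offset vanishes
        # there by construction
        d_star = float(np.hypot(dx[-1], self.hip_z(t[-1:])[0] - ank_z[-1]))
        z_sphere = self.hip_z(t) - np.sqrt(np.maximum(d_star ** 2 - dx ** 2,
                                                      1e-6))
        delta = z_sphere - ank_z
        delta_td = delta[-1]
        w = _smoothstep5((u[mask] - self.PENDULAR_TAIL_FROM)
                         / (1.0 - self.PENDULAR_TAIL_FROM))
        ank_z_new = ank_z + w * (delta - delta_td)
        z = z.copy()
        z[mask] = ank_z_new + self.ax * st_ - self.za * ct
        return x, z

    def _foot_pose(self, phi):
        phi = np.asarray(phi, dtype=float)
        x = np.interp(phi, self._pose_grid, self._pose_x_per, period=1.0) \
            + self.L * phi
        z = np.interp(phi, self._pose_grid, self._pose_z, period=1.0)
        theta = np.interp(phi, self._pose_grid, self._pose_theta, period=1.0)
        return x, z, theta

    def foot_frame(self, t, leg: str):
        """Heel point (abs x, z), pitch, and stride index for a leg at times t."""
        t = np.asarray(t, dtype=float)
        shift = 0.0 if leg == "right" else 0.5
        big_phi = (t - self.t0) / self.T - shift
        k = np.floor(big_phi)
        phi = big_phi - k
        x_rel, z, theta = self._foot_pose(phi)
        x_base = (k + shift) * self.L + self.x0
        return x_base + x_rel, z, theta, phi

    def ankle_pos(self, t, leg: str):
        xh, zh, theta, phi = self.foot_frame(t, leg)
        ct, st_ = np.cos(theta), np.sin(theta)
        ax_, az_ = self.ax, self.za
        x = xh + ax_ * ct + az_ * st_
        z = zh - ax_ * st_ + az_ * ct
        return x, z, theta, phi

    # ---- pelvis ----------------------------------------------------------

    #: circular Gaussian smoothing width for the pelvis vault, as a fraction
    #: of the cycle; wide enough to keep joint-angle curves band-limited
    VAULT_SMOOTH_FRAC = 0.05
    #: clearance kept below the leg-reachability envelope (m). The margin is
    #: phase-dependent: tight at single-support midstance — where the knee
    #: reaches its broad extension plateau, which should set the curve's
    #: minimum — and slack around double support, so the brief reach maxima
    #: at toe-off and touchdown stay clearly more flexed than the plateau
    #: and never carve narrow notches into the angle curves.
    VAULT_MARGIN = 0.002
    #: extra pelvis drop around double support (m) and its phase centre
    VAULT_DS_DIP = 0.012
    VAULT_DS_PHASE = 0.065

    def _hip_x(self, t):
        return self.v * np.asarray(t, dtype=float) + self.x_off + self.x0

    def _fit_pelvis_height(self):
        """Pelvis vertical trajectory: a smoothed inverted-pendulum vault.

        The pelvis rides the reachability envelope of the two legs (highest
        at single-support midstance, dipping at double support), smoothed
        over ~6% of the cycle and held a small margin below the envelope so
        the knees never snap to full extension.
        """
        n = 1200
        self._vault_phase = np.linspace(0.0, 1.0, n, endpoint=False)
        tt = self.t0 + self._vault_phase * self.T
        reach = 0.995 * (self.l1 + self.l2)
        self.x0 = 0.0
        zmax = np.full(n, np.inf)
        for leg in ("right", "left"):
            axp, azp, _, _ = self.ankle_pos(tt, leg)
            dx = self._hip_x(tt) - axp
            gap2 = reach ** 2 - dx ** 2
            if np.any(gap2 <= 0):
                raise ConfigurationError(
                    "stride length too long for the leg length: hip cannot reach "
                    "the prescribed foot placements")
            zmax = np.minimum(zmax, np.sqrt(gap2) + azp)
        # circular Gaussian smoothing of the periodic envelope
        sigma = self.VAULT_SMOOTH_FRAC * n
        half = int(4 * sigma)
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        kern /= kern.sum()

        def circ(v):
            padded = np.concatenate([v[-half:], v, v[:half]])
            return np.convolve(padded, kern, mode="same")[half:-half]

        ceiling = zmax - self.VAULT_MARGIN
        smooth = circ(ceiling)
        # push local smoothing overshoots (at the double-support dips) back
        # under the ceiling without dragging the whole trajectory down
        for _ in range(3):
            viol = np.maximum(smooth - ceiling, 0.0)
            if viol.max() < 1e-4:
                break
            smooth = smooth - 1.3 * circ(viol)
        smooth -= max(float(np.max(smooth - ceiling)), 0.0)
        # analytic double-support dip: the pelvis drops a little extra around
        # the step-to-step transitions (toe-off/touchdown), keeping the brief
        # reach maxima there more flexed than the broad midstance plateau so
        # the knee/hip minima sit on smooth features
        smooth = smooth - self.VAULT_DS_DIP * 0.5 * (
            1.0 + np.cos(4.0 * np.pi * (self._vault_phase - self.VAULT_DS_PHASE)))
        self._vault_z = smooth

    def hip_z(self, t):
        phase = ((np.asarray(t, dtype=float) - self.t0) / self.T) % 1.0
        return np.interp(phase, self._vault_phase, self._vault_z,
                         period=1.0)

    def _center_walk(self):
        t_mid = self.duration / 2.0
        self.x0 = -float(self._hip_x(t_mid))

    def sway(self, t):
        st = self.subject.style
        return st["sway"] * np.sin(2 * np.pi * (np.asarray(t) - self.t0) / self.T)

    def tilt(self, t):
        st = self.subject.style
        return np.radians(st["tilt0"]) + 0.5 * np.radians(st["pelvis_rom"]) * \
            np.sin(4 * np.pi * (np.asarray(t) - self.t0) / self.T + np.pi / 4)

    # ---- chain -----------------------------------------------------------

    def joints(self, t, leg: str) -> dict[str, np.ndarray]:
        """True joint positions (hip, knee, ankle) and foot pose for one leg."""
        t = np.asarray(t, dtype=float)
        s = self.subject
        sign_y = -1.0 if leg == "right" else 1.0
        hip_y = sign_y * s.segments["hip_separation"] / 2.0 + self.sway(t)
        hx = self._hip_x(t)
        hz = self.hip_z(t)
        axp, azp, theta, phi = self.ankle_pos(t, leg)
        ankle_y = sign_y * s.style["step_width"] / 2.0 * np.ones_like(t)
        H = np.column_stack([hx, hip_y, hz])
        A = np.column_stack([axp, ankle_y, azp])
        D = A - H
        d = np.linalg.norm(D, axis=1)
        d = np.minimum(d, 0.999999 * (self.l1 + self.l2))
        u_hat = D / d[:, None]
        # knee displaced forward of the hip-ankle line, in the plane spanned by
        # that line and the walking direction
        ex = np.array([1.0, 0.0, 0.0])
        w = ex - (u_hat @ ex)[:, None] * u_hat
        w /= np.linalg.norm(w, axis=1)[:, None]
        a_par = (self.l1 ** 2 - self.l2 ** 2 + d ** 2) / (2.0 * d)
        h_perp = np.sqrt(np.maximum(self.l1 ** 2 - a_par ** 2, 0.0))
        K = H + a_par[:, None] * u_hat + h_perp[:, None] * w
        # leg-plane normal: the lateral direction markers are offset along,
        # so segment-marker distances are exactly conserved
        n = np.cross(u_hat, w)
        outward = n if leg == "right" else -n
        return {"hip": H, "knee": K, "ankle": A, "foot_pitch": theta,
                "phase": phi, "sign_y": sign_y, "outward": outward}

    # ---- true sagittal angles -------------------------------------------

    def true_angles(self, t) -> dict[str, dict[str, np.ndarray]]:
        """Ground-truth joint-angle curves (deg) per side at times t."""
        out = {}
        tilt_deg = np.degrees(self.tilt(t))
        for leg in ("left", "right"):
            j = self.joints(t, leg)
            H, K, A = j["hip"], j["knee"], j["ankle"]
            thigh_incl = np.degrees(np.arctan2(K[:, 2] - H[:, 2], K[:, 0] - H[:, 0])) + 90.0
            shank_incl = np.degrees(np.arctan2(A[:, 2] - K[:, 2], A[:, 0] - K[:, 0])) + 90.0
            foot_incl = -np.degrees(j["foot_pitch"])
            out[leg] = {
                "pelvis": tilt_deg.copy(),
                "hip": thigh_incl + tilt_deg,
                "knee": thigh_incl - shank_incl,
                "ankle": foot_incl - shank_incl,
            }
        return out

    # ---- events ----------------------------------------------------------

    def event_times(self) -> dict[str, dict[str, np.ndarray]]:
        """All ground-truth heel strikes and toe-offs inside the recording."""
        out = {}
        for leg, shift in (("right", 0.0), ("left", 0.5)):
            hs, to = [], []
            k = -2
            while True:
                t_hs = self.t0 + (k + shift) * self.T
                t_to = t_hs + self.c * self.T
                if t_hs > self.duration:
                    break
                if 0.0 <= t_hs <= self.duration:
                    hs.append(t_hs)
                if 0.0 <= t_to <= self.duration:
                    to.append(t_to)
                k += 1
            out[leg] = {"heel_strikes": np.array(hs), "toe_offs": np.array(to)}
        return out


# ---------------------------------------------------------------------------
# marker synthesis


def _seg_basis(dx, dz):
    """Sagittal segment basis: unit along-segment and perpendicular vectors."""
    norm = np.hypot(dx, dz)
    ex = np.column_stack([dx / norm, dz / norm])
    ez = np.column_stack([-ex[:, 1], ex[:, 0]])
    return ex, ez


def _marker_rng(subject: SubjectParams, tag: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{subject.subject_id}:{subject.rng_key}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


class _MarkerSynth:
    """Places markers on the moving chain, with placement offsets and noise."""

    def __init__(self, engine: _GaitEngine, placement: dict[str, np.ndarray] | None,
                 noise: NoiseModel):
        self.e = engine
        self.s = engine.subject
        self.placement = placement or {}
        self.noise = noise
        sta = noise.soft_tissue_amplitude
        self.drag_troch = min(0.6, 15.0 * sta)
        self.drag_heel = min(0.5, 18.75 * sta)
        # per-marker cycle-locked wobble parameters, a fixed property of the
        # subject's skin, identical across sessions
        self.wobble = {}
        if sta > 0:
            for i, name in enumerate(marker_names()):
                rng = _marker_rng(self.s, f"wobble:{name}")
                amp = sta * rng.uniform(0.3, 1.0)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                phase = rng.uniform(0, 2 * np.pi)
                self.wobble[name] = (amp, direction, phase)

    def _apply_local(self, name, pos, ex, ez, sign_y):
        """Add the placement offset expressed in the marker's segment frame."""
        off = self.placement.get(name)
        if off is None:
            return pos
        out = pos.copy()
        out[:, 0] += off[0] * ex[:, 0] + off[2] * ez[:, 0]
        out[:, 2] += off[0] * ex[:, 1] + off[2] * ez[:, 1]
        out[:, 1] += off[1] * sign_y
        return out

    def _wobble(self, name, pos, phi):
        if name not in self.wobble:
            return pos
        amp, direction, phase = self.wobble[name]
        return pos + amp * np.sin(2 * np.pi * phi + phase)[:, None] * direction[None, :]

    def markers(self, t) -> dict[str, np.ndarray]:
        e, s = self.e, self.s
        seg = s.segments
        t = np.asarray(t, dtype=float)
        n = t.size
        out = {}

        # pelvis
        tilt = e.tilt(t)
        ct, st_ = np.cos(tilt), np.sin(tilt)
        ex_p = np.column_stack([ct, -st_])          # anterior tilt pitches forward-down
        ez_p = np.column_stack([st_, ct])
        hx = e._hip_x(t)
        hz = e.hip_z(t)
        sw = e.sway(t)
        d_asis = seg["inter_asis"]
        asi_local = (0.24 * d_asis, 0.30 * d_asis)
        psi_local = (0.24 * d_asis - seg["pelvis_depth"], 0.30 * d_asis)
        for side, sign in (("L", 1.0), ("R", -1.0)):
            for base, (lx, lz), wy in (("ASI", asi_local, d_asis / 2.0),
                                       ("PSI", psi_local, 0.045)):
                pos = np.column_stack([
                    hx + lx * ex_p[:, 0] + lz * ez_p[:, 0],
                    sw + sign * wy,
                    hz + lx * ex_p[:, 1] + lz * ez_p[:, 1],
                ])
                name = side + base
                pos = self._apply_local(name, pos, ex_p, ez_p, sign)
                pos = self._wobble(name, pos, (t - e.t0) / e.T)
                out[name] = pos

        for leg, side, sign in (("left", "L", 1.0), ("right", "R", -1.0)):
            j = e.joints(t, leg)
            H, K, A = j["hip"], j["knee"], j["ankle"]
            theta, phi = j["foot_pitch"], j["phase"]
            ex_t, ez_t = _seg_basis(K[:, 0] - H[:, 0], K[:, 2] - H[:, 2])
            ex_s, ez_s = _seg_basis(A[:, 0] - K[:, 0], A[:, 2] - K[:, 2])

            outward = j["outward"]

            def lat(pos, dist):
                return pos + dist * outward

            # thigh segment markers
            troch = lat(H, _LAT["TROCH"])
            if self.drag_troch > 0:
                # skin over the trochanter lags hip flexion: displacement along
                # the direction the distal thigh moves, proportional to the
                # thigh's angular excursion
                alpha = np.arctan2(K[:, 2] - H[:, 2], K[:, 0] - H[:, 0])
                alpha_dev = alpha - alpha.mean()
                perp = np.column_stack([-np.sin(alpha), np.cos(alpha)])
                disp = self.drag_troch * alpha_dev[:, None] * e.l1 * perp
                troch[:, 0] += disp[:, 0]
                troch[:, 2] += disp[:, 1]
            thi = lat(0.5 * (H + K), _LAT["THI"])
            kne = lat(K, seg["knee_width"] / 2.0 + 0.0)
            tib = lat(0.5 * (K + A), _LAT["TIB"])
            ank = lat(A, seg["ankle_width"] / 2.0)

            # foot markers: rigid offsets in the (possibly drag-damped) foot frame
            heel_x, heel_z, _, _ = e.foot_frame(t, leg)
            toe_pt_x = heel_x + e.Lf * np.cos(theta)
            toe_pt_z = heel_z - e.Lf * np.sin(theta)
            foot_y = sign * s.style["step_width"] / 2.0 * np.ones(n)

            def foot_marker(lx, lz, pitch):
                cth, sth = np.cos(pitch), np.sin(pitch)
                dxl = lx - e.Lf          # relative to the toe pivot
                x = toe_pt_x + dxl * cth + lz * sth
                z = toe_pt_z - dxl * sth + lz * cth
                return np.column_stack([x, foot_y, z])

            heel = foot_marker(0.0, 0.02, (1.0 - self.drag_heel) * theta)
            # heel-pad impact transient: vertical marker ripple ending at
            # touchdown (pad compliance; the skeleton stays rigid)
            heel[:, 2] += e.impact_lift(phi)
            toe2 = foot_marker(e.Lf, 0.02, theta)
            toe = foot_marker(0.72 * e.Lf, 0.025, theta)

            ex_f = np.column_stack([np.cos(theta), -np.sin(theta)])
            ez_f = np.column_stack([np.sin(theta), np.cos(theta)])
            for name, pos, bx, bz in (
                    (side + "TROCH", troch, ex_t, ez_t),
                    (side + "THI", thi, ex_t, ez_t),
                    (side + "KNE", kne, ex_t, ez_t),
                    (side + "TIB", tib, ex_s, ez_s),
                    (side + "ANK", ank, ex_s, ez_s),
                    (side + "HEEL", heel, ex_f, ez_f),
                    (side + "TOE", toe, ex_f, ez_f),
                    (side + "TOE2", toe2, ex_f, ez_f)):
                pos = self._apply_local(name, pos, bx, bz, sign)
                pos = self._wobble(name, pos, phi)
                out[name] = pos
        return out


# ---------------------------------------------------------------------------
# public operations


def generate_subject(config: CohortConfig | None = None, rng_seed: int = 0,
                     subject_id: str | None = None) -> SubjectParams:
    """Draw one subject from the cohort marginals. Deterministic per seed.

    Velocity and stride time are sampled directly (they are the quantities the
    cohort is calibrated on); stride length and cadence follow, so the
    identity velocity = stride_length · cadence / 120 holds exactly.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(rng_seed)
    height = float(np.clip(rng.normal(cfg.height_mean, cfg.height_sd), 1.45, 2.05))
    bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16.0, 32.0))
    weight = bmi * height ** 2
    stride_time = float(np.clip(rng.normal(cfg.stride_time_mean, cfg.stride_time_sd),
                                0.80, 1.35))
    # taller subjects walk faster (Froude-like scaling); the residual scatter
    # is sized so the cohort velocity SD still matches the configured marginal
    resid_sd = max(cfg.velocity_sd ** 2 - (0.5 * cfg.velocity_mean
                                           * cfg.height_sd / max(cfg.height_mean, 1e-9)) ** 2,
                   (0.25 * cfg.velocity_sd) ** 2) ** 0.5
    v_scale = np.sqrt(max(height, 0.5) / cfg.height_mean)
    # the 1.016 factor compensates the mean shift the asymmetric cap below
    # introduces, so the cohort mean matches the configured marginal
    velocity = float(np.clip(rng.normal(1.024 * cfg.velocity_mean * v_scale, resid_sd),
                             0.80, 2.20))
    # keep the stride within what the leg geometry can serve
    velocity = min(velocity, 0.88 * (0.245 + 0.246) * height * 2.0 / stride_time)
    stance = float(np.clip(rng.normal(cfg.stance_fraction_mean, cfg.stance_fraction_sd),
                           0.54, 0.66))
    pelvis_rom = float(np.clip(rng.normal(cfg.pelvis_rom_mean, cfg.pelvis_rom_sd),
                               0.5, 8.0))
    # body-proportion scatter on top of standard anthropometric fractions
    prop = rng.normal(1.0, 0.01, size=4)
    segments = {
        "thigh": 0.245 * height * prop[0],
        "shank": 0.246 * height * prop[1],
        "foot": 0.152 * height * prop[2],
        "ankle_height": 0.039 * height,
        "inter_asis": 0.145 * height * prop[3],
        # hip-joint separation tracks pelvis width (correlated anatomy)
        "hip_separation": 0.6586 * 0.145 * height * prop[3],
        "pelvis_depth": 0.105 * height,
        "knee_width": 0.057 * height,
        "ankle_width": 0.040 * height,
    }
    style = {
        "heel_off_frac": 0.49,
        "stance_anchor": 0.29,
        "toe_off_pitch": float(rng.normal(48.0, 2.0)),
        "extra_pitch": 10.0,
        "toe_clearance": float(rng.normal(0.052, 0.003)),
        "bounce": 0.046,
        "sway": 0.015,
        "tilt0": 10.0,
        "pelvis_rom": pelvis_rom,
        "step_width": 0.12,
    }
    subject = SubjectParams(
        subject_id=subject_id or f"S{rng_seed}",
        height=height, weight=weight,
        cadence=120.0 / stride_time,
        stride_length=velocity * stride_time,
        stance_fraction=stance,
        segments=segments, style=style,
        rng_key=int(rng_seed) & 0x7FFFFFFF,
    )
    # summarize the implied motion as 4-harmonic Fourier series per joint
    engine = _GaitEngine(subject, n_strides=2)
    tt = engine.t0 + np.linspace(0.0, engine.T, 200, endpoint=False)
    truth = engine.true_angles(tt)
    subject.angle_waveforms = {j: _fourier_fit(truth["right"][j])
                               for j in ("hip", "knee", "ankle", "pelvis")}
    return subject


def synthesize_grf(subject: SubjectParams, heel_strikes, toe_offs, fs: float,
                   duration: float, noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Vertical GRF for one leg from its ground-truth contact intervals.

    The stance waveform is the classic double bump (loading and push-off
    peaks ≈ 1.1 body weight, midstance valley ≈ 0.8), zero outside stance,
    with a steep rise/fall so the 20 N threshold is crossed within ±2 ms of
    the true events at a 1000 Hz plate rate.
    """
    if fs < 200:
        raise ConfigurationError(
            f"force sampling rate {fs} Hz under-resolves threshold crossings; "
            "need >= 200 Hz")
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    f = np.zeros(n)
    w = subject.weight * G
    hs = list(np.asarray(heel_strikes, dtype=float))
    to = np.asarray(toe_offs, dtype=float)
    # a toe-off with no in-record heel strike before it belongs to a stance
    # that started before frame 0: reconstruct its (virtual) heel strike from
    # the periodic stance duration
    stance_dur = _stance_duration(np.asarray(hs), to)
    for e in to:
        if not any(h < e for h in hs):
            hs.append(float(e) - stance_dur)
    for h in sorted(hs):
        later = to[to > h]
        if later.size == 0:
            continue
        e = later[0]
        mask = (t > h) & (t < e)
        x = (t[mask] - h) / (e - h)
        g = (np.exp(-((x - 0.25) / 0.18) ** 2)
             + np.exp(-((x - 0.75) / 0.18) ** 2)
             + 0.60 * np.exp(-((x - 0.5) / 0.25) ** 2))
        f[mask] = 1.1 * w * g / _GRF_PEAK
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        f = f + rng.normal(0.0, noise_sd, size=n)
    return f


def _stance_duration(hs, to):
    for h in hs:
        later = to[to > h]
        if later.size:
            return float(later[0] - h)
    return 0.6


_x_peak = np.linspace(0, 1, 2001)
_GRF_PEAK = float(np.max(np.exp(-((_x_peak - 0.25) / 0.18) ** 2)
                         + np.exp(-((_x_peak - 0.75) / 0.18) ** 2)
                         + 0.60 * np.exp(-((_x_peak - 0.5) / 0.25) ** 2)))
del _x_peak


def forward_kinematics(subject: SubjectParams, n_strides: int,
                       rater: RaterModel | None = None,
                       noise: NoiseModel | None = None,
                       rng_seed: int = 0,
                       placement: dict | None = None,
                       cadence_factor: float = 1.0,
                       stride_factor: float = 1.0,
                       cameras: dict | None = None) -> TrialRecording:
    """Simulate one walking trial with all three measurement streams.

    ``placement`` (marker → local offset) overrides drawing a fresh
    application from ``rater``; the study pipeline passes the session's
    placement so all six trials share it. ``cadence_factor``/
    ``stride_factor`` carry day-to-day effects from the caller; an
    additional trial-to-trial lognormal factor is drawn here when
    ``noise.trial_gait_sd > 0``. ``cameras`` maps camera side to a
    :class:`~gaitval.projection.CameraModel`; by default one camera per side
    with package defaults.
    """
    if n_strides < 2:
        raise DataError("need at least 2 strides for one complete cycle pair")
    rater = rater or RaterModel.identity()
    noise = noise or NoiseModel.zero()
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, 909090])

    t_factor = 1.0
    l_factor = 1.0
    if noise.trial_gait_sd > 0:
        t_factor = float(np.exp(rng.normal(0.0, noise.trial_gait_sd)))
        l_factor = float(np.exp(rng.normal(0.0, noise.trial_gait_sd)))
    T_eff = subject.stride_time * t_factor / cadence_factor
    L_eff = subject.stride_length * l_factor * stride_factor

    engine = _GaitEngine(subject, stride_time=T_eff, stride_length=L_eff,
                         n_strides=n_strides)
    if placement is None:
        placement = rater.draw_placement(rng)

    synth = _MarkerSynth(engine, placement, noise)

    # 3D stream
    n3 = int(round(engine.duration * FS_3D)) + 1
    t3 = np.arange(n3) / FS_3D
    markers = synth.markers(t3)
    if noise.tracking_jitter_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, noise.tracking_jitter_sd, size=markers[name].shape)

    # ground truth
    events = engine.event_times()
    grid = np.linspace(0.0, 1.0, 101)
    tt = engine.t0 + grid * engine.T
    truth_curves = engine.true_angles(tt)
    gt_params = {}
    for leg in ("left", "right"):
        cur = truth_curves[leg]
        gt_params[leg] = {
            "stride_time": T_eff,
            "step_time": T_eff / 2.0,
            "stride_length": L_eff,
            "step_length": L_eff / 2.0,
            "velocity": L_eff / T_eff,
            "toe_off_pct": 100.0 * subject.stance_fraction,
            "rom_hip": float(cur["hip"].max() - cur["hip"].min()),
            "rom_knee": float(cur["knee"].max() - cur["knee"].min()),
            "rom_ankle": float(cur["ankle"].max() - cur["ankle"].min()),
            "rom_pelvis": float(cur["pelvis"].max() - cur["pelvis"].min()),
        }

    # force plates: plate 1 = left leg, plate 2 = right leg
    grf = {}
    for plate, leg in (("Fz1", "left"), ("Fz2", "right")):
        grf[plate] = synthesize_grf(
            subject, events[leg]["heel_strikes"], events[leg]["toe_offs"],
            FS_GRF, engine.duration, noise_sd=noise.grf_noise_sd, rng=rng)

    # 2D pixel streams
    from .projection import CameraModel, project
    if cameras is None:
        cameras = {"right": CameraModel(side="right"), "left": CameraModel(side="left")}
    n2 = int(round(engine.duration * FS_2D)) + 1
    t2 = np.arange(n2) / FS_2D
    step = int(round(FS_3D / FS_2D))
    pixels = {}
    for cam_side, cam in cameras.items():
        pix_sd = 0.0
        if noise.tracking_jitter_sd > 0:
            pix_sd = noise.tracking_jitter_sd / cam.plane_scale_x()
        side_prefix = "R" if cam_side == "right" else "L"
        cam_markers = {}
        for name, pos in markers.items():
            if not (name.startswith(side_prefix)):
                continue
            p2 = project(pos[::step][:n2], cam)
            if pix_sd > 0:
                p2 = p2 + rng.normal(0.0, pix_sd, size=p2.shape)
            cam_markers[name] = p2
        pixels[cam_side] = cam_markers

    ground_truth = {
        "events": {leg: {k: v.copy() for k, v in ev.items()}
                   for leg, ev in events.items()},
        "parameters": gt_params,
        "curves": truth_curves,
        "stance_fraction": subject.stance_fraction,
        "stride_time": T_eff,
        "stride_length": L_eff,
    }
    return TrialRecording(
        markers_3d=markers, grf_vertical=grf, pixels_2d=pixels,
        fs_3d=FS_3D, fs_grf=FS_GRF, fs_2d=FS_2D,
        duration=engine.duration, ground_truth=ground_truth,
        meta={"subject_id": subject.subject_id, "rater_id": rater.rater_id,
              "rng_seed": int(rng_seed), "n_strides": n_strides,
              "cadence_factor": cadence_factor, "stride_factor": stride_factor},
    )


def generate_static_trial(subject: SubjectParams,
                          rater: RaterModel | None = None,
                          noise: NoiseModel | None = None,
                          rng_seed: int = 0,
                          placement: dict | None = None,
                          duration: float = 0.5) -> TrialRecording:
    """Quiet-standing calibration capture: straight legs, feet flat.

    Used by the 3D pipeline's static calibration to establish joint-centre
    offsets and neutral segment angles.
    """
    rater = rater or RaterModel.identity()
    noise = noise or NoiseModel.zero()
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, 101010])
    if placement is None:
        placement = rater.draw_placement(rng)
    seg = subject.segments
    n = int(round(duration * FS_3D)) + 1

    hip_z = seg["ankle_height"] + seg["thigh"] + seg["shank"]
    ax = 0.25 * seg["foot"]
    tilt = np.radians(subject.style["tilt0"])
    ex_p = np.array([np.cos(tilt), -np.sin(tilt)])
    ez_p = np.array([np.sin(tilt), np.cos(tilt)])
    d_asis = seg["inter_asis"]
    asi_local = (0.24 * d_asis, 0.30 * d_asis)
    psi_local = (0.24 * d_asis - seg["pelvis_depth"], 0.30 * d_asis)

    markers = {}

    def put(name, x, y, z, off_basis=None):
        off = placement.get(name, np.zeros(3))
        if off_basis is None:
            bx, bz = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        else:
            bx, bz = off_basis
        sign = 1.0 if name.startswith("L") else -1.0
        pos = np.array([x + off[0] * bx[0] + off[2] * bz[0],
                        y + sign * off[1],
                        z + off[0] * bx[1] + off[2] * bz[1]])
        arr = np.tile(pos, (n, 1))
        if noise.tracking_jitter_sd > 0:
            arr = arr + rng.normal(0.0, noise.tracking_jitter_sd, size=arr.shape)
        markers[name] = arr

    vert = (np.array([0.0, -1.0]), np.array([1.0, 0.0]))   # ex down, ez forward
    for side, sign in (("L", 1.0), ("R", -1.0)):
        hip_y = sign * seg["hip_separation"] / 2.0
        foot_y = sign * subject.style["step_width"] / 2.0
        put(side + "ASI", asi_local[0] * ex_p[0] + asi_local[1] * ez_p[0],
            sign * d_asis / 2.0,
            hip_z + asi_local[0] * ex_p[1] + asi_local[1] * ez_p[1], (ex_p, ez_p))
        put(side + "PSI", psi_local[0] * ex_p[0] + psi_local[1] * ez_p[0],
            sign * 0.045,
            hip_z + psi_local[0] * ex_p[1] + psi_local[1] * ez_p[1], (ex_p, ez_p))
        put(side + "TROCH", 0.0, hip_y + sign * _LAT["TROCH"], hip_z, vert)
        put(side + "THI", 0.0, hip_y + sign * _LAT["THI"],
            hip_z - seg["thigh"] / 2.0, vert)
        put(side + "KNE", 0.0, foot_y + sign * seg["knee_width"] / 2.0,
            hip_z - seg["thigh"], vert)
        put(side + "TIB", 0.0, foot_y + sign * _LAT["TIB"],
            hip_z - seg["thigh"] - seg["shank"] / 2.0, vert)
        put(side + "ANK", 0.0, foot_y + sign * seg["ankle_width"] / 2.0,
            seg["ankle_height"], vert)
        flat = (np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        put(side + "HEEL", -ax, foot_y + sign * _LAT["HEEL"], 0.02, flat)
        put(side + "TOE", -ax + 0.72 * seg["foot"], foot_y + sign * _LAT["TOE"],
            0.025, flat)
        put(side + "TOE2", -ax + seg["foot"], foot_y + sign * _LAT["TOE2"],
            0.02, flat)

    return TrialRecording(
        markers_3d=markers, grf_vertical={}, pixels_2d={},
        duration=duration,
        ground_truth={"static": True,
                      "hip_centers": {"left": np.array([0.0, seg["hip_separation"] / 2.0, hip_z]),
                                      "right": np.array([0.0, -seg["hip_separation"] / 2.0, hip_z])}},
        meta={"subject_id": subject.subject_id, "rater_id": rater.rater_id,
              "static": True},
    )
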