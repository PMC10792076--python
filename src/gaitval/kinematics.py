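"""Planar segmental model: filtering, joint angles, cycle normalization.

The 2D video path measures *relative segment angles* from marker pairs, not
joint-centre angles: each segment's inclination is the angle of the line
through its two markers, and a joint angle is the difference of the two
adjacent inclinations. Conventions (all read 0 in quiet standing with the
foot flat):

* pelvis: anterior tilt positive, inclination of the PSIS→ASIS line vs
  horizontal (sign flipped so that ASIS-down = anterior = positive);
* hip: flexion positive, thigh inclination relative to the pelvis segment
  (a lab-vertical reference is selectable);
* knee: flexion positive, thigh inclination minus shank inclination;
* ankle: dorsiflexion positive, foot-sole inclination minus shank
  inclination (the 90° between shank and foot in neutral is absorbed so
  anatomical neutral reads 0).

Angle curves are reported per frame in degrees and time-normalized to 101
samples over one gait cycle (0–100%). Range of motion is max minus min of
the normalized curve; it is invariant to the constant offsets that marker
placement errors introduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError, DataError, MissingMarkerError

__all__ = [
    "FilterSpec", "JointAngleCurve", "butterworth_lowpass", "segment_angle",
    "relative_angles", "time_normalize", "range_of_motion",
]

#: markers required by the planar model, per analysed side (side prefix resolved
#: by the caller): great trochanter, lateral knee, lateral ankle, heel, second
#: toe, and the ASIS/PSIS pair that forms the pelvis segment.
REQUIRED_MARKERS = ("TROCH", "KNE", "ANK", "HEEL", "TOE2", "ASI", "PSI")


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification (default 6 Hz, 2nd order, zero-lag)."""

    cutoff: float = 6.0
    order: int = 2
    zero_lag: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("filter cutoff must be positive")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")


def butterworth_lowpass(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Low-pass Butterworth filter along the first axis.

    Zero-lag mode applies the design forward and backward (``filtfilt``),
    squaring the magnitude response but cancelling the phase shift, so event
    timing derived from filtered signals is not displaced. DC gain is 1.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= fs / 2.0:
        raise ConfigurationError(
            f"cutoff {spec.cutoff} Hz is not below the Nyquist frequency {fs / 2.0} Hz")
    if x.shape[0] < 3 * spec.order:
        raise DataError(f"need at least {3 * spec.order} samples to filter")
    sos = _signal.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.zero_lag:
        padlen = min(x.shape[0] - 1, 3 * 2 * spec.order * 5)
        return _signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    return _signal.sosfilt(sos, x, axis=0)


def segment_angle(proximal, distal) -> np.ndarray:
    """Inclination of the proximal→distal segment vs the lab horizontal, degrees.

    Input arrays have shape (N, 2) with columns (x, z) in metric sagittal
    coordinates (or a single point each). The result is unwrapped across
    frames so it is continuous; its principal value lies in (-180, 180].
    Frames where the two markers coincide are flagged with NaN.
    """
    p = np.atleast_2d(np.asarray(proximal, dtype=float))
    d = np.atleast_2d(np.asarray(distal, dtype=float))
    if p.shape != d.shape or p.shape[-1] != 2:
        raise DataError("marker trajectories must have matching (N, 2) shapes")
    vec = d - p
    norm = np.hypot(vec[:, 0], vec[:, 1])
    degenerate = norm < 1e-12
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(vec[:, 1], vec[:, 0])
    if degenerate.all():
        return np.full(p.shape[0], np.nan)
    if degenerate.any():
        # interpolate through isolated degenerate frames before unwrapping,
        # then restore the NaN flags
        idx = np.arange(p.shape[0])
        ang = ang.copy()
        ang[degenerate] = np.interp(idx[degenerate], idx[~degenerate], ang[~degenerate])
    ang = np.unwrap(ang)
    out = np.degrees(ang)
    if degenerate.any():
        out[degenerate] = np.nan
    if p.shape[0] == 1:
        return out
    return out


@dataclass
class JointAngleCurve:
    """A sagittal joint-angle curve in degrees.

    ``normalized`` curves have exactly 101 samples covering 0–100% of the
    gait cycle; raw curves are per-frame at ``fs`` Hz.
    """

    joint: str
    side: str
    values: np.ndarray
    fs: float | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.joint not in ("hip", "knee", "ankle", "pelvis"):
            raise DataError(f"unknown joint {self.joint!r}")
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.normalized and self.values.shape[0] != 101:
            raise DataError("normalized curves must have exactly 101 samples")

    @property
    def rom(self) -> float:
        return range_of_motion(self.values)


def relative_angles(markers_2d: dict, side: str, fs: float | None = None,
                    hip_reference: str = "pelvis") -> dict[str, JointAngleCurve]:
    """Joint-angle curves from metric sagittal marker trajectories.

    Parameters
    ----------
    markers_2d : dict
        Maps the names in :data:`REQUIRED_MARKERS` to (N, 2) arrays of
        metric (x forward, z up) coordinates. Side prefixes must already be
        resolved by the caller.
    side : {"left", "right"}
    hip_reference : {"pelvis", "vertical"}
        Whether hip flexion is measured against the pelvis segment (default)
        or the lab vertical.
    """
    for name in REQUIRED_MARKERS:
        if name not in markers_2d:
            raise MissingMarkerError(name)
    if hip_reference not in ("pelvis", "vertical"):
        raise ConfigurationError("hip_reference must be 'pelvis' or 'vertical'")

    pelvis_raw = segment_angle(markers_2d["PSI"], markers_2d["ASI"])
    thigh_raw = segment_angle(markers_2d["TROCH"], markers_2d["KNE"])
    shank_raw = segment_angle(markers_2d["KNE"], markers_2d["ANK"])
    foot_raw = segment_angle(markers_2d["HEEL"], markers_2d["TOE2"])

    pelvis_tilt = -pelvis_raw                 # anterior (ASIS down) positive
    thigh_incl = thigh_raw + 90.0             # 0 when vertical, + when flexed forward
    shank_incl = shank_raw + 90.0
    foot_incl = foot_raw                      # 0 when sole horizontal

    hip = thigh_incl + (pelvis_tilt if hip_reference == "pelvis" else 0.0)
    knee = thigh_incl - shank_incl
    # dorsiflexion: the foot rotates toe-up relative to the shank, or
    # equivalently the shank inclines forward (knee ahead of ankle, which is a
    # *negative* shank inclination in this convention) over a flat foot
    ankle = foot_incl - shank_incl

    return {
        "pelvis": JointAngleCurve("pelvis", side, pelvis_tilt, fs=fs),
        "hip": JointAngleCurve("hip", side, hip, fs=fs),
        "knee": JointAngleCurve("knee", side, knee, fs=fs),
        "ankle": JointAngleCurve("ankle", side, ankle, fs=fs),
    }


def time_normalize(values, fs: float, heel_strikes: tuple[float, float],
                   n_points: int = 101) -> np.ndarray:
    """Resample one gait cycle onto a 0–100% grid by linear interpolation.

    ``heel_strikes`` are the two consecutive same-side heel-strike times in
    seconds (frame 0 is t = 0). Sample ``i`` of the output corresponds to
    ``i``% of the cycle; the endpoints are the (interpolated) curve values at
    the two heel strikes.
    """
    v = np.asarray(values, dtype=float)
    t0, t1 = heel_strikes
    if not t1 > t0:
        raise DataError(f"heel strikes must be increasing, got {t0} >= {t1}")
    times = np.arange(v.shape[0]) / fs
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise DataError("cycle extends beyond the recorded curve")
    grid = np.linspace(t0, t1, n_points)
    return np.interp(grid, times, v)


def range_of_motion(curve) -> float:
    """Max minus min of a joint-angle curve, degrees (always >= 0)."""
    if isinstance(curve, JointAngleCurve):
        curve = curve.values
    v = np.asarray(curve, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DataError("cannot compute range of motion of an empty/NaN curve")
    return float(v.max() - v.min())
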