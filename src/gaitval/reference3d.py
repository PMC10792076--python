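"""3D reference path: joint centres from static calibration, sagittal angles.

Plays the role of a conventional optoelectronic pipeline at desk scale:
a quiet-standing calibration capture plus tape/caliper anthropometrics
(inter-ASIS distance, leg length, knee and ankle width) define per-segment
joint-centre offsets; dynamic trials then yield joint-centre-based sagittal
angles, with events taken from the force plates (see
:func:`gaitval.events.detect_events_force`).

The hip-centre estimate is a transparent geometric surrogate — fixed
fractions of the measured inter-ASIS distance along the pelvis technical
frame — validated against simulator ground truth, not against any
commercial implementation. Trajectory smoothing uses the same zero-lag
Butterworth filter as the 2D path; a generalized cross-validated quintic
spline would add heavy machinery with negligible effect at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, MissingMarkerError
from .kinematics import JointAngleCurve

__all__ = ["JointCenterModel", "JointCenters", "static_calibration",
           "sagittal_angles_3d"]

#: hip centre offset, as fractions of the measured inter-ASIS distance,
#: applied in the pelvis technical frame (back from mid-ASIS, down, lateral)
HIP_BACK_FRAC = 0.24
HIP_DOWN_FRAC = 0.30
HIP_LATERAL_FRAC = 0.3293      # half the hip-separation / inter-ASIS ratio

REQUIRED_ANTHROPOMETRICS = ("inter_asis", "leg_length", "knee_width", "ankle_width")


@dataclass
class JointCenters:
    """Per-frame joint-centre trajectories for one side, metres."""

    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    side: str


@dataclass
class JointCenterModel:
    """Calibrated joint-centre offsets plus neutral-posture references."""

    anthropometrics: dict
    ankle_neutral_deg: dict = field(default_factory=dict)   # per side

    def centers(self, markers: dict, side: str) -> JointCenters:
        """Joint centres from a (filtered) marker dictionary."""
        prefix = side[0].upper()
        for base in ("ASI", "PSI", "KNE", "ANK"):
            for p in ("L", "R"):
                if p + base not in markers:
                    raise MissingMarkerError(p + base)
        d = self.anthropometrics["inter_asis"]
        mid_asi = 0.5 * (markers["LASI"] + markers["RASI"])
        mid_psi = 0.5 * (markers["LPSI"] + markers["RPSI"])
        xhat = _unit(mid_asi - mid_psi)
        yhat = _unit(markers["LASI"] - markers["RASI"])
        zhat = _unit(np.cross(xhat, yhat))
        yhat = np.cross(zhat, xhat)
        lat_sign = 1.0 if prefix == "L" else -1.0
        hip = (mid_asi - HIP_BACK_FRAC * d * xhat - HIP_DOWN_FRAC * d * zhat
               + lat_sign * HIP_LATERAL_FRAC * d * yhat)
        # medial direction per frame: normal of the plane spanned by the
        # hip-to-ankle axis and the walking direction (stable even with the
        # knee at full extension), oriented toward the body midline
        kne = markers[prefix + "KNE"]
        ank = markers[prefix + "ANK"]
        ex = np.array([1.0, 0.0, 0.0])
        # fixed-point refinement: the ankle centre both defines and depends
        # on the leg-plane normal; a few iterations reach sub-micron drift
        ankle = ank
        for _ in range(8):
            u = _unit(ankle - hip)
            w = _unit(ex - (u @ ex)[:, None] * u)
            n = np.cross(u, w)
            medial = n * np.where(n[:, 1:2] * (-lat_sign) > 0, 1.0, -1.0)
            ankle = ank + 0.5 * self.anthropometrics["ankle_width"] * medial
        knee = kne + 0.5 * self.anthropometrics["knee_width"] * medial
        return JointCenters(hip=hip, knee=knee, ankle=ankle, side=side)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(v)
    out = v / np.linalg.norm(v, axis=1)[:, None]
    return out


def static_calibration(static_markers: dict, anthropometrics: dict) -> JointCenterModel:
    """Build the joint-centre model from a quiet-standing capture.

    ``static_markers`` maps marker names to (N, 3) standing trajectories;
    ``anthropometrics`` must provide inter_asis, leg_length, knee_width and
    ankle_width (metres). The standing posture also defines each side's
    neutral shank–foot angle, which is subtracted from dynamic ankle curves
    so that anatomical neutral reads 0°.
    """
    for key in REQUIRED_ANTHROPOMETRICS:
        if key not in anthropometrics:
            raise ConfigurationError(f"missing anthropometric measurement {key!r}")
        if anthropometrics[key] < 0:
            raise ConfigurationError(f"anthropometric {key!r} must be non-negative")
    model = JointCenterModel(anthropometrics=dict(anthropometrics))
    # neutral ankle reference from the static pose
    for side in ("left", "right"):
        prefix = side[0].upper()
        if prefix + "TOE2" not in static_markers:
            raise MissingMarkerError(prefix + "TOE2")
        c = model.centers({k: v.mean(axis=0, keepdims=True)
                           for k, v in static_markers.items()}, side)
        toe2 = static_markers[prefix + "TOE2"].mean(axis=0, keepdims=True)
        foot_incl = _sagittal_incl(c.ankle, toe2)
        shank_incl = _sagittal_incl(c.knee, c.ankle) + 90.0
        model.ankle_neutral_deg[side] = float((foot_incl - shank_incl)[0])
    return model


def _sagittal_incl(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inclination (deg) of the a→b line projected on the sagittal plane."""
    d = np.atleast_2d(b) - np.atleast_2d(a)
    return np.degrees(np.arctan2(d[:, 2], d[:, 0]))


def sagittal_angles_3d(markers: dict, model: JointCenterModel, side: str,
                       fs: float | None = None) -> dict[str, JointAngleCurve]:
    """Joint-centre-based sagittal angle curves for one side.

    Conventions match the 2D segmental model (flexion / dorsiflexion /
    anterior tilt positive, neutral standing = 0°), so the two routes are
    directly comparable. The foot axis is ankle-centre → TOE2 with the
    static neutral offset removed.
    """
    prefix = side[0].upper()
    if prefix + "TOE2" not in markers:
        raise MissingMarkerError(prefix + "TOE2")
    c = model.centers(markers, side)
    mid_asi = 0.5 * (markers["LASI"] + markers["RASI"])
    mid_psi = 0.5 * (markers["LPSI"] + markers["RPSI"])
    pelvis_tilt = -_sagittal_incl(mid_psi, mid_asi)
    thigh_incl = _sagittal_incl(c.hip, c.knee) + 90.0
    shank_incl = _sagittal_incl(c.knee, c.ankle) + 90.0
    foot_incl = _sagittal_incl(c.ankle, markers[prefix + "TOE2"])
    ankle = (foot_incl - shank_incl) - model.ankle_neutral_deg.get(side, 0.0)
    return {
        "pelvis": JointAngleCurve("pelvis", side, pelvis_tilt, fs=fs),
        "hip": JointAngleCurve("hip", side, thigh_incl + pelvis_tilt, fs=fs),
        "knee": JointAngleCurve("knee", side, thigh_incl - shank_incl, fs=fs),
        "ankle": JointAngleCurve("ankle", side, ankle, fs=fs),
    }
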