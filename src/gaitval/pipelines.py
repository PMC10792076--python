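"""Per-trial extraction: from recorded streams to gait parameters.

Composes the measurement chain for each route:

* **3D reference**: zero-lag low-pass filtering of 200 Hz marker
  trajectories, force-plate events at the 20 N threshold, joint-centre
  sagittal angles, cycle normalization, spatio-temporal parameters. The
  analysed cycle is the one containing the force-plate contact closest to
  the walkway centre.
* **2D video**: metric sagittal trajectories (plane-calibrated pixels, or an
  orthographic sagittal view when validating the algorithms themselves),
  kinematic event detection from the heel and second-toe markers, relative
  segment angles, the cycle centred in the camera field. Step parameters
  are refused (contralateral heel strikes are not identifiable from one
  sagittal camera).

The first and last 0.25 s of every trial are excluded from cycle selection
to keep filter transients out of the analysis.
"""

from __future__ import annotations

import numpy as np

from . import events as _events
from . import kinematics as _kin
from . import stp as _stp
from .errors import DataError, EventDetectionError
from .projection import Calibration2D, pixels_to_meters
from .reference3d import JointCenterModel, sagittal_angles_3d
from .synthetic import TrialRecording

__all__ = ["extract_parameters_3d", "extract_parameters_2d",
           "trial_pixels_to_sagittal", "EDGE_TRIM_S"]

EDGE_TRIM_S = 0.25

_PLATE_FOR_SIDE = {"left": "Fz1", "right": "Fz2"}


def _filter_markers(markers: dict, fs: float, spec: _kin.FilterSpec) -> dict:
    return {name: _kin.butterworth_lowpass(pos, fs, spec)
            for name, pos in markers.items()}


def _select_cycle(cycles, duration: float, heel_x, fs: float,
                  center_x: float | None):
    """Pick the analysed cycle: centred in the field (2D) or in time (3D)."""
    valid = [c for c in cycles
             if c[0] >= EDGE_TRIM_S and c[2] <= duration - EDGE_TRIM_S]
    if not valid:
        raise EventDetectionError("no complete gait cycle clear of the trial edges")

    def cost(c):
        if center_x is None:
            return abs(0.5 * (c[0] + c[2]) - duration / 2.0)
        x0 = np.interp(c[0], np.arange(heel_x.size) / fs, heel_x)
        x1 = np.interp(c[2], np.arange(heel_x.size) / fs, heel_x)
        return abs(0.5 * (x0 + x1) - center_x)

    return min(valid, key=cost)


def extract_parameters_3d(trial: TrialRecording, center_model: JointCenterModel,
                          side: str, filter_spec: _kin.FilterSpec | None = None,
                          ) -> tuple[_stp.GaitParameters, dict]:
    """3D-route parameters and normalized angle curves for one leg."""
    spec = filter_spec or _kin.FilterSpec()
    fs = trial.fs_3d
    markers = _filter_markers(trial.markers_3d, fs, spec)
    prefix = side[0].upper()

    plate = _PLATE_FOR_SIDE[side]
    if plate not in trial.grf_vertical:
        raise DataError(f"no force-plate signal for the {side} leg")
    ev = _events.detect_events_force(trial.grf_vertical[plate], trial.fs_grf,
                                     side=side)
    heel_x = markers[prefix + "HEEL"][:, 0]
    h0, to, h1 = _select_cycle(ev.cycles(), trial.duration, heel_x, fs,
                               center_x=None)

    angles = sagittal_angles_3d(markers, center_model, side, fs=fs)
    curves = {}
    for joint, curve in angles.items():
        norm = _kin.time_normalize(curve.values, fs, (h0, h1))
        curves[joint] = _kin.JointAngleCurve(joint, side, norm, normalized=True)

    t_axis = np.arange(heel_x.size) / fs
    x_h0 = float(np.interp(h0, t_axis, heel_x))
    x_h1 = float(np.interp(h1, t_axis, heel_x))
    stride_len, step_len = np.nan, np.nan
    step_t = np.nan
    stride_len = x_h1 - x_h0

    contra = "left" if side == "right" else "right"
    contra_plate = _PLATE_FOR_SIDE[contra]
    if contra_plate in trial.grf_vertical:
        try:
            ev_c = _events.detect_events_force(trial.grf_vertical[contra_plate],
                                               trial.fs_grf, side=contra)
            prior = ev_c.heel_strikes[ev_c.heel_strikes < h0]
            if prior.size:
                step_t = _stp.step_time(h0, float(prior[-1]))
                # strike-to-strike convention: the contralateral heel is read
                # at its own strike instant (by the ipsilateral strike it has
                # already risen and advanced)
                contra_heel_x = markers[contra[0].upper() + "HEEL"][:, 0]
                x_contra = float(np.interp(float(prior[-1]), t_axis, contra_heel_x))
                step_len = x_h0 - x_contra
        except EventDetectionError:
            pass

    st = _stp.stride_time([h0, h1])
    params = _stp.GaitParameters(
        side=side, source="3D",
        stride_time=st,
        step_time=step_t,
        stride_length=stride_len,
        step_length=step_len,
        velocity=stride_len / st,
        toe_off_pct=_stp.toe_off_percent(h0, to, h1),
        rom_hip=curves["hip"].rom,
        rom_knee=curves["knee"].rom,
        rom_ankle=curves["ankle"].rom,
        rom_pelvis=curves["pelvis"].rom,
    )
    return params, curves


def trial_pixels_to_sagittal(trial: TrialRecording, camera_side: str,
                             calibration: Calibration2D) -> dict:
    """Plane-calibrated metric sagittal trajectories for one camera."""
    if camera_side not in trial.pixels_2d:
        raise DataError(f"no 2D stream for camera side {camera_side!r}")
    return {name: pixels_to_meters(pix, calibration)
            for name, pix in trial.pixels_2d[camera_side].items()}


#: event detection runs on more lightly smoothed trajectories than the angle
#: curves: the 6 Hz curve filter visibly spreads the sharp touchdown/lift-off
#: transients and would bias the detected times
EVENT_FILTER = _kin.FilterSpec(cutoff=12.0, order=2, zero_lag=True)


def extract_parameters_2d(markers_2d: dict, fs: float, side: str,
                          filter_spec: _kin.FilterSpec | None = None,
                          event_filter_spec: _kin.FilterSpec | None = None,
                          hip_reference: str = "pelvis",
                          center_x: float | None = 0.0,
                          duration: float | None = None,
                          ) -> tuple[_stp.GaitParameters, dict]:
    """2D-route parameters and normalized curves from metric sagittal data.

    ``markers_2d`` maps full marker names (e.g. ``"RHEEL"``) to (N, 2)
    metric trajectories for the analysed side. ``center_x`` is the camera
    field centre in the calibrated frame; pass None to centre in time
    instead (orthographic validation use).
    """
    spec = filter_spec or _kin.FilterSpec()
    ev_spec = event_filter_spec or EVENT_FILTER
    prefix = side[0].upper()
    required = {base: prefix + base for base in _kin.REQUIRED_MARKERS}
    for base, name in required.items():
        if name not in markers_2d:
            from .errors import MissingMarkerError
            raise MissingMarkerError(name)
    filt = {base: _kin.butterworth_lowpass(markers_2d[name], fs, spec)
            for base, name in required.items()}
    if duration is None:
        duration = (filt["HEEL"].shape[0] - 1) / fs

    heel_ev = _kin.butterworth_lowpass(markers_2d[prefix + "HEEL"], fs, ev_spec)
    toe_ev = _kin.butterworth_lowpass(markers_2d[prefix + "TOE2"], fs, ev_spec)
    ev = _events.detect_events_kinematic(heel_ev, toe_ev, fs, side=side)
    heel_x = filt["HEEL"][:, 0]
    h0, to, h1 = _select_cycle(ev.cycles(), duration, heel_x, fs, center_x)

    angles = _kin.relative_angles(filt, side, fs=fs, hip_reference=hip_reference)
    curves = {}
    for joint, curve in angles.items():
        norm = _kin.time_normalize(curve.values, fs, (h0, h1))
        curves[joint] = _kin.JointAngleCurve(joint, side, norm, normalized=True)

    t_axis = np.arange(heel_x.size) / fs
    x_h0 = float(np.interp(h0, t_axis, heel_x))
    x_h1 = float(np.interp(h1, t_axis, heel_x))
    st = _stp.stride_time([h0, h1])
    stride_len, _ = _stp.stride_and_step_lengths([x_h0, x_h1], None, source="2D")
    params = _stp.GaitParameters(
        side=side, source="2D",
        stride_time=st,
        stride_length=stride_len,
        velocity=stride_len / st,
        toe_off_pct=_stp.toe_off_percent(h0, to, h1),
        rom_hip=curves["hip"].rom,
        rom_knee=curves["knee"].rom,
        rom_ankle=curves["ankle"].rom,
        rom_pelvis=curves["pelvis"].rom,
    )
    return params, curves


def orthographic_sagittal(trial: TrialRecording, side: str,
                          fs_out: float | None = None) -> tuple[dict, float]:
    """Side-view (x, z) trajectories straight from the 3D stream.

    Bypasses the camera: used to validate the 2D measurement algorithms
    themselves (events, angles, STP) against ground truth without
    central-projection effects. Returns (markers_2d, fs).
    """
    fs_out = fs_out or trial.fs_2d
    step = int(round(trial.fs_3d / fs_out))
    if step < 1 or abs(trial.fs_3d / step - fs_out) > 1e-9:
        raise DataError("fs_out must divide the 3D sampling rate")
    prefix = side[0].upper()
    out = {}
    for name, pos in trial.markers_3d.items():
        if name.startswith(prefix):
            out[name] = pos[::step][:, [0, 2]]
    return out, fs_out
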