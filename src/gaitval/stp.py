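"""Spatio-temporal gait parameters and six-trial averaging.

Parameters are extracted per trial from one analysed gait cycle (the cycle
containing the force-plate contact for the 3D route, or the cycle centred in
the camera field for the 2D route) and then averaged across the session's
valid trials — parameter-then-average order, not curve-averaging.

Step parameters need the contralateral heel strike; the single-camera 2D
route cannot identify it (the far leg is occluded and off the calibration
plane), so requesting them from a 2D source raises :class:`CapabilityError`
rather than returning an approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .errors import CapabilityError, DataError

__all__ = ["GaitParameters", "stride_time", "step_time", "toe_off_percent",
           "stride_and_step_lengths", "average_trials"]

#: scalar outcome fields, in the order the study tables report them
PARAMETER_FIELDS = ("stride_time", "step_time", "stride_length", "step_length",
                    "velocity", "toe_off_pct", "rom_hip", "rom_knee",
                    "rom_ankle", "rom_pelvis")


@dataclass
class GaitParameters:
    """Per-trial (or session-averaged) scalar outcomes for one leg.

    Units: times s, lengths m, velocity m/s, toe-off % of gait cycle,
    RoM degrees. Fields that a source cannot provide are NaN.
    """

    side: str
    source: str                      # "2D" | "3D" | "truth"
    stride_time: float = np.nan
    step_time: float = np.nan
    stride_length: float = np.nan
    step_length: float = np.nan
    velocity: float = np.nan
    toe_off_pct: float = np.nan
    rom_hip: float = np.nan
    rom_knee: float = np.nan
    rom_ankle: float = np.nan
    rom_pelvis: float = np.nan
    n_trials_averaged: int = 1

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.source not in ("2D", "3D", "truth"):
            raise DataError(f"source must be '2D', '3D' or 'truth', got {self.source!r}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def stride_time(heel_strikes, cycle: int = 0) -> float:
    """Time between consecutive same-side heel strikes, seconds."""
    hs = np.asarray(heel_strikes, dtype=float)
    if hs.size < 2:
        raise DataError("stride time needs at least two heel strikes")
    if not 0 <= cycle < hs.size - 1:
        raise DataError(f"cycle index {cycle} out of range for {hs.size} heel strikes")
    return float(hs[cycle + 1] - hs[cycle])


def step_time(ipsilateral_hs: float, contralateral_hs: float) -> float:
    """Contralateral-to-ipsilateral heel-strike interval, seconds."""
    dt = ipsilateral_hs - contralateral_hs
    if dt <= 0:
        raise DataError("contralateral heel strike must precede the ipsilateral one")
    return float(dt)


def toe_off_percent(hs: float, to: float, next_hs: float) -> float:
    """Toe-off as a percentage of the gait cycle."""
    if not hs < to < next_hs:
        raise DataError(
            f"toe-off {to} must lie strictly inside the cycle ({hs}, {next_hs})")
    return float(100.0 * (to - hs) / (next_hs - hs))


def stride_and_step_lengths(heel_x_at_hs, contralateral_heel_x: float | None = None,
                            source: str = "3D") -> tuple[float, float]:
    """Stride length and (3D only) step length, metres.

    ``heel_x_at_hs`` holds the ipsilateral heel's forward positions at two
    consecutive heel strikes; ``contralateral_heel_x`` the contralateral
    heel's position at the (second) ipsilateral heel strike. Returns
    ``(stride_length, step_length)``; step length is NaN when no
    contralateral position is given.
    """
    x = np.asarray(heel_x_at_hs, dtype=float)
    if x.size != 2:
        raise DataError("need the heel position at exactly two consecutive heel strikes")
    stride = float(x[1] - x[0])
    if stride == 0.0:
        warnings.warn("zero stride length: identical heel positions at "
                      "consecutive heel strikes", stacklevel=2)
    if source == "2D" and contralateral_heel_x is not None:
        raise CapabilityError(
            "step length is not computable from the single-camera 2D route: "
            "the contralateral heel strike cannot be identified")
    if contralateral_heel_x is None:
        return stride, float("nan")
    return stride, float(x[1] - contralateral_heel_x)


def average_trials(per_trial: list[GaitParameters]) -> GaitParameters:
    """Arithmetic mean of each parameter across a session's valid trials.

    All trials must share side and source. NaN fields stay NaN in the mean
    (a parameter unavailable in any trial is reported unavailable).
    """
    if not per_trial:
        raise DataError("no trials to average")
    side = per_trial[0].side
    source = per_trial[0].source
    for t in per_trial[1:]:
        if t.side != side or t.source != source:
            raise DataError("cannot average trials with mixed side or source")
    out = GaitParameters(side=side, source=source,
                         n_trials_averaged=len(per_trial))
    for name in PARAMETER_FIELDS:
        vals = np.array([getattr(t, name) for t in per_trial], dtype=float)
        setattr(out, name, float(vals.mean()))
    return out
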