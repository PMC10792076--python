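"""Gait event detection: force-plate thresholding and marker kinematics.

Two detection routes coexist, mirroring how 3D and 2D gait labs work:

* **Force threshold** (reference route): heel strike is the first sample of a
  supra-threshold run of vertical ground-reaction force (default 20 N),
  toe-off the first sample after the run ends. Runs shorter than 100 ms are
  treated as noise and discarded.
* **Kinematic** (video route): heel strike from the heel marker — within each
  window where the heel's forward velocity drops below a fraction of its
  cycle mean, the event is the frame of peak vertical acceleration (the
  downward motion being arrested at touchdown); toe-off from the second-toe
  marker — the frame where its vertical velocity first exceeds a positive
  threshold after the stance minimum of vertical position.

The kinematic thresholds are surrogates for a commercial tracker's
unpublished constants; they are explicit keyword parameters so every run can
log them. Differentiation uses central differences (one-sided at the ends)
on trajectories the caller has already low-pass filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EventDetectionError

__all__ = ["GaitEvents", "detect_events_force", "detect_heel_strike_kinematic",
           "detect_toe_off_kinematic", "detect_events_kinematic"]

FORCE_THRESHOLD_N = 20.0
MIN_CONTACT_S = 0.100


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (seconds) for one leg.

    Events are strictly interleaved: hs[i] < to[i] < hs[i+1]. ``method``
    records provenance; ``force_threshold`` is only meaningful for the force
    route.
    """

    side: str
    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    method: str                       # "force_threshold" | "kinematic"
    force_threshold: float | None = None
    failures: list = field(default_factory=list)

    def __post_init__(self):
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.method not in ("force_threshold", "kinematic"):
            raise DataError(f"unknown event method {self.method!r}")
        self._check_interleaving()

    def _check_interleaving(self):
        hs, to = self.heel_strikes, self.toe_offs
        if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
            raise DataError("event times must be strictly ascending")
        # no toe-off may coincide with a heel strike, and each cycle
        # (consecutive heel-strike pair) holds at most one toe-off
        if hs.size and to.size and np.isin(to, hs).any():
            raise DataError("toe-off coincides with a heel strike")
        for i in range(hs.size - 1):
            inside = np.sum((to > hs[i]) & (to < hs[i + 1]))
            if inside > 1:
                raise DataError("heel strikes and toe-offs are not interleaved")

    def cycles(self) -> list[tuple[float, float, float]]:
        """(heel_strike, toe_off, next_heel_strike) triples for complete cycles."""
        out = []
        for i in range(self.heel_strikes.size - 1):
            h0, h1 = self.heel_strikes[i], self.heel_strikes[i + 1]
            inside = self.toe_offs[(self.toe_offs > h0) & (self.toe_offs < h1)]
            if inside.size == 1:
                out.append((float(h0), float(inside[0]), float(h1)))
        return out


def detect_events_force(grf, fs: float, threshold: float = FORCE_THRESHOLD_N,
                        side: str = "right",
                        min_contact: float = MIN_CONTACT_S) -> GaitEvents:
    """Force-plate event detection at a vertical-force threshold.

    Heel strike = first sample of each supra-threshold run, toe-off = first
    sample after the run falls below the threshold. Runs shorter than
    ``min_contact`` seconds are discarded.
    """
    f = np.asarray(grf, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise DataError("GRF must be a 1-D signal")
    above = f > threshold
    if not above.any():
        raise EventDetectionError(
            f"force signal never exceeds the {threshold} N threshold")
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(f.size)  # contact runs off the end of the recording
    hs, to = [], []
    for s, e in zip(starts, ends):
        if (e - s) / fs < min_contact:
            continue
        if s > 0:
            hs.append(s / fs)     # a run starting at sample 0 has no onset
        if e < f.size:
            to.append(e / fs)     # a run reaching the end has no lift-off
    if not hs:
        raise EventDetectionError("no contact longer than the minimum duration")
    return GaitEvents(side=side, heel_strikes=np.array(hs), toe_offs=np.array(to),
                      method="force_threshold", force_threshold=threshold)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Central differences, one-sided at the endpoints."""
    return np.gradient(x, 1.0 / fs, edge_order=1)


def detect_heel_strike_kinematic(heel_xz, fs: float,
                                 velocity_fraction: float = 0.2,
                                 min_stance: float = 0.15,
                                 search_window_s: float = 0.25,
                                 side: str = "right") -> np.ndarray:
    """Heel-strike times from a (filtered) heel-marker sagittal trajectory.

    ``heel_xz`` has shape (N, 2): forward position and height. A coarse
    pre-pass marks candidate stance windows where the forward velocity is
    below ``velocity_fraction`` of its mean; within each window the event is
    the frame of maximum vertical acceleration — the arrest of the downward
    motion at touchdown. The acceleration search is confined to the first
    ``search_window_s`` seconds of each window: touchdown sits at the start
    of the low-velocity window, while heel-off (which also accelerates the
    marker) sits at its end.
    """
    p = np.asarray(heel_xz, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise DataError("heel trajectory must have shape (N, 2)")
    vx = _derivative(p[:, 0], fs)
    az = _derivative(_derivative(p[:, 1], fs), fs)
    v_mean = float(np.mean(vx))
    if v_mean <= 0.05:
        raise EventDetectionError("no forward progression in the heel trajectory")
    low = vx < velocity_fraction * v_mean
    windows = _contiguous_runs(low, int(round(min_stance * fs)))
    if not windows:
        raise EventDetectionError("no candidate stance windows in the heel trajectory")
    times = []
    lead = max(2, int(round(search_window_s * fs)))
    for s, e in windows:
        if s == 0:
            continue  # stance already under way at recording start: no touchdown seen
        stop = min(e, s + lead)
        i = s + int(np.argmax(az[s:stop]))
        times.append(i / fs)
    if not times:
        raise EventDetectionError("no complete touchdown in the heel trajectory")
    return np.asarray(times)


def detect_toe_off_kinematic(toe_xz, fs: float,
                             lift_velocity: float = 0.35,
                             velocity_fraction: float = 0.2,
                             min_stance: float = 0.15,
                             side: str = "right") -> np.ndarray:
    """Toe-off times from a (filtered) second-toe sagittal trajectory.

    The second-toe marker is the last point of the foot to leave the ground,
    so its forward velocity is near zero through all of stance (including
    heel rise). Within each low-forward-velocity window, the event is the
    first frame after the stance minimum of vertical position where the
    vertical velocity exceeds ``lift_velocity`` m/s.
    """
    p = np.asarray(toe_xz, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise DataError("toe trajectory must have shape (N, 2)")
    z = p[:, 1]
    z_range = float(z.max() - z.min())
    if z_range < 0.01:
        raise EventDetectionError("toe trajectory never lifts off the ground")
    vx = _derivative(p[:, 0], fs)
    vz = _derivative(z, fs)
    v_mean = float(np.mean(vx))
    if v_mean <= 0.05:
        raise EventDetectionError("no forward progression in the toe trajectory")
    low = vx < velocity_fraction * v_mean
    windows = _contiguous_runs(low, int(round(min_stance * fs)))
    if not windows:
        raise EventDetectionError("no stance windows in the toe trajectory")
    times = []
    for s, e in windows:
        i_min = s + int(np.argmin(z[s:e]))
        stop = min(z.size, e + int(round(0.2 * fs)))
        seg = vz[i_min:stop]
        # sustained crossing: two consecutive supra-threshold samples, so a
        # single noise blip cannot trigger a spuriously early toe-off
        above = seg > lift_velocity
        sustained = np.flatnonzero(above[:-1] & above[1:])
        if sustained.size == 0:
            continue  # incomplete final stance: no lift recorded
        i = int(sustained[0])
        # sub-frame localization of the threshold crossing
        if i > 0 and seg[i] > seg[i - 1]:
            frac = (lift_velocity - seg[i - 1]) / (seg[i] - seg[i - 1])
            frac = float(np.clip(frac, 0.0, 1.0))
        else:
            frac = 0.0
        times.append((i_min + i - 1 + frac) / fs if i > 0
                     else (i_min + i) / fs)
    if not times:
        raise EventDetectionError("no toe-off found after any stance minimum")
    return np.unique(np.asarray(times))


def detect_events_kinematic(heel_xz, toe_xz, fs: float, side: str = "right",
                            **kwargs) -> GaitEvents:
    """Combined kinematic heel-strike + toe-off detection for one leg.

    Toe-offs that precede the first or follow the last heel strike by more
    than a cycle are kept as-is; interleaving is validated by
    :class:`GaitEvents`.
    """
    hs = detect_heel_strike_kinematic(heel_xz, fs, side=side,
                                      **{k: v for k, v in kwargs.items()
                                         if k in ("velocity_fraction", "min_stance")})
    to = detect_toe_off_kinematic(toe_xz, fs, side=side,
                                  **{k: v for k, v in kwargs.items()
                                     if k in ("lift_velocity", "min_stance")})
    return GaitEvents(side=side, heel_strikes=hs, toe_offs=to, method="kinematic")


def _contiguous_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Start/end indices (half-open) of True runs no shorter than min_len."""
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(s, e) for s, e in zip(starts, ends) if e - s >= max(min_len, 2)]
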