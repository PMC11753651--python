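"""Gait event detection from relative-velocity zero crossings.

Heel strike (HS) and toe off (TO) are found without force plates, from the
anteroposterior velocity of two foot points relative to the pelvis origin:

* the *proximal* foot point (the foot segment origin, heel end) for HS, and
* the *distal* foot point (one foot length along the foot's long axis, toe
  end) for TO.

With the relative position taken as foot-minus-pelvis and the AP axis along
the direction of progression, the heel's relative AP position peaks at heel
strike and the toe's bottoms out at toe off, so by default HS is the
negative-going zero crossing of the heel signal and TO the positive-going
crossing of the toe signal.  Descriptions that take the relative signal the
other way round (pelvis-minus-foot) quote the same events with the opposite
signs; ``EventConfig.hs_crossing`` flips the convention if needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import MissingSegmentError, ValidationError
from .kinematics import (
    SegmentPoseTrajectory,
    progression_direction,
    relative_velocity,
)

FOOT_LONG_AXIS = np.array([0.0, 1.0, 0.0])  # foot local +y runs heel -> toe


@dataclass(frozen=True)
class EventConfig:
    """Tunables for event detection.

    filter_cutoff_hz:
        Zero-lag Butterworth low-pass cutoff applied to the relative
        velocities before crossing detection; ``None`` disables filtering.
    filter_order:
        Effective order of the zero-lag filter (forward-backward pass of a
        half-order Butterworth); must be even.
    refractory_s:
        Minimum spacing between consecutive same-type events; later
        violators are discarded.  0.4 s is well below any physiological
        stride time.
    interpolate_subframe:
        Locate crossings by linear interpolation between frames (otherwise
        snap to the nearer frame).
    foot_length_m:
        Heel-to-toe distance used to construct the distal foot point.
    edge_margin_s:
        Events closer than this to either end of the record are dropped
        (finite-difference and filter edge effects).
    hs_crossing:
        "negative" (default, heel at peak forward relative position) or
        "positive"; TO always uses the opposite direction on the toe signal.
    """

    filter_cutoff_hz: float | None = 6.0
    filter_order: int = 4
    refractory_s: float = 0.4
    interpolate_subframe: bool = True
    foot_length_m: float = 0.25
    edge_margin_s: float = 0.1
    hs_crossing: str = "negative"

    def __post_init__(self) -> None:
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValidationError("filter_order: must be an even integer >= 2")
        if self.hs_crossing not in ("negative", "positive"):
            raise ValidationError("hs_crossing: must be 'negative' or 'positive'")


@dataclass
class GaitEventSet:
    """Detected heel-strike and toe-off times (seconds) for one side."""

    side: str
    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.atleast_1d(np.asarray(self.heel_strikes, dtype=float))
        self.toe_offs = np.atleast_1d(np.asarray(self.toe_offs, dtype=float))
        for name, arr in (("heel_strikes", self.heel_strikes), ("toe_offs", self.toe_offs)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{name}: event times must be strictly increasing")

    def shifted(self, delta: float) -> "GaitEventSet":
        return GaitEventSet(self.side, self.heel_strikes + delta, self.toe_offs + delta)


@dataclass
class GaitCycle:
    """One gait cycle: consecutive ipsilateral heel strikes enclosing one
    ipsilateral toe off and one contralateral heel strike."""

    side: str
    t_hs_start: float
    t_to: float
    t_hs_contra: float
    t_hs_end: float

    def __post_init__(self) -> None:
        if not (self.t_hs_start < self.t_to < self.t_hs_end):
            raise ValidationError("cycle: requires t_hs_start < t_to < t_hs_end")
        if not (self.t_hs_start < self.t_hs_contra < self.t_hs_end):
            raise ValidationError("cycle: requires t_hs_start < t_hs_contra < t_hs_end")

    @property
    def duration(self) -> float:
        return self.t_hs_end - self.t_hs_start


def zero_crossings(
    series: np.ndarray,
    frame_rate: float,
    direction: str = "positive",
    *,
    t0: float = 0.0,
    interpolate: bool = True,
) -> np.ndarray:
    """Times of sign-change zero crossings in a sampled series.

    A positive crossing is reported between frames i and i+1 when
    ``series[i] < 0 <= series[i+1]`` (mirror condition for negative).  The
    event time is linearly interpolated between the two frame times; an exact
    zero at a frame with a sign change is assigned that frame's time.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValidationError("series: 1-D with at least 2 samples required")
    a, b = series[:-1], series[1:]
    if direction == "positive":
        mask = (a < 0) & (b >= 0)
    elif direction == "negative":
        mask = (a > 0) & (b <= 0)
    else:
        raise ValidationError("direction: must be 'positive' or 'negative'")
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = -a[idx] / (b[idx] - a[idx])
    if not interpolate:
        frac = np.round(frac)
    return t0 + (idx + frac) / frame_rate


def _apply_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0 or refractory_s <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def lowpass(series: np.ndarray, frame_rate: float, cutoff_hz: float | None,
            order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass; ``order`` is the effective order of the
    forward-backward pass."""
    if cutoff_hz is None or cutoff_hz <= 0:
        return np.asarray(series, dtype=float)
    if order < 2 or order % 2:
        raise ValidationError("filter_order: must be an even integer >= 2")
    sos = butter(order // 2, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    return sosfiltfilt(sos, series)


def foot_points(foot: SegmentPoseTrajectory, foot_length_m: float):
    """Proximal (heel) and distal (toe) foot point tracks, metres."""
    heel = foot.positions
    toe = heel + foot_length_m * np.einsum("nij,j->ni", foot.rotations, FOOT_LONG_AXIS)
    return heel, toe


def detect_events(
    trial: dict[str, SegmentPoseTrajectory],
    side: str,
    config: EventConfig | None = None,
    progression: np.ndarray | None = None,
) -> GaitEventSet:
    """Detect HS and TO for one side of a trial.

    ``trial`` maps segment ids to trajectories and must contain ``pelvis``
    and ``foot_{side}``.  An empty event list of either type is flagged with a
    warning, not fatal.
    """
    config = config or EventConfig()
    if side not in ("L", "R"):
        raise ValidationError("side: must be 'L' or 'R'")
    for seg in ("pelvis", f"foot_{side}"):
        if seg not in trial:
            raise MissingSegmentError(f"trial is missing segment '{seg}'")
    pelvis = trial["pelvis"]
    foot = trial[f"foot_{side}"]
    fs = pelvis.frame_rate
    if progression is None:
        progression = progression_direction(pelvis)

    heel, toe = foot_points(foot, config.foot_length_m)
    v_heel = relative_velocity(heel, pelvis.positions, progression, fs)
    v_toe = relative_velocity(toe, pelvis.positions, progression, fs)
    v_heel = lowpass(v_heel, fs, config.filter_cutoff_hz, config.filter_order)
    v_toe = lowpass(v_toe, fs, config.filter_cutoff_hz, config.filter_order)

    hs_dir = config.hs_crossing
    to_dir = "positive" if hs_dir == "negative" else "negative"
    hs = zero_crossings(v_heel, fs, hs_dir, interpolate=config.interpolate_subframe)
    to = zero_crossings(v_toe, fs, to_dir, interpolate=config.interpolate_subframe)

    t_max = (len(v_heel) - 1) / fs
    margin = config.edge_margin_s
    hs = hs[(hs >= margin) & (hs <= t_max - margin)]
    to = to[(to >= margin) & (to <= t_max - margin)]
    hs = _apply_refractory(hs, config.refractory_s)
    to = _apply_refractory(to, config.refractory_s)

    for name, arr in (("heel-strike", hs), ("toe-off", to)):
        if arr.size == 0:
            warnings.warn(f"no {name} events detected on side {side}", stacklevel=2)
    return GaitEventSet(side, hs, to)


def assemble_cycles(
    left: GaitEventSet, right: GaitEventSet
) -> tuple[list[GaitCycle], list[str]]:
    """Build at most one valid gait cycle per side (the earliest).

    A valid cycle is a pair of consecutive ipsilateral heel strikes enclosing
    exactly one ipsilateral toe off and exactly one contralateral heel
    strike.  Sides without a valid cycle are omitted, with a warning record
    returned alongside the cycles.
    """
    cycles: list[GaitCycle] = []
    notes: list[str] = []
    for own, other in ((left, right), (right, left)):
        found = None
        hs = own.heel_strikes
        for h1, h2 in zip(hs[:-1], hs[1:]):
            tos = own.toe_offs[(own.toe_offs > h1) & (own.toe_offs < h2)]
            contra = other.heel_strikes[(other.heel_strikes > h1) & (other.heel_strikes < h2)]
            if len(tos) == 1 and len(contra) == 1:
                found = GaitCycle(own.side, h1, float(tos[0]), float(contra[0]), h2)
                break
        if found is None:
            notes.append(f"side {own.side}: no valid gait cycle")
        else:
            cycles.append(found)
    return cycles, notes


def with_overrides(config: EventConfig, **kwargs) -> EventConfig:
    """Functional update helper for EventConfig."""
    return replace(config, **kwargs)
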