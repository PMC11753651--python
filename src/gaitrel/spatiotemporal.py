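"""Spatiotemporal gait parameters computed from gait cycles and foot tracks.

Temporal definitions (per side, from one cycle plus both event sets):
stance = HS-to-TO, swing = TO-to-next-HS, stride = HS-to-HS, step = time from
the contralateral HS to the ipsilateral HS ending the cycle, double support =
(first contralateral TO after the starting HS, minus the starting HS) plus
(ipsilateral TO minus contralateral HS).

Spatial definitions use heel (proximal foot) positions projected into the
progression frame: stride length is the AP distance between ipsilateral heel
positions at the two enclosing heel strikes; step length the AP distance from
the contralateral heel at its HS to the ipsilateral heel at cycle end; stride
width the absolute mediolateral distance between the ipsilateral heel at the
starting HS and the contralateral heel at its HS.  Speed is stride length
over stride time, so speed x stride time = stride length holds exactly by
construction.  Projections (not 3-D Euclidean distances) make length and
width an orthogonal decomposition of the displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import CycleRangeError, ValidationError
from .events import GaitCycle, GaitEventSet
from .kinematics import VERTICAL, progression_frame


@dataclass
class SideParameters:
    """Per-side spatiotemporal parameters for one analyzed cycle."""

    stance_time: float  # s
    swing_time: float  # s
    step_time: float  # s
    stride_time: float  # s
    step_length: float  # m
    stride_length: float  # m
    steps_per_minute: float
    strides_per_minute: float
    speed: float  # m/s
    double_support_time: float  # s (nan when the contralateral TO is clipped)


@dataclass
class SpatiotemporalRecord:
    """All per-side and bilateral parameters for one trial."""

    left: SideParameters | None
    right: SideParameters | None
    cycle_time: float  # s, bilateral mean of stride times
    double_support_time: float  # s
    speed: float  # m/s
    stride_length: float  # m
    stride_width: float  # m

    def to_flat_dict(self) -> dict[str, float]:
        out = {
            "cycle_time_s": self.cycle_time,
            "double_support_time_s": self.double_support_time,
            "speed_m_per_s": self.speed,
            "stride_length_m": self.stride_length,
            "stride_width_m": self.stride_width,
        }
        for prefix, side in (("left", self.left), ("right", self.right)):
            vals = {f.name: math.nan for f in fields(SideParameters)} if side is None \
                else {f.name: getattr(side, f.name) for f in fields(SideParameters)}
            out[f"{prefix}_stance_time_s"] = vals["stance_time"]
            out[f"{prefix}_step_length_m"] = vals["step_length"]
            out[f"{prefix}_step_time_s"] = vals["step_time"]
            out[f"{prefix}_steps_per_minute"] = vals["steps_per_minute"]
            out[f"{prefix}_stride_length_m"] = vals["stride_length"]
            out[f"{prefix}_strides_per_minute"] = vals["strides_per_minute"]
            out[f"{prefix}_swing_time_s"] = vals["swing_time"]
        return out


BILATERAL_PARAMS = (
    "cycle_time_s",
    "double_support_time_s",
    "speed_m_per_s",
    "stride_length_m",
    "stride_width_m",
)
UNILATERAL_PARAMS = tuple(
    f"{side}_{base}"
    for side in ("left", "right")
    for base in (
        "stance_time_s",
        "step_length_m",
        "step_time_s",
        "steps_per_minute",
        "stride_length_m",
        "strides_per_minute",
        "swing_time_s",
    )
)
ALL_PARAMS = BILATERAL_PARAMS + UNILATERAL_PARAMS


def temporal_parameters(
    cycle: GaitCycle, ipsi: GaitEventSet, contra: GaitEventSet
) -> dict[str, float]:
    """Temporal fields for one cycle; double support is nan when the
    contralateral toe off after the starting HS is outside the record."""
    stance = cycle.t_to - cycle.t_hs_start
    swing = cycle.t_hs_end - cycle.t_to
    stride = cycle.duration
    step = cycle.t_hs_end - cycle.t_hs_contra
    contra_to = contra.toe_offs[contra.toe_offs > cycle.t_hs_start]
    if contra_to.size:
        double_support = (contra_to[0] - cycle.t_hs_start) + (cycle.t_to - cycle.t_hs_contra)
    else:
        double_support = math.nan
    return {
        "stance_time": stance,
        "swing_time": swing,
        "stride_time": stride,
        "step_time": step,
        "double_support_time": double_support,
        "strides_per_minute": 60.0 / stride,
        "steps_per_minute": 60.0 / step,
    }


def _interp_track(track: np.ndarray, frame_rate: float, t: float, t0: float = 0.0) -> np.ndarray:
    times = t0 + np.arange(len(track)) / frame_rate
    if t < times[0] - 1e-12 or t > times[-1] + 1e-12:
        raise CycleRangeError(f"event time {t:.4f} outside track range")
    return np.array([np.interp(t, times, track[:, k]) for k in range(track.shape[1])])


def spatial_parameters(
    cycle: GaitCycle,
    heel_tracks: dict[str, np.ndarray],
    frame_rate: float,
    progression: np.ndarray,
) -> dict[str, float]:
    """Spatial fields for one cycle from both heel tracks ((n, 3) metres)."""
    frame = progression_frame(progression)
    ml_axis, ap_axis = frame[:, 0], frame[:, 1]
    ipsi = heel_tracks[cycle.side]
    contra = heel_tracks["L" if cycle.side == "R" else "R"]

    p_start = _interp_track(ipsi, frame_rate, cycle.t_hs_start)
    p_end = _interp_track(ipsi, frame_rate, cycle.t_hs_end)
    p_contra = _interp_track(contra, frame_rate, cycle.t_hs_contra)

    stride_length = float((p_end - p_start) @ ap_axis)
    step_length = float((p_end - p_contra) @ ap_axis)
    stride_width = float(abs((p_start - p_contra) @ ml_axis))
    return {
        "stride_length": stride_length,
        "step_length": step_length,
        "stride_width": stride_width,
        "speed": stride_length / cycle.duration,
    }


def side_parameters(
    cycle: GaitCycle,
    events: dict[str, GaitEventSet],
    heel_tracks: dict[str, np.ndarray],
    frame_rate: float,
    progression: np.ndarray,
) -> tuple[SideParameters, float]:
    """All per-side fields for one cycle; returns (parameters, stride_width)."""
    ipsi = events[cycle.side]
    contra = events["L" if cycle.side == "R" else "R"]
    t = temporal_parameters(cycle, ipsi, contra)
    s = spatial_parameters(cycle, heel_tracks, frame_rate, progression)
    params = SideParameters(
        stance_time=t["stance_time"],
        swing_time=t["swing_time"],
        step_time=t["step_time"],
        stride_time=t["stride_time"],
        step_length=s["step_length"],
        stride_length=s["stride_length"],
        steps_per_minute=t["steps_per_minute"],
        strides_per_minute=t["strides_per_minute"],
        speed=s["speed"],
        double_support_time=t["double_support_time"],
    )
    return params, s["stride_width"]


def bilateral_summary(
    left: SideParameters | None,
    right: SideParameters | None,
    stride_widths: dict[str, float],
) -> dict[str, float]:
    """Bilateral fields as the mean of the two sides; nan-flagged when a side
    is missing."""
    if left is None or right is None:
        return {k: math.nan for k in
                ("cycle_time", "double_support_time", "speed", "stride_length", "stride_width")}
    return {
        "cycle_time": (left.stride_time + right.stride_time) / 2.0,
        "double_support_time": (left.double_support_time + right.double_support_time) / 2.0,
        "speed": (left.speed + right.speed) / 2.0,
        "stride_length": (left.stride_length + right.stride_length) / 2.0,
        "stride_width": (stride_widths["L"] + stride_widths["R"]) / 2.0,
    }


def trial_record(
    cycles: list[GaitCycle],
    events: dict[str, GaitEventSet],
    heel_tracks: dict[str, np.ndarray],
    frame_rate: float,
    progression: np.ndarray,
) -> SpatiotemporalRecord:
    """Assemble the full per-trial record from the (<= 2) valid cycles."""
    by_side: dict[str, SideParameters] = {}
    widths: dict[str, float] = {}
    for cycle in cycles:
        params, width = side_parameters(cycle, events, heel_tracks, frame_rate, progression)
        by_side[cycle.side] = params
        widths[cycle.side] = width
    left = by_side.get("L")
    right = by_side.get("R")
    bilateral = bilateral_summary(left, right, widths) if widths else {
        k: math.nan for k in
        ("cycle_time", "double_support_time", "speed", "stride_length", "stride_width")
    }
    return SpatiotemporalRecord(
        left=left,
        right=right,
        cycle_time=bilateral["cycle_time"],
        double_support_time=bilateral["double_support_time"],
        speed=bilateral["speed"],
        stride_length=bilateral["stride_length"],
        stride_width=bilateral["stride_width"],
    )
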