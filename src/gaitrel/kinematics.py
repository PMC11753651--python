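"""Segment poses to joint/segment angle waveforms.

Conventions
-----------
Laboratory axes: X = mediolateral, Y = anteroposterior, Z = vertical.
A segment pose is a rigid-body transform (3x3 rotation + position in metres)
expressed in the laboratory frame; segments are unconstrained 6-DoF bodies.

Angles are Cardan angles in the fixed x-y-z sequence (rotation about x, then
the rotated y, then the rotated z), reported in degrees.  The x, y and z
components are read clinically as sagittal, frontal and transverse rotations.
Joint rotations express the distal segment relative to the proximal segment;
segment rotations express the segment relative to a frame aligned with the
direction of gait progression.  For left-side joints and segments the frontal
and transverse components are negated so that left and right curves share one
clinical sign convention (the pelvis, a midline segment, is never negated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AlignmentError,
    CycleRangeError,
    GimbalLockWarning,
    InsufficientProgressionError,
    ValidationError,
)

SEGMENTS = ("pelvis", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")
PLANES = ("x", "y", "z")
PLANE_NAMES = {"x": "sagittal", "y": "frontal", "z": "transverse"}
VERTICAL = np.array([0.0, 0.0, 1.0])

_ORTHO_TOL = 1e-6


def _check_rotations(rotations: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    rtr = np.einsum("nji,njk->nik", rotations, rotations)
    err = np.abs(rtr - np.eye(3)).max()
    if err > tol:
        raise ValidationError(
            f"rotations: not orthonormal within {tol:g} (max deviation {err:.3g})"
        )
    if np.any(np.linalg.det(rotations) <= 0):
        raise ValidationError("rotations: determinant must be +1 (improper rotation)")


@dataclass
class SegmentPoseTrajectory:
    """Time series of rigid-body poses for one body segment.

    Parameters
    ----------
    segment_id:
        One of ``SEGMENTS``.
    frame_rate:
        Sampling rate in Hz.
    rotations:
        Array (n, 3, 3) of lab-frame rotation matrices.
    positions:
        Array (n, 3) of lab-frame origin positions in metres.
    """

    segment_id: str
    frame_rate: float
    rotations: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate: must be > 0")
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValidationError("rotations: expected shape (n, 3, 3)")
        if self.positions.shape != (self.rotations.shape[0], 3):
            raise ValidationError("positions: expected shape (n, 3) matching rotations")
        if self.n_frames < 2:
            raise ValidationError("poses: at least 2 frames required")
        _check_rotations(self.rotations)

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def poses(self) -> np.ndarray:
        """(n, 4, 4) homogeneous transforms."""
        out = np.zeros((self.n_frames, 4, 4))
        out[:, :3, :3] = self.rotations
        out[:, :3, 3] = self.positions
        out[:, 3, 3] = 1.0
        return out

    @classmethod
    def from_poses(cls, segment_id: str, frame_rate: float, poses: np.ndarray):
        poses = np.asarray(poses, dtype=float)
        return cls(segment_id, frame_rate, poses[:, :3, :3], poses[:, :3, 3])


@dataclass
class AngleWaveform:
    """Three-plane angle time series (degrees) for a joint or segment."""

    entity: str
    side: str | None
    frame_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValidationError("components: x, y, z must have equal length")

    def component(self, plane: str) -> np.ndarray:
        return getattr(self, plane)


@dataclass
class NormalizedWaveform:
    """A 101-point angle curve over 0-100% of the gait cycle."""

    entity: str
    side: str | None
    plane: str
    samples: np.ndarray = field(default_factory=lambda: np.zeros(101))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (101,):
            raise ValidationError("samples: exactly 101 values required")


# ---------------------------------------------------------------------------
# Cardan decomposition / composition
# ---------------------------------------------------------------------------

def cardan_angles(rotation: np.ndarray, *, validate: bool = True) -> np.ndarray:
    """Decompose rotation matrices into fixed x-y-z Cardan angles (degrees).

    Recomposing rotations about x, then y, then z (``compose_cardan``)
    reproduces the input.  Near gimbal lock (|y| within 1 degree of 90) a
    :class:`GimbalLockWarning` is emitted and the residual rotation is assigned
    by the zero-z convention.

    Accepts a single 3x3 matrix or an (n, 3, 3) batch; returns shape (3,) or
    (n, 3).
    """
    rotation = np.asarray(rotation, dtype=float)
    single = rotation.ndim == 2
    batch = rotation.reshape(-1, 3, 3)
    if validate:
        _check_rotations(batch)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy's own gimbal-lock warning
        angles = Rotation.from_matrix(batch).as_euler("XYZ", degrees=True)
    if np.any(np.abs(np.abs(angles[:, 1]) - 90.0) < 1.0):
        warnings.warn(
            "middle Cardan angle within 1 deg of +/-90: decomposition is "
            "degenerate, residual assigned by zero-z convention",
            GimbalLockWarning,
            stacklevel=2,
        )
    return angles[0] if single else angles


def compose_cardan(x, y, z, *, degrees: bool = True) -> np.ndarray:
    """Compose rotations about x, then y, then z into matrices.

    Scalars give one 3x3 matrix; equal-length arrays give an (n, 3, 3) batch.
    """
    angles = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
    single = angles.ndim == 1
    mats = Rotation.from_euler("XYZ", angles.reshape(-1, 3), degrees=degrees).as_matrix()
    return mats[0] if single else mats


# ---------------------------------------------------------------------------
# Joint and segment angle waveforms
# ---------------------------------------------------------------------------

def _negate_left(angles: np.ndarray, side: str | None) -> np.ndarray:
    if side == "L":
        angles = angles.copy()
        angles[:, 1] *= -1.0
        angles[:, 2] *= -1.0
    return angles


def joint_angle_waveform(
    proximal: SegmentPoseTrajectory,
    distal: SegmentPoseTrajectory,
    side: str | None,
    entity: str = "joint",
) -> AngleWaveform:
    """Distal-relative-to-proximal Cardan angles per frame.

    For ``side="L"`` the frontal (y) and transverse (z) components are negated.
    """
    if proximal.n_frames != distal.n_frames:
        raise AlignmentError(
            f"frame counts differ: {proximal.n_frames} vs {distal.n_frames}"
        )
    if proximal.frame_rate != distal.frame_rate:
        raise AlignmentError("frame rates differ")
    rel = np.einsum("nji,njk->nik", proximal.rotations, distal.rotations)
    angles = _negate_left(cardan_angles(rel, validate=False), side)
    return AngleWaveform(entity, side, proximal.frame_rate,
                         angles[:, 0], angles[:, 1], angles[:, 2])


def progression_frame(progression: np.ndarray) -> np.ndarray:
    """Right-handed frame with Y' = progression, Z' = lab vertical."""
    progression = np.asarray(progression, dtype=float).copy()
    progression[2] = 0.0
    norm = np.linalg.norm(progression)
    if norm == 0:
        raise ValidationError("progression: zero-length vector")
    yp = progression / norm
    xp = np.cross(yp, VERTICAL)
    xp /= np.linalg.norm(xp)
    return np.column_stack([xp, yp, VERTICAL])


def segment_angle_waveform(
    segment: SegmentPoseTrajectory,
    progression: np.ndarray,
    side: str | None,
    entity: str = "segment",
) -> AngleWaveform:
    """Segment Cardan angles relative to the direction of gait progression.

    The reference frame has its Y axis along ``progression`` (horizontal unit
    vector) and Z along the lab vertical.  Left-side segments get the frontal/
    transverse negation; pass ``side=None`` for the midline pelvis.
    """
    frame = progression_frame(progression)
    rel = np.einsum("ji,njk->nik", frame, segment.rotations)
    angles = _negate_left(cardan_angles(rel, validate=False), side)
    return AngleWaveform(entity, side, segment.frame_rate,
                         angles[:, 0], angles[:, 1], angles[:, 2])


def progression_direction(
    pelvis: SegmentPoseTrajectory, *, min_displacement: float = 0.5
) -> np.ndarray:
    """Horizontal unit vector from first to last pelvis position."""
    disp = pelvis.positions[-1] - pelvis.positions[0]
    disp[2] = 0.0
    norm = np.linalg.norm(disp)
    if norm <= min_displacement:
        raise InsufficientProgressionError(
            f"insufficient progression: net horizontal pelvis displacement "
            f"{norm:.3f} m <= {min_displacement} m"
        )
    return disp / norm


def relative_velocity(
    point_track: np.ndarray,
    reference_track: np.ndarray,
    axis: np.ndarray,
    frame_rate: float,
) -> np.ndarray:
    """Finite-difference velocity of (point - reference) projected on ``axis``.

    Central differences in the interior, one-sided at the two ends (exact for
    an affine relative position).
    """
    point_track = np.asarray(point_track, dtype=float)
    reference_track = np.asarray(reference_track, dtype=float)
    if len(point_track) != len(reference_track):
        raise AlignmentError("point and reference tracks must have equal length")
    if len(point_track) < 3:
        raise ValidationError("tracks: at least 3 samples required for velocity")
    rel = (point_track - reference_track) @ np.asarray(axis, dtype=float)
    # second-order one-sided differences at the two ends keep endpoint
    # velocities accurate to O(h^2) (exact for affine and quadratic signals)
    return np.gradient(rel, 1.0 / frame_rate, edge_order=2)


def time_normalize(
    values: np.ndarray,
    frame_rate: float,
    cycle: tuple[float, float],
    n_points: int = 101,
    t0: float = 0.0,
) -> np.ndarray:
    """Linearly resample one waveform component onto ``n_points`` equally
    spaced times spanning a gait cycle.

    ``cycle`` is (t_HS_start, t_HS_end) in the same clock as the samples
    (sample k at time ``t0 + k / frame_rate``).
    """
    values = np.asarray(values, dtype=float)
    t_start, t_end = cycle
    if not t_start < t_end:
        raise CycleRangeError(f"cycle: start {t_start} must precede end {t_end}")
    times = t0 + np.arange(len(values)) / frame_rate
    if t_start < times[0] - 1e-12 or t_end > times[-1] + 1e-12:
        raise CycleRangeError(
            f"cycle [{t_start:.4f}, {t_end:.4f}] outside sampled range "
            f"[{times[0]:.4f}, {times[-1]:.4f}]"
        )
    grid = np.linspace(t_start, t_end, n_points)
    return np.interp(grid, times, values)
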