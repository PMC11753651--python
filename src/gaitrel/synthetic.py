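"""Synthetic gait-study generator with known ground truth.

Emulates the study design of a markerless gait-reliability experiment: a
number of subjects each walk a straight walkway in several sessions, with
several trials per session, each trial containing one full gait cycle per
limb sampled at a fixed frame rate.  The generator stands in for the capture
hardware: it produces 6-DoF segment pose trajectories (pelvis, both thighs,
shanks and feet) plus exact ground-truth events, spatiotemporal parameters
and angle waveforms, so the whole downstream pipeline is testable without any
external data.

Construction
------------
The pelvis advances along the lab anteroposterior (AP) axis at the template's
implied speed with sinusoidal vertical and mediolateral oscillation.  Thigh
and shank poses follow forward kinematics of the chain driven by 3-harmonic
Fourier joint-angle templates evaluated at the gait phase; the left limb is
the sagittal-plane mirror of the right, phase-offset by half a cycle.

Ground contact is programmed, not physically simulated.  The heel (foot
origin) carries a first-harmonic AP excursion relative to the pelvis whose
maximum falls exactly at the programmed heel strike, and the foot pitch
follows a closed-form program (solved by first-harmonic phasor algebra) that
places the minimum of the toe's relative AP position exactly at the
programmed toe off.  Because both signals are band-limited, their velocity
zero crossings survive zero-lag low-pass filtering unchanged, and the event
detector recovers the programmed contact times to sub-frame accuracy on
noiseless data.  The trade-off is a foot that glides rather than sticking to
the floor during stance; no downstream quantity observes this.

Hierarchical variance: template parameters receive additive subject, session
and trial effects (zero-mean normal, one draw per label), and all segment
positions receive isotropic Gaussian frame noise.  Per-trial RNG substreams
are derived from (seed, subject, session, trial), so trial order never
changes results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError, ValidationError
from .events import GaitEventSet
from .kinematics import SegmentPoseTrajectory, cardan_angles, compose_cardan
from .spatiotemporal import SideParameters, SpatiotemporalRecord

ENTITIES_JOINT = ("hip", "knee", "ankle")
ENTITIES_SEGMENT = ("pelvis", "thigh", "shank", "foot")

#: Fourier coefficients [a0, a1, b1, a2, b2, a3, b3] in degrees:
#: f(phi) = a0 + sum_k a_k cos(2 pi k phi) + b_k sin(2 pi k phi).
#: Amplitudes follow the clinical plane hierarchy: large sagittal excursions,
#: small frontal, smaller transverse.  Foot pitch (hence ankle sagittal and
#: transverse) is owned by the contact program, so only the ankle's frontal
#: component (rotation about the foot long axis) is a free template.
DEFAULT_COEFFS: dict[tuple[str, str], tuple[float, ...]] = {
    ("hip", "x"): (8.0, 20.0, 8.0, -3.0, 2.0, 1.0, 0.5),
    ("hip", "y"): (4.0, 3.0, 1.5, 1.0, -0.8, 0.3, 0.2),
    ("hip", "z"): (2.0, 2.0, 1.2, 0.8, 0.5, 0.3, -0.2),
    ("knee", "x"): (18.0, -12.0, -18.0, 8.0, 6.0, 1.5, 1.0),
    ("knee", "y"): (2.0, 2.6, 1.4, 0.8, 0.5, 0.3, 0.1),
    ("knee", "z"): (1.0, 1.5, 0.8, 0.5, 0.3, 0.2, 0.1),
    ("ankle", "y"): (1.0, 2.5, 1.2, 0.8, 0.4, 0.2, 0.1),
    ("pelvis", "x"): (6.0, 1.0, 0.5, 0.8, 0.4, 0.1, 0.1),
    ("pelvis", "y"): (0.0, 2.5, 1.0, 0.5, 0.3, 0.1, 0.0),
    ("pelvis", "z"): (0.0, 3.5, 1.5, 0.4, 0.2, 0.1, 0.0),
}

SCALAR_PARAMS = ("cadence", "stride_length", "stride_width", "stance_fraction")


def fourier_eval(coeffs, phi) -> np.ndarray:
    """Evaluate a 3-harmonic Fourier series at gait phase ``phi`` (cycles)."""
    coeffs = np.asarray(coeffs, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.full(phi.shape, coeffs[0])
    for k in (1, 2, 3):
        out = out + coeffs[2 * k - 1] * np.cos(2 * np.pi * k * phi) \
                  + coeffs[2 * k] * np.sin(2 * np.pi * k * phi)
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a gait-reliability study."""

    n_subjects: int = 9
    n_sessions: int = 3
    n_trials_collected: int = 5
    n_trials_sampled: int = 5
    frame_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_trials_collected", "n_trials_sampled"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name}: must be >= 1")
        if self.n_trials_sampled > self.n_trials_collected:
            raise ValidationError("n_trials_sampled: cannot exceed n_trials_collected")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate: must be > 0")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_trials_collected


@dataclass
class GaitTemplate:
    """Normative gait parameters driving trial synthesis.

    Defaults reproduce typical healthy-adult overground walking (cadence
    53.5 strides/min, stride 1.366 m, hence speed 1.218 m/s, stance fraction
    0.665 giving ~0.37 s of total double support per cycle).
    """

    cadence: float = 53.5  # strides/min
    stride_length: float = 1.366  # m
    stride_width: float = 0.172  # m
    stance_fraction: float = 0.665
    joint_waveform_coeffs: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_COEFFS.items()})
    segment_lengths: dict = field(default_factory=lambda: {
        "thigh": 0.42, "shank": 0.43, "foot": 0.25})
    pelvis_oscillation_amplitudes: tuple[float, float] = (0.025, 0.02)  # (vertical, ML) m
    pelvis_height: float = 0.95  # m
    pelvis_width: float = 0.24  # m, hip-centre spacing
    heel_excursion: float = 0.07  # m, heel AP amplitude relative to the pelvis

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValidationError(
                f"stance_fraction: {self.stance_fraction} outside (0, 1)")
        for name in ("cadence", "stride_length", "stride_width",
                     "pelvis_height", "pelvis_width", "heel_excursion"):
            if getattr(self, name) < 0 or (name in ("cadence", "stride_length")
                                           and getattr(self, name) <= 0):
                raise ValidationError(f"{name}: must be positive")
        for seg, length in self.segment_lengths.items():
            if length <= 0:
                raise ValidationError(f"segment_lengths[{seg}]: must be > 0")
        for key, coeffs in self.joint_waveform_coeffs.items():
            if len(coeffs) != 7:
                raise ValidationError(
                    f"joint_waveform_coeffs[{key}]: expected 7 coefficients")

    @property
    def stride_time(self) -> float:
        return 60.0 / self.cadence

    @property
    def speed(self) -> float:
        return self.stride_length * self.cadence / 60.0


@dataclass(frozen=True)
class VarianceComponents:
    """Hierarchical SDs for template perturbation plus frame noise.

    Each dict maps a scalar template parameter (in its own units) or the two
    waveform keys ``angle_offset_deg`` / ``angle_scale`` (additive offset in
    degrees; relative amplitude scale) to the SD of the zero-mean normal
    effect drawn once per subject / session / trial.
    """

    sd_subject: dict = field(default_factory=dict)
    sd_session: dict = field(default_factory=dict)
    sd_trial: dict = field(default_factory=dict)
    sd_frame_noise: float = 0.0015  # m

    def __post_init__(self) -> None:
        for level in (self.sd_subject, self.sd_session, self.sd_trial):
            for key, val in level.items():
                if val < 0:
                    raise ValidationError(f"variance component {key}: SD must be >= 0")
        if self.sd_frame_noise < 0:
            raise ValidationError("sd_frame_noise: must be >= 0")

    @classmethod
    def default(cls) -> "VarianceComponents":
        return cls(
            sd_subject={"cadence": 3.2, "stride_length": 0.10,
                        "stride_width": 0.022, "stance_fraction": 0.010,
                        "angle_offset_deg": 2.0, "angle_scale": 0.06},
            sd_session={"cadence": 0.9, "stride_length": 0.025,
                        "stride_width": 0.005, "stance_fraction": 0.004,
                        "angle_offset_deg": 0.8, "angle_scale": 0.025},
            sd_trial={"cadence": 0.5, "stride_length": 0.020,
                      "stride_width": 0.006, "stance_fraction": 0.004,
                      "angle_offset_deg": 0.5, "angle_scale": 0.015},
            sd_frame_noise=0.0015,
        )

    @classmethod
    def zero(cls) -> "VarianceComponents":
        """Fully deterministic study: no effects, no frame noise."""
        return cls(sd_frame_noise=0.0)


@dataclass
class SyntheticStudy:
    """A generated study: labelled trials plus per-trial ground truth."""

    design: StudyDesign
    template: GaitTemplate
    variance: VarianceComponents
    frame_rate: float
    trials: dict  # (subject, session, trial) -> {segment_id: SegmentPoseTrajectory}
    truth_events: dict  # label -> {"L": GaitEventSet, "R": GaitEventSet}
    truth_params: dict  # label -> SpatiotemporalRecord
    truth_waveforms: dict  # label -> {(entity, plane, side): (101,) ndarray}

    def labels(self) -> list[tuple[int, int, int]]:
        return sorted(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def make_template(profile_name: str = "default_adult",
                  overrides: dict | None = None) -> GaitTemplate:
    """Build a gait template, optionally overriding individual fields.

    Unknown or invalid override fields raise :class:`ValidationError` naming
    the field.
    """
    if profile_name != "default_adult":
        raise ValidationError(f"profile_name: unknown profile '{profile_name}'")
    template = GaitTemplate()
    if not overrides:
        return template
    valid = set(template.__dataclass_fields__)
    kwargs = {}
    for key, value in overrides.items():
        if key not in valid:
            raise ValidationError(f"overrides: unknown template field '{key}'")
        if key in ("joint_waveform_coeffs", "segment_lengths"):
            merged = dict(getattr(template, key))
            merged.update(value)
            value = merged
        kwargs[key] = value
    return replace(template, **kwargs)


def _level_rng(seed: int, stream: int, *labels: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream, *labels])


def _draw_effects(rng: np.random.Generator, sds: dict, coeff_keys) -> dict:
    """One draw per parameter; draw order is fixed so that zero SDs still
    consume the same stream positions."""
    eff = {}
    for name in SCALAR_PARAMS:
        eff[name] = rng.standard_normal() * sds.get(name, 0.0)
    for key in coeff_keys:
        eff[("offset", key)] = rng.standard_normal() * sds.get("angle_offset_deg", 0.0)
        eff[("scale", key)] = rng.standard_normal() * sds.get("angle_scale", 0.0)
    return eff


def sample_trial_parameters(
    template: GaitTemplate,
    vc: VarianceComponents,
    labels: tuple[int, int, int],
    seed: int,
) -> GaitTemplate:
    """Perturb a template with subject + session + trial effects.

    The subject effect depends only on (seed, subject), the session effect on
    (seed, subject, session), the trial effect on all three labels, so trials
    of one subject share that subject's effect exactly.
    """
    si, se, tr = labels
    coeff_keys = sorted(template.joint_waveform_coeffs)
    eff_levels = [
        _draw_effects(_level_rng(seed, 11, si), vc.sd_subject, coeff_keys),
        _draw_effects(_level_rng(seed, 12, si, se), vc.sd_session, coeff_keys),
        _draw_effects(_level_rng(seed, 13, si, se, tr), vc.sd_trial, coeff_keys),
    ]

    def total(key) -> float:
        return sum(eff[key] for eff in eff_levels)

    coeffs = {}
    for key in coeff_keys:
        base = np.asarray(template.joint_waveform_coeffs[key], dtype=float).copy()
        base[0] += total(("offset", key))
        base[1:] *= 1.0 + total(("scale", key))
        coeffs[key] = tuple(base)

    stance = template.stance_fraction + total("stance_fraction")
    return replace(
        template,
        cadence=template.cadence + total("cadence"),
        stride_length=template.stride_length + total("stride_length"),
        stride_width=max(0.0, template.stride_width + total("stride_width")),
        stance_fraction=float(np.clip(stance, 0.52, 0.88)),
        joint_waveform_coeffs=coeffs,
    )


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

def _foot_pitch_program(template: GaitTemplate):
    """Closed-form foot pitch placing the toe's relative-AP minimum at the
    programmed toe off.

    With heel relative AP position A cos(2 pi phi) (maximum at heel strike,
    phi = 0) and toe = heel + L_f cos(theta) along AP, choosing
    cos(theta(phi)) = 1 - D/2 + (D/2) cos(2 pi phi - gamma) with
    D = 4 A sin(beta/2) / L_f, gamma = beta/2 + pi/2, beta = 2 pi (c - 1/2)
    makes the toe signal a pure first harmonic with its minimum exactly at
    phase c (stance fraction).
    """
    a = template.heel_excursion
    lf = template.segment_lengths["foot"]
    beta = 2.0 * np.pi * (template.stance_fraction - 0.5)
    d = 4.0 * a * abs(math.sin(beta / 2.0)) / lf
    if d >= 2.0:
        raise GenerationError(
            "foot too short for the heel excursion / stance fraction: "
            "the foot-pitch program has no solution (reduce heel_excursion)")
    gamma = beta / 2.0 + np.pi / 2.0

    def pitch_deg(phi: np.ndarray) -> np.ndarray:
        u = 1.0 - d / 2.0 + (d / 2.0) * np.cos(2.0 * np.pi * phi - gamma)
        return np.degrees(np.arccos(np.clip(u, -1.0, 1.0)))

    return pitch_deg


def _side_angles(template: GaitTemplate, phi: np.ndarray, side: str):
    """Joint/segment angle programs for one side at its own gait phase."""
    sgn = -1.0 if side == "L" else 1.0
    coeffs = template.joint_waveform_coeffs
    pel_phi = phi + (0.5 if side == "L" else 0.0)

    def ev(entity, plane, at):
        return fourier_eval(coeffs[(entity, plane)], at)

    pitch = _foot_pitch_program(template)(phi)
    return {
        "pelvis": np.stack([ev("pelvis", "x", pel_phi),
                            ev("pelvis", "y", pel_phi),
                            ev("pelvis", "z", pel_phi)], axis=-1),
        "hip": np.stack([ev("hip", "x", phi),
                         sgn * ev("hip", "y", phi),
                         sgn * ev("hip", "z", phi)], axis=-1),
        "knee": np.stack([ev("knee", "x", phi),
                          sgn * ev("knee", "y", phi),
                          sgn * ev("knee", "z", phi)], axis=-1),
        "foot": np.stack([pitch,
                          sgn * ev("ankle", "y", phi),
                          np.zeros_like(phi)], axis=-1),
    }


def _chain_rotations(angles: dict) -> dict:
    """Forward-kinematic rotation chain (lab frame) from angle programs."""
    r_pelvis = compose_cardan(*angles["pelvis"].T)
    r_thigh = r_pelvis @ compose_cardan(*angles["hip"].T)
    r_shank = r_thigh @ compose_cardan(*angles["knee"].T)
    r_foot = compose_cardan(*angles["foot"].T)
    return {"pelvis": r_pelvis, "thigh": r_thigh, "shank": r_shank, "foot": r_foot}


def synthesize_trial(
    template: GaitTemplate,
    design: StudyDesign,
    labels: tuple[int, int, int] = (0, 0, 0),
    *,
    sd_frame_noise: float = 0.0,
    duration_s: float | None = None,
):
    """Generate one trial: segment poses, truth events, truth parameters and
    truth waveforms.

    The trial spans two stride times: a quarter-cycle lead-in before the
    first right heel strike and a quarter-cycle tail after the last left heel
    strike, so finite-difference velocities are defined at every event.
    """
    T = template.stride_time
    c = template.stance_fraction
    L = template.stride_length
    W = template.stride_width
    v = L / T
    fs = design.frame_rate
    duration = 2.0 * T if duration_s is None else duration_s
    if duration < 2.0 * T - 1e-9:
        raise GenerationError(
            f"trial of {duration:.2f} s too short for a full bilateral cycle "
            f"(needs {2.0 * T:.2f} s)")
    n = int(np.floor(duration * fs)) + 1
    if n < 32:
        raise GenerationError("trial too short: fewer than 32 frames")
    t = np.arange(n) / fs
    phi_r = t / T - 0.25
    phi_l = phi_r - 0.5

    amp_v, amp_ml = template.pelvis_oscillation_amplitudes
    pelvis_pos = np.column_stack([
        amp_ml * np.sin(2 * np.pi * phi_r),
        v * t,
        template.pelvis_height + amp_v * np.cos(4 * np.pi * phi_r),
    ])

    segments: dict[str, SegmentPoseTrajectory] = {}
    rots_by_side = {}
    for side, phi in (("R", phi_r), ("L", phi_l)):
        sgn = 1.0 if side == "R" else -1.0
        angles = _side_angles(template, phi, side)
        rots = _chain_rotations(angles)
        rots_by_side[side] = rots

        hip_centre = pelvis_pos + np.einsum(
            "nij,j->ni", rots["pelvis"],
            np.array([sgn * template.pelvis_width / 2.0, 0.0, -0.05]))
        knee = hip_centre + np.einsum(
            "nij,j->ni", rots["thigh"],
            np.array([0.0, 0.0, -template.segment_lengths["thigh"]]))

        phi_m = np.mod(phi, 1.0)
        swing = phi_m >= c
        bump = np.zeros_like(phi_m)
        bump[swing] = 0.05 * np.sin(np.pi * (phi_m[swing] - c) / (1.0 - c)) ** 2
        heel = np.column_stack([
            np.full(n, sgn * W / 2.0),
            v * t + template.heel_excursion * np.cos(2 * np.pi * phi),
            0.05 + bump,
        ])

        segments[f"thigh_{side}"] = SegmentPoseTrajectory(
            f"thigh_{side}", fs, rots["thigh"], hip_centre)
        segments[f"shank_{side}"] = SegmentPoseTrajectory(
            f"shank_{side}", fs, rots["shank"], knee)
        segments[f"foot_{side}"] = SegmentPoseTrajectory(
            f"foot_{side}", fs, rots["foot"], heel)

    segments["pelvis"] = SegmentPoseTrajectory(
        "pelvis", fs, rots_by_side["R"]["pelvis"], pelvis_pos)

    if sd_frame_noise > 0:
        rng = _level_rng(design.seed, 21, *labels)
        for seg in sorted(segments):
            traj = segments[seg]
            traj.positions = traj.positions + rng.normal(
                0.0, sd_frame_noise, traj.positions.shape)

    t_end = t[-1]

    def in_range(times):
        return np.array([x for x in times if 0.0 <= x <= t_end])

    hs_r = in_range([0.25 * T, 1.25 * T])
    hs_l = in_range([0.75 * T, 1.75 * T])
    to_r = in_range([(0.25 + c) * T, (1.25 + c) * T])
    to_l = in_range([(c - 0.25) * T, (c + 0.75) * T])
    truth_events = {"L": GaitEventSet("L", hs_l, to_l),
                    "R": GaitEventSet("R", hs_r, to_r)}

    side_truth = SideParameters(
        stance_time=c * T, swing_time=(1.0 - c) * T, step_time=0.5 * T,
        stride_time=T, step_length=L / 2.0, stride_length=L,
        steps_per_minute=120.0 / T, strides_per_minute=60.0 / T,
        speed=L / T, double_support_time=2.0 * (c - 0.5) * T)
    truth_record = SpatiotemporalRecord(
        left=side_truth, right=replace(side_truth),
        cycle_time=T, double_support_time=2.0 * (c - 0.5) * T,
        speed=L / T, stride_length=L, stride_width=W)

    truth_waveforms = _truth_waveforms(template)
    return segments, truth_events, truth_record, truth_waveforms


def _truth_waveforms(template: GaitTemplate) -> dict:
    """Exact angle curves at 101 evenly spaced phases of the gait cycle.

    Hip and knee are the Fourier templates themselves; ankle and the thigh/
    shank/foot segment curves are closed-form compositions of the same
    programs (no sampling or event detection involved).
    """
    phi = np.linspace(0.0, 1.0, 101)
    out: dict[tuple[str, str, str], np.ndarray] = {}
    for side in ("R", "L"):
        angles = _side_angles(template, phi, side)
        rots = _chain_rotations(angles)
        neg = -1.0 if side == "L" else 1.0

        def put(entity, curves):
            for j, plane in enumerate(("x", "y", "z")):
                out[(entity, plane, side)] = curves[:, j]

        hip = cardan_angles(np.einsum("nji,njk->nik", rots["pelvis"], rots["thigh"]),
                            validate=False)
        knee = cardan_angles(np.einsum("nji,njk->nik", rots["thigh"], rots["shank"]),
                             validate=False)
        ankle = cardan_angles(np.einsum("nji,njk->nik", rots["shank"], rots["foot"]),
                              validate=False)
        for arr in (hip, knee, ankle):
            arr[:, 1] *= neg
            arr[:, 2] *= neg
        put("hip", hip)
        put("knee", knee)
        put("ankle", ankle)

        for entity in ("thigh", "shank", "foot"):
            seg = cardan_angles(rots[entity], validate=False)
            seg[:, 1] *= neg
            seg[:, 2] *= neg
            put(entity, seg)
        # midline pelvis: no left/right negation
        put("pelvis", cardan_angles(rots["pelvis"], validate=False))
    return out


def generate_study(
    design: StudyDesign,
    template: GaitTemplate | None = None,
    vc: VarianceComponents | None = None,
) -> SyntheticStudy:
    """Generate a complete labelled study, reproducible from ``design.seed``."""
    template = template or make_template()
    vc = vc if vc is not None else VarianceComponents.default()

    trials, truth_events, truth_params, truth_waveforms = {}, {}, {}, {}
    for si in range(design.n_subjects):
        for se in range(design.n_sessions):
            for tr in range(design.n_trials_collected):
                label = (si, se, tr)
                perturbed = sample_trial_parameters(template, vc, label, design.seed)
                segs, events, record, waves = synthesize_trial(
                    perturbed, design, label, sd_frame_noise=vc.sd_frame_noise)
                trials[label] = segs
                truth_events[label] = events
                truth_params[label] = record
                truth_waveforms[label] = waves
    return SyntheticStudy(design, template, vc, design.frame_rate,
                          trials, truth_events, truth_params, truth_waveforms)
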