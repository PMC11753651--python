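"""Published reference values for reproduction checks.

Point estimates printed by the original reliability study of an eight-camera
markerless motion-capture system in nine healthy adults (nine subjects,
three sessions, five sampled trials each, 135 trials, one bilateral gait
cycle per trial) — the study whose analysis this package reimplements.
Shipped so that summary quantities (e.g. the per-plane averages of the
between-session CMD tables) can be recomputed and compared without access to
the deposited data files.
"""

from __future__ import annotations

JOINTS = ("hip", "knee", "ankle")
SEGMENTS = ("pelvis", "thigh", "shank", "foot")
PLANES = ("sagittal", "frontal", "transverse")

#: Between-session CMD means, joint kinematics table.
JOINT_CMD_BETWEEN = {
    ("hip", "sagittal"): 0.975, ("hip", "frontal"): 0.684, ("hip", "transverse"): 0.747,
    ("knee", "sagittal"): 0.989, ("knee", "frontal"): 0.459, ("knee", "transverse"): 0.159,
    ("ankle", "sagittal"): 0.944, ("ankle", "frontal"): 0.519, ("ankle", "transverse"): 0.076,
}

#: Within-session CMD means, joint kinematics table.
JOINT_CMD_WITHIN = {
    ("hip", "sagittal"): 0.988, ("hip", "frontal"): 0.796, ("hip", "transverse"): 0.803,
    ("knee", "sagittal"): 0.992, ("knee", "frontal"): 0.542, ("knee", "transverse"): 0.126,
    ("ankle", "sagittal"): 0.968, ("ankle", "frontal"): 0.594, ("ankle", "transverse"): 0.037,
}

#: Between-session CMD means, segment kinematics table.
SEGMENT_CMD_BETWEEN = {
    ("pelvis", "sagittal"): 0.468, ("pelvis", "frontal"): 0.409, ("pelvis", "transverse"): 0.855,
    ("thigh", "sagittal"): 0.988, ("thigh", "frontal"): 0.792, ("thigh", "transverse"): 0.504,
    ("shank", "sagittal"): 0.996, ("shank", "frontal"): 0.729, ("shank", "transverse"): 0.194,
    ("foot", "sagittal"): 0.990, ("foot", "frontal"): 0.674, ("foot", "transverse"): 0.691,
}

#: Headline spatiotemporal reliability values from the same study.
SPATIOTEMPORAL_HEADLINE = {
    "between_icc_left_step_time": 0.896,
    "between_icc_left_cadence": 0.894,
    "between_sem_left_step_time_s": 0.018,
    "between_mdc_left_step_time_s": 0.050,
    "between_sem_left_cadence": 3.593,
    "between_mdc_left_cadence": 9.958,
    "grand_mean_cycle_time_s": 1.125,
    "grand_mean_speed_m_per_s": 1.218,
    "grand_mean_stride_length_m": 1.366,
    "grand_mean_stride_width_m": 0.172,
}


def plane_average(table: dict, plane: str, entities=None) -> float:
    """Average a CMD table over entities within one anatomical plane."""
    entities = tuple(entities) if entities is not None else tuple(
        {e for e, _ in table})
    vals = [table[(e, plane)] for e in entities]
    return sum(vals) / len(vals)
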