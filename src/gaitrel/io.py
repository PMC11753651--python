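"""Dataset and results I/O.

The canonical interchange format is a versioned JSON schema
(``gaitrel-dataset/1``): metadata (frame rate, lab-axis convention, units)
plus one entry per trial holding per-segment rotation and position arrays and
an optional ground-truth block.  Positions are stored in metres to 1e-6,
rotations to 1e-9; write-read round trips are lossless to that precision.
Unknown extra fields are accepted and preserved for forward compatibility.

C3D import/export is available when the optional ``ezc3d`` dependency is
installed (guarded import): each segment is stored as four point channels —
its origin and the tips of its three unit axes — which round-trips the full
6-DoF pose through the point-based C3D container.

Supplementary-style files (normalized-waveform JSON, spatiotemporal XLSX)
are adapted through user-editable column/key mappings (TOML or dict), since
deposited schemas vary; adapters feed the reliability stage directly,
bypassing event detection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GaitDataset
from .errors import SchemaError, ValidationError
from .events import GaitEventSet
from .kinematics import SegmentPoseTrajectory

SCHEMA_VERSION = "gaitrel-dataset/1"
_KNOWN_TOP = {"schema", "metadata", "trials"}
_KNOWN_TRIAL = {"subject", "session", "trial", "segments", "ground_truth"}


# ---------------------------------------------------------------------------
# JSON dataset schema
# ---------------------------------------------------------------------------

def _round(arr: np.ndarray, decimals: int) -> list:
    return np.round(np.asarray(arr, dtype=float), decimals).tolist()


def write_dataset_json(study, path, *, include_ground_truth: bool = True) -> None:
    """Serialize a study/dataset (duck-typed: frame_rate, trials, and
    optionally truth_events / truth_params) to the JSON dataset schema."""
    truth_events = getattr(study, "truth_events", None)
    truth_params = getattr(study, "truth_params", None)
    trials_out = []
    for label in sorted(study.trials):
        si, se, tr = label
        segments = {
            seg_id: {
                "rotations": _round(traj.rotations, 9),
                "positions": _round(traj.positions, 6),
            }
            for seg_id, traj in sorted(study.trials[label].items())
        }
        entry = {"subject": int(si), "session": int(se), "trial": int(tr),
                 "segments": segments}
        if include_ground_truth and truth_events is not None:
            gt: dict = {"events": {
                side: {"heel_strikes": _round(ev.heel_strikes, 6),
                       "toe_offs": _round(ev.toe_offs, 6)}
                for side, ev in truth_events[label].items()}}
            if truth_params is not None:
                gt["parameters"] = {
                    k: round(float(v), 9)
                    for k, v in truth_params[label].to_flat_dict().items()}
            entry["ground_truth"] = gt
        trials_out.append(entry)

    doc = {
        "schema": SCHEMA_VERSION,
        "metadata": {
            "frame_rate": study.frame_rate,
            "lab_axes": {"x": "mediolateral", "y": "anteroposterior", "z": "vertical"},
            "units": {"position": "m", "time": "s", "angle": "deg"},
        },
        "trials": trials_out,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_dataset_json(path) -> GaitDataset:
    """Read and validate a JSON dataset; fails fast with a JSON-pointer-style
    location on the first schema violation."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"/: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError("/: expected a JSON object")
    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"/schema: expected '{SCHEMA_VERSION}'")
    meta = doc.get("metadata")
    if not isinstance(meta, dict):
        raise SchemaError("/metadata: missing or not an object")
    if "frame_rate" not in meta:
        raise SchemaError("/metadata/frame_rate: missing")
    frame_rate = float(meta["frame_rate"])
    if "trials" not in doc or not isinstance(doc["trials"], list):
        raise SchemaError("/trials: missing or not an array")

    trials, truth_events, truth_params = {}, {}, {}
    for i, entry in enumerate(doc["trials"]):
        where = f"/trials/{i}"
        for req in ("subject", "session", "trial", "segments"):
            if req not in entry:
                raise SchemaError(f"{where}/{req}: missing")
        label = (entry["subject"], entry["session"], entry["trial"])
        segs = {}
        n_frames = None
        for seg_id, data in entry["segments"].items():
            swhere = f"{where}/segments/{seg_id}"
            for req in ("rotations", "positions"):
                if req not in data:
                    raise SchemaError(f"{swhere}/{req}: missing")
            try:
                traj = SegmentPoseTrajectory(
                    seg_id, frame_rate,
                    np.asarray(data["rotations"], dtype=float),
                    np.asarray(data["positions"], dtype=float))
            except (ValidationError, ValueError) as exc:
                raise SchemaError(f"{swhere}: {exc}") from exc
            if n_frames is None:
                n_frames = traj.n_frames
            elif traj.n_frames != n_frames:
                raise SchemaError(f"{swhere}: frame count {traj.n_frames} != {n_frames}")
            segs[seg_id] = traj
        trials[label] = segs
        gt = entry.get("ground_truth")
        if gt:
            if "events" in gt:
                truth_events[label] = {
                    side: GaitEventSet(side,
                                       np.asarray(ev["heel_strikes"], dtype=float),
                                       np.asarray(ev["toe_offs"], dtype=float))
                    for side, ev in gt["events"].items()}
            if "parameters" in gt:
                truth_params[label] = dict(gt["parameters"])

    extras = {k: v for k, v in doc.items() if k not in _KNOWN_TOP}
    return GaitDataset(frame_rate, trials,
                       truth_events=truth_events or None,
                       truth_params=truth_params or None,
                       metadata=meta, extras=extras)


# ---------------------------------------------------------------------------
# C3D (optional dependency)
# ---------------------------------------------------------------------------

_AXIS_SUFFIXES = ("_O", "_AX", "_AY", "_AZ")


def _require_ezc3d():
    try:
        import ezc3d  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D support requires the optional 'ezc3d' package "
            "(pip install gaitrel[c3d]); the JSON dataset schema needs no "
            "extra dependency") from exc
    return ezc3d


def write_c3d(trial: dict, frame_rate: float, path) -> None:  # pragma: no cover
    """Export one trial to C3D: per segment, four points (origin + unit-axis
    tips, millimetres) encode the 6-DoF pose."""
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    labels, frames = [], None
    arrays = []
    for seg_id, traj in sorted(trial.items()):
        frames = traj.n_frames
        origin = traj.positions
        for suffix, col in zip(_AXIS_SUFFIXES, (None, 0, 1, 2)):
            labels.append(f"{seg_id}{suffix}")
            pts = origin if col is None else origin + traj.rotations[:, :, col]
            arrays.append(pts * 1000.0)  # m -> mm
    data = np.zeros((4, len(labels), frames))
    for j, arr in enumerate(arrays):
        data[:3, j, :] = arr.T
        data[3, j, :] = 1.0
    c3d["parameters"]["POINT"]["RATE"]["value"] = [frame_rate]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = labels
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["mm"]
    c3d["data"]["points"] = data
    c3d.write(str(path))


def read_c3d(path) -> tuple[dict, float]:  # pragma: no cover
    """Read a trial written by :func:`write_c3d`; millimetre points are
    converted to metres and axis-tip channels rebuilt into rotations."""
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = c3d["parameters"]["POINT"]["UNITS"]["value"][0].strip().lower()
    scale = 0.001 if units == "mm" else 1.0
    pts = c3d["data"]["points"][:3] * scale  # (3, nlabels, nframes)
    by_label = {lab: pts[:, j, :].T for j, lab in enumerate(labels)}

    seg_ids = sorted({lab[:-len("_O")] for lab in labels if lab.endswith("_O")})
    trial = {}
    for seg_id in seg_ids:
        missing = [seg_id + s for s in _AXIS_SUFFIXES if seg_id + s not in by_label]
        if missing:
            raise SchemaError(
                f"C3D: segment '{seg_id}' missing channels {missing}; "
                f"found {sorted(by_label)}")
        origin = by_label[seg_id + "_O"]
        # axis-tip channels sit one metre along each axis from the origin
        cols = [by_label[seg_id + s] - origin for s in _AXIS_SUFFIXES[1:]]
        rotations = np.stack(cols, axis=-1)  # (n, 3, 3)
        trial[seg_id] = SegmentPoseTrajectory(seg_id, rate, rotations, origin)
    return trial, rate


# ---------------------------------------------------------------------------
# Supplementary-file adapters (mapping-driven)
# ---------------------------------------------------------------------------

DEFAULT_KINEMATICS_MAPPING = {
    "records": "records", "subject": "subject", "session": "session",
    "trial": "trial", "entity": "entity", "side": "side", "plane": "plane",
    "points": "points",
}

DEFAULT_SPATIOTEMPORAL_MAPPING = {
    "sheet": 0,
    "columns": {"subject": "subject", "session": "session", "trial": "trial"},
}


def load_mapping(path) -> dict:
    """Read an adapter mapping from a TOML file."""
    import tomllib  # noqa: PLC0415
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def adapt_kinematics_json(path, mapping: dict | None = None) -> dict:
    """Adapt a normalized-waveform JSON file to pipeline structures.

    Returns ``{(entity, plane): {(subject, session, trial, side): (101,)
    array}}``, ready for the CMD stage.  The mapping gives the source key for
    each required field; unmapped/unknown keys and non-101-point waveforms
    are hard errors.
    """
    m = {**DEFAULT_KINEMATICS_MAPPING, **(mapping or {})}
    doc = json.loads(Path(path).read_text())
    records = doc[m["records"]] if isinstance(doc, dict) else doc
    required = ("subject", "session", "trial", "entity", "side", "plane", "points")
    out: dict = {}
    for i, rec in enumerate(records):
        missing = [f for f in required if m[f] not in rec]
        if missing:
            raise SchemaError(
                f"record {i}: unmapped/missing keys {[m[f] for f in missing]}; "
                f"record has {sorted(rec)}")
        points = np.asarray(rec[m["points"]], dtype=float)
        if points.shape != (101,):
            raise SchemaError(
                f"record {i}: waveform length {points.shape} != (101,)")
        key = (rec[m["entity"]], rec[m["plane"]])
        out.setdefault(key, {})[
            (rec[m["subject"]], rec[m["session"]], rec[m["trial"]], rec[m["side"]])
        ] = points
    return out


def adapt_spatiotemporal_xlsx(path, mapping: dict | None = None) -> pd.DataFrame:
    """Adapt a spatiotemporal XLSX table to a canonical trial-level frame.

    ``mapping["columns"]`` maps canonical names (must include subject,
    session, trial) to source column headers; remaining mapped columns are
    parameter values.  Missing source columns are an explicit error.
    """
    m = {**DEFAULT_SPATIOTEMPORAL_MAPPING, **(mapping or {})}
    df = pd.read_excel(path, sheet_name=m.get("sheet", 0))
    columns = m["columns"]
    for req in ("subject", "session", "trial"):
        if req not in columns:
            raise SchemaError(f"mapping omits required column '{req}'")
    missing = [src for src in columns.values() if src not in df.columns]
    if missing:
        raise SchemaError(
            f"source file lacks mapped columns {missing}; has {list(df.columns)}")
    renamed = df[list(columns.values())].rename(
        columns={src: canon for canon, src in columns.items()})
    return renamed
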