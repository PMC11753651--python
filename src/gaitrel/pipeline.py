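"""End-to-end study analysis: sampling, per-trial processing, aggregation.

For every trial the pipeline detects gait events, assembles one gait cycle
per side, computes the spatiotemporal record and the 101-point normalized
angle waveforms for three joints and four segments in three planes.  Scalars
are then summarized with ICC(3,k)/SEM/MDC within and between sessions;
waveforms with the CMD.

Aggregation layouts
-------------------
* Within-session ICC (default "stacked"): rows are subject-session units,
  columns the sampled trials.  The alternative "per_session_mean" layout
  computes one ICC per session (rows = subjects, columns = trials) and
  averages the estimates.
* Between-session ICC: rows are subjects, columns the session means of the
  sampled trials.
* SEM uses ICC(3,1) from the same ANOVA together with the SD of the
  parameter over all analyzed trials; MDC = 1.96 * sqrt(2) * SEM.
* Within-session CMD: per subject, per session, per side across the sampled
  trials, averaged over sessions and then sides; between-session CMD: per
  subject across session-mean waveforms, averaged over sides.  Grand means
  and SDs are taken over all collected trials while the reliability
  statistics use only the sampled ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import TrialProcessingError, ValidationError
from .events import EventConfig, assemble_cycles, detect_events
from .kinematics import (
    PLANE_NAMES,
    joint_angle_waveform,
    progression_direction,
    segment_angle_waveform,
    time_normalize,
)
from .reliability import (
    CmdSummary,
    IccResult,
    classify_icc,
    cmd,
    icc_3k,
    mdc,
    sem,
    summarize_cmd,
)
from .spatiotemporal import ALL_PARAMS, trial_record

JOINT_DEFS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"),
              "ankle": ("shank", "foot")}
SEGMENT_DEFS = ("pelvis", "thigh", "shank", "foot")
KINEMATIC_VARIABLES = tuple(
    (entity, plane)
    for entity in (*JOINT_DEFS, *SEGMENT_DEFS)
    for plane in ("x", "y", "z")
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration."""

    n_trials_sampled: int = 5
    sampling_seed: int = 0
    event: EventConfig = field(default_factory=EventConfig)
    icc_layout: str = "stacked"  # or "per_session_mean"
    sides_combined: bool = True
    max_failure_fraction: float = 0.1
    output_formats: tuple[str, ...] = ("csv",)

    def __post_init__(self) -> None:
        if self.n_trials_sampled < 2:
            raise ValidationError("n_trials_sampled: must be >= 2")
        if self.icc_layout not in ("stacked", "per_session_mean"):
            raise ValidationError("icc_layout: 'stacked' or 'per_session_mean'")


@dataclass
class StudyReport:
    """Aggregated results in the layout of the published reliability tables."""

    joint_table: pd.DataFrame
    segment_table: pd.DataFrame
    spatiotemporal_table: pd.DataFrame
    per_trial: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------------------
# Sampling and per-trial processing
# ---------------------------------------------------------------------------

def sample_trials(labels, n: int, seed: int) -> list:
    """Uniform without-replacement sampling of ``n`` trials per
    subject-session cell, deterministic under ``seed``."""
    cells: dict = {}
    for label in sorted(labels):
        cells.setdefault(label[:2], []).append(label)
    chosen = []
    for idx, (cell, members) in enumerate(sorted(cells.items())):
        if len(members) < n:
            raise ValidationError(
                f"subject-session cell {cell}: only {len(members)} trials, need {n}")
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 41, idx])
        pick = rng.choice(len(members), size=n, replace=False)
        chosen.extend(members[i] for i in sorted(pick))
    return chosen


def process_trial(trial: dict, frame_rate: float, config: AnalysisConfig):
    """Events, cycles, spatiotemporal record and normalized waveforms for one
    trial.  Returns (flat record dict, {(entity, plane, side): (101,)}, notes)."""
    progression = progression_direction(trial["pelvis"])
    events = {side: detect_events(trial, side, config.event, progression)
              for side in ("L", "R")}
    cycles, notes = assemble_cycles(events["L"], events["R"])
    if not cycles:
        raise TrialProcessingError("no valid gait cycle on either side")

    heel_tracks = {side: trial[f"foot_{side}"].positions for side in ("L", "R")}
    record = trial_record(cycles, events, heel_tracks, frame_rate, progression)

    waveforms: dict = {}
    for cycle in cycles:
        side = cycle.side
        window = (cycle.t_hs_start, cycle.t_hs_end)
        for entity, (prox, dist) in JOINT_DEFS.items():
            prox_traj = trial[prox if prox == "pelvis" else f"{prox}_{side}"]
            dist_traj = trial[f"{dist}_{side}"]
            wf = joint_angle_waveform(prox_traj, dist_traj, side, entity)
            for plane in ("x", "y", "z"):
                waveforms[(entity, plane, side)] = time_normalize(
                    wf.component(plane), frame_rate, window)
        for entity in SEGMENT_DEFS:
            seg = trial["pelvis" if entity == "pelvis" else f"{entity}_{side}"]
            wf = segment_angle_waveform(
                seg, progression, None if entity == "pelvis" else side, entity)
            for plane in ("x", "y", "z"):
                waveforms[(entity, plane, side)] = time_normalize(
                    wf.component(plane), frame_rate, window)
    return record.to_flat_dict(), waveforms, notes


# ---------------------------------------------------------------------------
# Scalar reliability
# ---------------------------------------------------------------------------

def _nan_icc(n: int, k: int) -> IccResult:
    nan = math.nan
    return IccResult(nan, nan, (nan, nan), n, k, nan, 0, 0, nan, nan, nan,
                     degenerate=True)


def _safe_icc(mat: pd.DataFrame) -> IccResult:
    """ICC over a pivoted matrix; undersized designs (a single session or
    too few complete rows) yield a flagged nan result instead of an error."""
    arr = mat.dropna().to_numpy()
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        return _nan_icc(*arr.shape) if arr.ndim == 2 else _nan_icc(0, 0)
    return icc_3k(arr)


def _within_icc(sampled: pd.DataFrame, param: str, layout: str) -> IccResult:
    if layout == "stacked":
        mat = sampled.pivot_table(index=["subject", "session"],
                                  columns="trial_rank", values=param)
        return _safe_icc(mat)
    results = []
    for _, sub in sampled.groupby("session"):
        mat = sub.pivot_table(index="subject", columns="trial_rank", values=param)
        results.append(_safe_icc(mat))
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    first = results[0]
    return IccResult(
        icc=mean([r.icc for r in results]),
        icc_single=mean([r.icc_single for r in results]),
        ci95=(mean([r.ci95[0] for r in results]), mean([r.ci95[1] for r in results])),
        n=first.n, k=first.k, f_value=mean([r.f_value for r in results]),
        df1=first.df1, df2=first.df2,
        bms=mean([r.bms for r in results]), jms=mean([r.jms for r in results]),
        ems=mean([r.ems for r in results]),
        degenerate=any(r.degenerate for r in results))


def _between_icc(sampled: pd.DataFrame, param: str) -> IccResult:
    means = sampled.groupby(["subject", "session"])[param].mean().unstack("session")
    return _safe_icc(means)


def scalar_reliability(df_all: pd.DataFrame, df_sampled: pd.DataFrame,
                       params=ALL_PARAMS, layout: str = "stacked") -> pd.DataFrame:
    """Reliability table (one row per parameter): grand mean/SD over all
    trials; within- and between-session ICC(3,k), SEM and MDC from the
    sampled trials."""
    rows = []
    for param in params:
        sd_total = float(df_all[param].std(ddof=1))
        row: dict = {"parameter": param,
                     "mean": float(df_all[param].mean()), "sd": sd_total}
        for scope, icc_result in (("within", _within_icc(df_sampled, param, layout)),
                                  ("between", _between_icc(df_sampled, param))):
            # a negative consistency ICC means no usable true-score variance;
            # SEM is then the whole SD (clip into sem()'s [0, 1] domain)
            s = (math.nan if math.isnan(icc_result.icc_single)
                 else sem(sd_total, min(max(icc_result.icc_single, 0.0), 1.0)))
            row.update({
                f"{scope}_sem": s,
                f"{scope}_mdc": math.nan if math.isnan(s) else mdc(s),
                f"{scope}_icc": icc_result.icc,
                f"{scope}_icc_single": icc_result.icc_single,
                f"{scope}_ci_lo": icc_result.ci95[0],
                f"{scope}_ci_hi": icc_result.ci95[1],
                f"{scope}_band": classify_icc(icc_result.icc),
                f"{scope}_degenerate": icc_result.degenerate,
            })
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Waveform (CMD) reliability
# ---------------------------------------------------------------------------

def waveform_reliability(curves: dict, sampled_labels, variables=KINEMATIC_VARIABLES,
                         sides_combined: bool = True) -> pd.DataFrame:
    """CMD table from normalized waveforms.

    ``curves`` maps (entity, plane, side) -> {(subject, session, trial) ->
    (101,) array}; only sampled labels enter.  Returns one row per (entity,
    plane) with within- and between-session summaries across subjects.
    """
    sampled = set(sampled_labels)
    rows = []
    for entity, plane in variables:
        within_by_subject: dict = {}
        between_by_subject: dict = {}
        for side in ("L", "R"):
            per_label = curves.get((entity, plane, side), {})
            by_cell: dict = {}
            for label, curve in per_label.items():
                if label in sampled:
                    by_cell.setdefault(label[:2], []).append(curve)
            cells_by_subject: dict = {}
            for (subj, sess), reps in by_cell.items():
                if len(reps) >= 2:
                    cells_by_subject.setdefault(subj, {})[sess] = np.vstack(reps)
            for subj, by_sess in cells_by_subject.items():
                w = float(np.mean([cmd(m) for m in by_sess.values()]))
                within_by_subject.setdefault(subj, []).append(w)
                if len(by_sess) >= 2:
                    session_means = np.vstack(
                        [m.mean(axis=0) for _, m in sorted(by_sess.items())])
                    between_by_subject.setdefault(subj, []).append(
                        cmd(session_means))
            if not sides_combined:
                break
        within_vals = [float(np.mean(v)) for v in within_by_subject.values()]
        between_vals = [float(np.mean(v)) for v in between_by_subject.values()]
        row = {"entity": entity, "plane": PLANE_NAMES[plane]}
        for scope, vals in (("within", within_vals), ("between", between_vals)):
            # a single-session dataset has no between-session repetitions;
            # degrade to a nan summary rather than failing the whole run
            if len(vals) < 2:
                summary = CmdSummary(math.nan, math.nan,
                                     (math.nan, math.nan), len(vals))
            else:
                summary = summarize_cmd(vals)
            row.update({
                f"{scope}_mean": summary.mean, f"{scope}_sd": summary.sd,
                f"{scope}_ci_lo": summary.ci95[0], f"{scope}_ci_hi": summary.ci95[1],
                f"{scope}_band": summary.band,
            })
        rows.append(row)
    return pd.DataFrame(rows).set_index(["entity", "plane"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_study(dataset, config: AnalysisConfig | None = None) -> StudyReport:
    """Run the complete analysis over a dataset (anything exposing
    ``frame_rate`` and ``trials``)."""
    config = config or AnalysisConfig()
    labels = sorted(dataset.trials)
    sampled = sample_trials(labels, config.n_trials_sampled, config.sampling_seed)

    records, curve_store, failures = [], {}, []
    for label in labels:
        try:
            flat, waveforms, _notes = process_trial(
                dataset.trials[label], dataset.frame_rate, config)
        except Exception as exc:  # logged, not fatal below the threshold
            failures.append({"label": list(label), "error": str(exc)})
            continue
        flat.update({"subject": label[0], "session": label[1], "trial": label[2]})
        records.append(flat)
        for key, curve in waveforms.items():
            curve_store.setdefault(key, {})[label] = curve

    n_total = len(labels)
    if n_total and len(failures) / n_total > config.max_failure_fraction:
        raise TrialProcessingError(
            f"{len(failures)}/{n_total} trials failed processing: {failures}")

    df_all = pd.DataFrame(records)
    processed = set(map(tuple, df_all[["subject", "session", "trial"]].itertuples(
        index=False, name=None)))
    sampled_ok = [lab for lab in sampled if lab in processed]
    df_sampled = df_all.set_index(["subject", "session", "trial"]).loc[
        sampled_ok].reset_index()
    rank = df_sampled.groupby(["subject", "session"]).cumcount()
    df_sampled = df_sampled.assign(trial_rank=rank)

    spatio = scalar_reliability(df_all, df_sampled, ALL_PARAMS, config.icc_layout)
    kin = waveform_reliability(curve_store, sampled_ok,
                               sides_combined=config.sides_combined)
    joint_table = kin.loc[list(JOINT_DEFS)]
    segment_table = kin.loc[list(SEGMENT_DEFS)]

    provenance = {
        "software": {"package": "gaitrel", "version": _pkg_version},
        "config": _config_dict(config),
        "n_trials_total": n_total,
        "n_trials_analyzed": len(records),
        "n_trials_sampled": len(sampled_ok),
        "failures": failures,
    }
    per_trial = df_all.set_index(["subject", "session", "trial"]).sort_index()
    return StudyReport(joint_table, segment_table, spatio, per_trial, provenance)


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    d["output_formats"] = list(d["output_formats"])
    return d


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_TABLES = ("joint_table", "segment_table", "spatiotemporal_table", "per_trial")
_FILE_STEMS = {"joint_table": "joint_kinematics",
               "segment_table": "segment_kinematics",
               "spatiotemporal_table": "spatiotemporal",
               "per_trial": "per_trial"}


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: f"{x:.3f}" if pd.notna(x) else "")
    return out


_MD_HEADERS = {
    "within_mean": "Within-Session CMD Mean", "within_sd": "Within SD",
    "within_ci_lo": "Within CI95 lo", "within_ci_hi": "Within CI95 hi",
    "within_band": "Within Band",
    "between_mean": "Between-Session CMD Mean", "between_sd": "Between SD",
    "between_ci_lo": "Between CI95 lo", "between_ci_hi": "Between CI95 hi",
    "between_band": "Between Band",
}


def _markdown_table(df: pd.DataFrame) -> str:
    flat = _fmt(df.reset_index())
    cols = [_MD_HEADERS.get(str(c), str(c)) for c in flat.columns[df.index.nlevels:]]
    lines = ["Variable | " + " | ".join(cols),
             " | ".join(["---"] * (len(cols) + 1))]
    for _, row in flat.iterrows():
        label = " ".join(str(row.iloc[i]) for i in range(df.index.nlevels))
        lines.append(label + " | " + " | ".join(
            str(v) for v in row.iloc[df.index.nlevels:]))
    return "\n".join(lines)


def render_report(report: StudyReport, out_dir, formats=("csv",)) -> list[Path]:
    """Write report tables (3-decimal formatting) and the provenance block.

    Formats: csv, xlsx, markdown.  Re-rendering the same report is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    (out_dir / "provenance.json").write_text(
        json.dumps(report.provenance, sort_keys=True, indent=1))
    written.append(out_dir / "provenance.json")

    for attr in _TABLES:
        df = getattr(report, attr)
        stem = _FILE_STEMS[attr]
        if "csv" in formats:
            path = out_dir / f"{stem}.csv"
            _fmt(df).to_csv(path)
            written.append(path)
        if "xlsx" in formats:
            path = out_dir / f"{stem}.xlsx"
            df.to_excel(path)
            written.append(path)
    if "markdown" in formats:
        md = ["# Gait reliability report", ""]
        for title, attr in (("Joint kinematics (CMD)", "joint_table"),
                            ("Segment kinematics (CMD)", "segment_table"),
                            ("Spatiotemporal parameters (ICC/SEM/MDC)",
                             "spatiotemporal_table")):
            md += [f"## {title}", "", _markdown_table(getattr(report, attr)), ""]
        path = out_dir / "report.md"
        path.write_text("\n".join(md))
        written.append(path)
    return written
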