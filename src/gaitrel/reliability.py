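"""Reliability statistics: CMD for waveforms; ICC(3,k), SEM and MDC for scalars.

The coefficient of multiple determination (CMD, the squared coefficient of
multiple correlation) measures how much of the pooled variance of W repeated
waveforms is explained by their shared mean curve:

    CMD = 1 - [ sum_wt (Y_wt - Ybar_t)^2 / (T (W - 1)) ]
            / [ sum_wt (Y_wt - Ybar)^2  / (W T - 1) ]

with Ybar_t the time-point mean across repetitions and Ybar the grand mean.
CMD <= 1 always; it can be negative when repetitions disagree more than the
overall signal varies.

The intraclass correlation ICC(3,k) is the two-way mixed-effects consistency
coefficient for the average of k measurements, from the two-way ANOVA mean
squares (rows BMS, columns JMS, residual EMS):

    ICC(3,k) = (BMS - EMS) / BMS
    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

linked by the Spearman-Brown identity.  The 95% CI comes from the F statistic
BMS/EMS with (n-1, (n-1)(k-1)) degrees of freedom.

SEM = SD_total * sqrt(1 - ICC(3,1)) and MDC = 1.96 * sqrt(2) * SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputWarning, IncompleteMatrixError, ValidationError

MDC_FACTOR = 1.96 * math.sqrt(2.0)

CMD_BANDS = ("below_small", "small", "medium", "large")
ICC_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass
class CmdSummary:
    """Mean, sample SD and t-based CI95 of per-subject CMD values."""

    mean: float
    sd: float
    ci95: tuple[float, float]
    n: int

    @property
    def band(self) -> str:
        return classify_cmd(self.mean)


@dataclass
class IccResult:
    """ICC(3,k) with its F-based CI and the ICC(3,1) companion."""

    icc: float
    icc_single: float
    ci95: tuple[float, float]
    n: int
    k: int
    f_value: float
    df1: int
    df2: int
    bms: float
    jms: float
    ems: float
    degenerate: bool = False

    @property
    def band(self) -> str:
        return classify_icc(self.icc)


def cmd(waveforms: np.ndarray) -> float:
    """Coefficient of multiple determination of a W x T repetition matrix.

    Identical repetitions give exactly 1.  Zero total variance (all values
    equal) is degenerate: 1 is returned with a :class:`DegenerateInputWarning`.
    """
    y = np.asarray(waveforms, dtype=float)
    if y.ndim != 2:
        raise ValidationError("waveforms: expected a 2-D W x T matrix")
    w, t = y.shape
    if w < 2 or t < 2:
        raise ValidationError("waveforms: need W >= 2 repetitions and T >= 2 points")
    if np.isnan(y).any():
        raise IncompleteMatrixError("waveforms: missing values not allowed")
    mean_t = y.mean(axis=0)
    grand = y.mean()
    ss_within = ((y - mean_t) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    # relative threshold: identical repetitions leave only accumulation
    # residue of order eps^2 * scale in the sums of squares
    if ss_total <= 1e-20 * w * t * max(1.0, grand * grand):
        warnings.warn("all waveform values identical; CMD defined as 1",
                      DegenerateInputWarning, stacklevel=2)
        return 1.0
    num = ss_within / (t * (w - 1))
    den = ss_total / (w * t - 1)
    return 1.0 - num / den


def summarize_cmd(per_subject_cmds, confidence: float = 0.95) -> CmdSummary:
    """Mean, sample SD and t-interval across per-subject CMD values."""
    values = np.asarray(per_subject_cmds, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n < 2:
        raise ValidationError("per_subject_cmds: at least 2 values required")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd / math.sqrt(n)
    return CmdSummary(mean, sd, (mean - half, mean + half), n)


def icc_3k(matrix: np.ndarray, confidence: float = 0.95) -> IccResult:
    """Two-way mixed-effects consistency ICC for the average of k columns.

    ``matrix`` is a complete n x k array: rows are measurement units
    (subjects or subject-session units), columns repeated measurements.
    BMS = 0 (no between-row variance) is flagged degenerate with nan ICCs.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValidationError("matrix: expected 2-D n x k")
    if np.isnan(m).any():
        raise IncompleteMatrixError("matrix: complete design required (missing cells)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError("matrix: need n >= 2 rows and k >= 2 columns")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    df1, df2 = n - 1, (n - 1) * (k - 1)
    bms = ss_rows / df1
    jms = ss_cols / (k - 1)
    ems = ss_err / df2

    # constant inputs leave only float accumulation residue in the mean
    # squares; treat anything at that scale as exactly zero
    tiny = 1e-20 * max(1.0, grand * grand)
    bms = 0.0 if bms <= tiny else bms
    ems = 0.0 if ems <= tiny else ems

    if bms == 0.0:
        warnings.warn("no between-row variance; ICC undefined",
                      DegenerateInputWarning, stacklevel=2)
        return IccResult(math.nan, math.nan, (math.nan, math.nan), n, k,
                         math.nan, df1, df2, bms, jms, ems, degenerate=True)

    icc_k = (bms - ems) / bms
    icc_1 = (bms - ems) / (bms + (k - 1) * ems)
    degenerate = ems == 0.0
    if degenerate:
        warnings.warn("zero residual variance; ICC is exactly 1",
                      DegenerateInputWarning, stacklevel=2)
        f_value = math.inf
        ci = (1.0, 1.0)
    else:
        f_value = bms / ems
        alpha = 1.0 - confidence
        f_low = f_value / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_up = f_value * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = (1.0 - 1.0 / f_low, 1.0 - 1.0 / f_up)
    return IccResult(float(icc_k), float(icc_1), ci, n, k, f_value, df1, df2,
                     bms, jms, ems, degenerate=degenerate)


def spearman_brown(icc_single: float, k: int) -> float:
    """ICC for the average of k measurements from the single-measurement ICC."""
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def sem(sd_total: float, icc_single: float) -> float:
    """Standard error of measurement: SD_total * sqrt(1 - ICC(3,1))."""
    if sd_total < 0:
        raise ValidationError("sd_total: must be >= 0")
    if not -1e-12 <= icc_single <= 1 + 1e-12:
        raise ValidationError(f"icc_single: {icc_single} outside [0, 1]")
    return sd_total * math.sqrt(max(0.0, 1.0 - min(icc_single, 1.0)))


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * sqrt(2) * SEM."""
    if sem_value < 0:
        raise ValidationError("sem_value: must be >= 0")
    return MDC_FACTOR * sem_value


def classify_cmd(value: float) -> str:
    """Effect-size band for a CMD value (strict thresholds 0.04/0.25/0.64)."""
    if math.isnan(value):
        return "undefined"
    if value > 0.64:
        return "large"
    if value > 0.25:
        return "medium"
    if value > 0.04:
        return "small"
    return "below_small"


def classify_icc(value: float) -> str:
    """Reliability band for an ICC: <0.5 poor, 0.5-0.75 moderate,
    0.75-0.9 good, >0.9 excellent."""
    if math.isnan(value):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"
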