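"""Device-validation statistics for BP estimators.

Everything needed to judge a cuffless estimator against the clinical
device standards:

* ΔBP summary (ΔBP = actual − estimated; negative means overestimation)
  with cumulative percentages of |ΔBP| within 5 / 10 / 15 mmHg,
* BHS letter grading of those percentages (A: 60/85/95, B: 50/75/90,
  C: 40/65/85, D otherwise; overall grade = worst of the three),
* the AAMI bound (|mean| <= 5 mmHg and SD <= 8 mmHg, boundary inclusive),
* Bland–Altman limits of agreement (mean ± 1.96·SD),
* Pearson correlation between actual and estimated BP,
* Shapiro–Wilk normality testing,
* the hypotension / normotension / hypertension interval breakdown
  (SBP <90 / 90–129 / >=130; DBP <60 / 60–79 / >=80, by ACTUAL BP),
* and the grouping-year sweep that retrains banks across bin widths.

Cumulative-percentage thresholds are inclusive and the sample (n−1)
standard deviation is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    EmptyBankError,
    InvalidConfigError,
    SampleSizeError,
    UndefinedCorrelationError,
)
from .features import FEATURE_NAMES
from . import gpr, model_bank

logger = logging.getLogger(__name__)

BHS_CRITERIA = {  # grade -> minimum cumulative % at (<=5, <=10, <=15) mmHg
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
GRADE_ORDER = "ABCD"

AAMI_MEAN_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0

SBP_INTERVALS = (("hypotension", -np.inf, 90.0), ("normotension", 90.0, 130.0), ("hypertension", 130.0, np.inf))
DBP_INTERVALS = (("hypotension", -np.inf, 60.0), ("normotension", 60.0, 80.0), ("hypertension", 80.0, np.inf))

ALLOWED_SWEEP_WIDTHS = {5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 100}


@dataclass(frozen=True)
class DeltaBPStats:
    """Summary of ΔBP = actual − estimated over a validation set."""

    mean: float
    sd: float
    n: int
    cum5: float
    cum10: float
    cum15: float

    def __post_init__(self) -> None:
        if not 0 <= self.cum5 <= self.cum10 <= self.cum15 <= 100:
            raise InvalidConfigError("cumulative percentages must be monotone in [0, 100]")
        if self.sd < 0:
            raise InvalidConfigError("sd must be >= 0")


@dataclass
class EvalReport:
    """Full statistical report for one estimator on one target."""

    stats: DeltaBPStats
    bhs_per_threshold: tuple[str, str, str]
    bhs_grade: str
    aami_pass: bool
    ba_lower: float
    ba_upper: float
    pearson_r: Optional[float]
    pearson_p: Optional[float]
    subgroups: Optional[dict] = None


def delta_stats(actual: Sequence[float], estimated: Sequence[float]) -> DeltaBPStats:
    """ΔBP summary; ΔBP = actual − estimated, thresholds inclusive."""
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape:
        raise InvalidConfigError("actual and estimated must share a length")
    if a.size < 2:
        raise InvalidConfigError("need at least 2 paired readings")
    d = a - e
    abs_d = np.abs(d)
    return DeltaBPStats(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)),
        n=int(d.size),
        cum5=float(100.0 * np.mean(abs_d <= 5.0)),
        cum10=float(100.0 * np.mean(abs_d <= 10.0)),
        cum15=float(100.0 * np.mean(abs_d <= 15.0)),
    )


def bhs_grade(cum5: float, cum10: float, cum15: float) -> tuple[tuple[str, str, str], str]:
    """Per-threshold BHS letter grades and the overall (worst) grade."""
    if not 0 <= cum5 <= cum10 <= cum15 <= 100:
        raise InvalidConfigError("cumulative percentages must be monotone in [0, 100]")

    def grade_one(value: float, column: int) -> str:
        for letter in "ABC":
            if value >= BHS_CRITERIA[letter][column]:
                return letter
        return "D"

    per = (grade_one(cum5, 0), grade_one(cum10, 1), grade_one(cum15, 2))
    overall = max(per, key=GRADE_ORDER.index)
    return per, overall


def aami_check(stats: DeltaBPStats) -> bool:
    """AAMI verdict: |mean ΔBP| <= 5 mmHg and SD <= 8 mmHg (inclusive)."""
    return abs(stats.mean) <= AAMI_MEAN_LIMIT and stats.sd <= AAMI_SD_LIMIT


def bland_altman_limits(stats: DeltaBPStats) -> tuple[float, float]:
    """Limits of agreement: mean ± 1.96·SD of the differences."""
    return stats.mean - 1.96 * stats.sd, stats.mean + 1.96 * stats.sd


def pearson_corr(actual: Sequence[float], estimated: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t transform)."""
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape or a.size < 3:
        raise InvalidConfigError("need equal-length inputs with n >= 3")
    if a.std() == 0 or e.std() == 0:
        raise UndefinedCorrelationError("zero variance in one input")
    res = _stats.pearsonr(a, e)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value; valid for 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise SampleSizeError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {v.size}")
    res = _stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def make_report(actual: Sequence[float], estimated: Sequence[float]) -> EvalReport:
    """Assemble the full evaluation report for one estimator."""
    stats = delta_stats(actual, estimated)
    per, overall = bhs_grade(stats.cum5, stats.cum10, stats.cum15)
    lower, upper = bland_altman_limits(stats)
    try:
        r, p = pearson_corr(actual, estimated)
    except (UndefinedCorrelationError, InvalidConfigError):
        r, p = None, None
    return EvalReport(
        stats=stats,
        bhs_per_threshold=per,
        bhs_grade=overall,
        aami_pass=aami_check(stats),
        ba_lower=lower,
        ba_upper=upper,
        pearson_r=r,
        pearson_p=p,
    )


def interval_breakdown(
    actual: Sequence[float], estimated: Sequence[float], target: str
) -> dict[str, Optional[EvalReport]]:
    """Per-interval reports with subjects partitioned by ACTUAL BP.

    Empty (or single-reading) subgroups are reported as ``None`` with the
    count kept in the companion ``{label}_n`` entry so sizes still sum to
    the total.
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape:
        raise InvalidConfigError("actual and estimated must share a length")
    intervals = SBP_INTERVALS if target == "SBP" else DBP_INTERVALS
    out: dict[str, Optional[EvalReport]] = {}
    for label, lo, hi in intervals:
        mask = (a >= lo) & (a < hi)
        out[f"{label}_n"] = int(mask.sum())
        if mask.sum() >= 2:
            out[label] = make_report(a[mask], e[mask])
        else:
            out[label] = None  # statistics undefined on 0–1 readings
    return out


def report_with_subgroups(actual, estimated, target: str) -> EvalReport:
    """Total-mode report carrying the interval-mode breakdown."""
    report = make_report(actual, estimated)
    report.subgroups = interval_breakdown(actual, estimated, target)
    return report


def grouping_sweep(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    widths: Sequence[int],
    target: str,
    fit_options: gpr.FitOptions = gpr.FitOptions(),
    min_cell_size: int = model_bank.DEFAULT_MIN_CELL_SIZE,
) -> dict[int, DeltaBPStats]:
    """Uncalibrated ΔBP statistics across age-grouping widths.

    For each width a fresh bin scheme is built, banks are retrained on
    the training split and evaluated (without calibration) on the test
    split; width 100 is a single bin, i.e. no grouping. Widths whose
    schemes produce zero trainable cells, or under which no test row has
    a model, are skipped with a warning.
    """
    bad = set(widths) - ALLOWED_SWEEP_WIDTHS
    if bad:
        raise InvalidConfigError(f"widths {sorted(bad)} not in {sorted(ALLOWED_SWEEP_WIDTHS)}")
    ycol = target.lower()
    out: dict[int, DeltaBPStats] = {}
    for width in widths:
        scheme = model_bank.AgeBinScheme.from_width(width)
        try:
            bank = model_bank.train_bank(
                train_table, scheme, target, fit_options, min_cell_size
            )
        except EmptyBankError:
            logger.warning("width %d produced no trainable cells; skipped", width)
            continue
        actual, estimated = [], []
        for _, row in test_table.iterrows():
            fv_arr = row[list(FEATURE_NAMES)].to_numpy(dtype=float)
            label = model_bank.assign_group(row["age"], scheme)
            key = (int(row["gender"]), label)
            if key not in bank.models:
                continue
            mean, _ = gpr.predict(bank.models[key], fv_arr)
            actual.append(float(row[ycol]))
            estimated.append(mean)
        if len(actual) < 2:
            logger.warning("width %d left no evaluable test rows; skipped", width)
            continue
        out[width] = delta_stats(actual, estimated)
    return out
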