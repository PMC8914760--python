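"""Gender x age-bin model banks and feedback calibration.

PPG morphology maps onto BP differently in different demographic strata,
so instead of one population regression the pipeline trains a *bank* of
exponential-GPR models, one per (gender, age bin) cell. SBP uses 30-year
bins (<30, 30-60, >=60) and DBP 15-year bins (<30, 30-45, 45-60, 60-75,
>=75), reflecting the wider dynamic range of SBP.

Feedback calibration personalises the estimator with a single reference
cuff reading: every age-bin model of the subject's gender predicts the
calibration feature vector(s), the bin whose predictions sit closest to
the reference (minimal mean absolute error) is selected — regardless of
the subject's chronological age — and the calibration pairs can then be
absorbed into a personal copy of that model (hyperparameters frozen,
posterior recomputed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyBankError,
    InvalidConfigError,
    MissingModelError,
    OutOfRangeAgeError,
)
from .features import FEATURE_NAMES, FeatureVector
from . import gpr

logger = logging.getLogger(__name__)

AGE_LO = 15
AGE_HI = 95  # exclusive upper edge of the partition

DEFAULT_SBP_WIDTH = 30
DEFAULT_DBP_WIDTH = 15

#: Minimum distinct subjects a cell needs before a model is trained.
DEFAULT_MIN_CELL_SIZE = 5


@dataclass(frozen=True)
class AgeBinScheme:
    """Ordered half-open age bins partitioning [15, 95).

    ``edges`` are the lower bounds of each bin (the first is 15); the top
    bin is unbounded above within the partition. Labels follow interval
    notation, e.g. ``"Age < 30"``, ``"30 <= Age < 60"``, ``"60 <= Age"``.
    """

    edges: tuple[int, ...]
    bin_width: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.edges or self.edges[0] != AGE_LO:
            raise InvalidConfigError("first bin edge must be 15")
        if list(self.edges) != sorted(set(self.edges)):
            raise InvalidConfigError("bin edges must be strictly increasing")
        if self.edges[-1] >= AGE_HI:
            raise InvalidConfigError("bin edges must stay below 95")

    @classmethod
    def from_width(cls, width: int) -> "AgeBinScheme":
        """Bins of ``width`` years: boundaries at multiples of the width.

        The last boundary is capped so the top bin spans at least
        min(width, 20) years; width >= 80 yields a single ungrouped bin.
        This reproduces the default schemes: width 30 -> {<30, 30-60,
        >=60}; width 15 -> {<30, 30-45, 45-60, 60-75, >=75}.
        """
        if width < 1:
            raise InvalidConfigError("bin width must be >= 1 year")
        cap = AGE_HI - min(width, 20)
        bounds = [b for b in range(width, AGE_HI, width) if AGE_LO < b <= cap]
        return cls(edges=tuple([AGE_LO] + bounds), bin_width=width)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for i, lo in enumerate(self.edges):
            if i == 0 and len(self.edges) > 1:
                out.append(f"Age < {self.edges[1]}")
            elif i == len(self.edges) - 1:
                out.append(f"{lo} <= Age" if i > 0 else "Age (all)")
            else:
                out.append(f"{lo} <= Age < {self.edges[i + 1]}")
        return tuple(out)

    def age_range(self, label: str) -> tuple[int, int]:
        """(lower, upper) bounds in years of a labelled bin."""
        i = self.labels.index(label)
        hi = self.edges[i + 1] if i + 1 < len(self.edges) else AGE_HI
        return self.edges[i], hi


def assign_group(age: float, scheme: AgeBinScheme) -> str:
    """Label of the unique half-open bin containing ``age`` (lower inclusive)."""
    if not AGE_LO <= age < AGE_HI:
        raise OutOfRangeAgeError(f"age {age} outside [{AGE_LO}, {AGE_HI})")
    idx = int(np.searchsorted(np.asarray(scheme.edges), age, side="right")) - 1
    return scheme.labels[idx]


def default_scheme(target: str) -> AgeBinScheme:
    if target == "SBP":
        return AgeBinScheme.from_width(DEFAULT_SBP_WIDTH)
    if target == "DBP":
        return AgeBinScheme.from_width(DEFAULT_DBP_WIDTH)
    raise InvalidConfigError(f"target must be 'SBP' or 'DBP', got {target!r}")


@dataclass
class ModelBank:
    """Mapping (gender, age-bin label) -> fitted GPR model for one target."""

    target: str
    scheme: AgeBinScheme
    models: dict[tuple[int, str], gpr.GPRModel]
    provenance: dict = field(default_factory=dict)

    def lookup(self, gender: int, label: str) -> gpr.GPRModel:
        key = (int(gender), label)
        if key not in self.models:
            raise MissingModelError(
                f"no {self.target} model for gender={gender}, bin={label!r}"
            )
        return self.models[key]

    def labels_for_gender(self, gender: int) -> list[str]:
        return [lab for lab in self.scheme.labels if (int(gender), lab) in self.models]


@dataclass
class CalibrationState:
    """Outcome of feedback calibration for one subject and target."""

    subject_id: str
    target: str
    selected_bin: str
    selected_gender: int
    calibration_pairs: list[tuple[FeatureVector, float]]
    scores: dict[str, float] = field(default_factory=dict)
    augmented: bool = False
    personal_model: Optional[gpr.GPRModel] = None

    def __post_init__(self) -> None:
        if not self.calibration_pairs:
            raise InvalidConfigError("calibration requires at least one pair")


def _config_digest(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def train_bank(
    table: pd.DataFrame,
    scheme: AgeBinScheme,
    target: str,
    fit_options: gpr.FitOptions = gpr.FitOptions(),
    min_cell_size: int = DEFAULT_MIN_CELL_SIZE,
    aggregate_subjects: bool = True,
) -> ModelBank:
    """Train one GPR per (gender, age-bin) cell of a feature table.

    ``table`` holds one row per (subject, window) with the 10 feature
    columns, ``subject_id`` and the target column (``sbp`` or ``dbp``).
    With ``aggregate_subjects`` (the default) the window rows of each
    subject are averaged into a single training row, mirroring a
    reference database that pairs one averaged PPG reading with one cuff
    BP per participant; repeated near-identical rows with an identical
    target would otherwise let the marginal likelihood collapse the noise
    variance to within-subject level and destroy cross-subject
    generalisation. Cells with fewer than ``min_cell_size`` distinct
    subjects are skipped with a warning and recorded in the bank's
    provenance. Rows are sorted canonically before fitting so training is
    order-independent.
    """
    if target not in ("SBP", "DBP"):
        raise InvalidConfigError(f"target must be 'SBP' or 'DBP', got {target!r}")
    ycol = target.lower()
    required = set(FEATURE_NAMES) | {"subject_id", ycol}
    missing = required - set(table.columns)
    if missing:
        raise InvalidConfigError(f"feature table missing columns {sorted(missing)}")
    if aggregate_subjects:
        agg = {name: "mean" for name in FEATURE_NAMES}
        agg[ycol] = "first"
        table = table.groupby("subject_id", as_index=False).agg(agg)
    sort_cols = ["subject_id"] + (["window_id"] if "window_id" in table.columns else [])
    table = table.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    labels = table["age"].map(lambda a: assign_group(a, scheme))
    models: dict[tuple[int, str], gpr.GPRModel] = {}
    skipped: list[dict] = []
    for (gender, label), cell in table.groupby([table["gender"].astype(int), labels]):
        n_subjects = cell["subject_id"].nunique()
        if n_subjects < min_cell_size:
            logger.warning(
                "skipping %s cell gender=%d bin=%r: %d subjects < %d",
                target, gender, label, n_subjects, min_cell_size,
            )
            skipped.append({"gender": int(gender), "bin": label, "n_subjects": int(n_subjects)})
            continue
        training = gpr.TrainingSet(
            cell[list(FEATURE_NAMES)].to_numpy(dtype=float),
            cell[ycol].to_numpy(dtype=float),
        )
        models[(int(gender), label)] = gpr.fit_gpr(training, fit_options)
    if not models:
        raise EmptyBankError(f"no trainable cells for target {target}")
    provenance = {
        "digest": _config_digest(
            {
                "target": target,
                "edges": list(scheme.edges),
                "min_cell_size": min_cell_size,
                "n_rows": int(len(table)),
                "fit_seed": fit_options.seed,
            }
        ),
        "skipped_cells": skipped,
    }
    return ModelBank(target=target, scheme=scheme, models=models, provenance=provenance)


def predict_uncalibrated(bank: ModelBank, fv: FeatureVector) -> float:
    """BP prediction from the subject's own demographic cell."""
    label = assign_group(fv.age, bank.scheme)
    model = bank.lookup(fv.gender, label)
    mean, _ = gpr.predict(model, fv.to_array())
    return float(mean)


def calibrate_select(
    bank: ModelBank,
    calib_features: Sequence[FeatureVector],
    reference_bp: Sequence[float],
    gender: int,
) -> CalibrationState:
    """Select the age-bin model minimising error against cuff readings.

    Every age bin trained for ``gender`` predicts each calibration
    feature vector; the score is the mean absolute error against the
    reference readings and the arg-min bin is selected. Ties break toward
    the subject's chronological bin, then toward the younger bin.
    """
    if len(calib_features) == 0 or len(calib_features) != len(reference_bp):
        raise InvalidConfigError("need equal, non-zero numbers of features and references")
    labels = bank.labels_for_gender(gender)
    if not labels:
        raise MissingModelError(f"no {bank.target} models for gender={gender}")
    refs = np.asarray(reference_bp, dtype=float)
    chrono = assign_group(calib_features[0].age, bank.scheme)
    scores: dict[str, float] = {}
    for label in labels:
        model = bank.models[(int(gender), label)]
        preds = np.array([gpr.predict(model, fv.to_array())[0] for fv in calib_features])
        scores[label] = float(np.mean(np.abs(preds - refs)))
    best = min(scores.values())
    tied = [lab for lab in labels if scores[lab] <= best + 1e-9]
    selected = chrono if chrono in tied else tied[0]  # labels ordered young -> old
    return CalibrationState(
        subject_id=getattr(calib_features[0], "subject_id", ""),
        target=bank.target,
        selected_bin=selected,
        selected_gender=int(gender),
        calibration_pairs=[(fv, float(r)) for fv, r in zip(calib_features, refs)],
        scores=scores,
    )


def augment_model(state: CalibrationState, bank: ModelBank) -> gpr.GPRModel:
    """Absorb the calibration pairs into a personal copy of the selected model.

    The bank's model is untouched; the returned copy shares its
    hyperparameters and standardizer but includes the calibration pairs
    in its training set, with the posterior solve recomputed. The state
    is updated in place to carry the personal model.
    """
    base = bank.lookup(state.selected_gender, state.selected_bin)
    X = np.array([fv.to_array() for fv, _ in state.calibration_pairs])
    y = np.array([r for _, r in state.calibration_pairs])
    personal = gpr.augment(base, X, y)
    state.personal_model = personal
    state.augmented = personal is not base
    return personal


def predict_calibrated(state: CalibrationState, bank: ModelBank, fv: FeatureVector) -> float:
    """BP prediction from the personal (selected, optionally augmented) model."""
    if state is None:
        raise MissingModelError("calibration state required; no silent fallback")
    model = state.personal_model
    if model is None:
        model = bank.lookup(state.selected_gender, state.selected_bin)
    mean, _ = gpr.predict(model, fv.to_array())
    return float(mean)
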