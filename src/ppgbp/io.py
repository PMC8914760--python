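"""File formats: cohort/feature/prediction CSV tables, waveforms, banks, reports.

All artifacts are plain text. Tabular kinds are CSV with fixed, documented
headers; waveforms are one-column CSV per subject plus a JSON sidecar;
model banks are a JSON directory (one file per cell plus a manifest);
evaluation reports are JSON. Gender appears as 0/1 integers (0 = female,
1 = male); ages are integer years. Round trips are lossless to 1e-12.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatVersionError, MissingArtifactError, SchemaError
from .evaluation import DeltaBPStats, EvalReport
from .features import FEATURE_NAMES
from .model_bank import AgeBinScheme, ModelBank
from .preprocess import PPGRecord
from .synthetic_cohort import SubjectProfile
from . import gpr

BANK_FORMAT_VERSION = 1

COHORT_COLUMNS = ["subject_id", "age", "gender", "sbp", "dbp", "heart_rate"]
FEATURE_COLUMNS = ["subject_id", "window_id", *FEATURE_NAMES, "sbp", "dbp"]
PREDICTION_COLUMNS = [
    "subject_id",
    "window_id",
    "target",
    "actual",
    "estimated_uncalibrated",
    "estimated_calibrated",
    "selected_bin",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing columns: {missing}")


def write_cohort(profiles: Sequence[SubjectProfile], path: Path) -> None:
    rows = [
        {
            "subject_id": p.subject_id,
            "age": p.age,
            "gender": p.gender,
            "sbp": p.sbp_true,
            "dbp": p.dbp_true,
            "heart_rate": p.heart_rate,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path: Path) -> list[SubjectProfile]:
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, "cohort")
    return [
        SubjectProfile(
            subject_id=str(r.subject_id),
            age=int(r.age),
            gender=int(r.gender),
            sbp_true=float(r.sbp),
            dbp_true=float(r.dbp),
            heart_rate=float(r.heart_rate),
        )
        for r in df.itertuples()
    ]


def write_waveform(record: PPGRecord, directory: Path, seed: int | None = None) -> None:
    """One-column CSV plus a JSON sidecar describing the recording."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / record.subject_id
    pd.DataFrame({"amplitude": record.samples}).to_csv(f"{stem}.csv", index=False)
    sidecar = {
        "subject_id": record.subject_id,
        "sampling_rate_hz": record.sampling_rate,
        "duration_s": record.duration,
        "seed": seed,
        "activity_counts": (
            None if record.activity_counts is None else record.activity_counts.tolist()
        ),
    }
    Path(f"{stem}.json").write_text(json.dumps(sidecar, indent=1))


def read_waveform(directory: Path, subject_id: str) -> PPGRecord:
    stem = Path(directory) / subject_id
    csv_path, json_path = Path(f"{stem}.csv"), Path(f"{stem}.json")
    if not csv_path.exists() or not json_path.exists():
        raise MissingArtifactError(f"waveform files not found for {subject_id} in {directory}")
    sidecar = json.loads(json_path.read_text())
    counts = sidecar.get("activity_counts")
    return PPGRecord(
        samples=pd.read_csv(csv_path)["amplitude"].to_numpy(),
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        subject_id=str(sidecar["subject_id"]),
        activity_counts=None if counts is None else np.asarray(counts, dtype=float),
    )


def write_features(table: pd.DataFrame, path: Path) -> None:
    _require_columns(table, FEATURE_COLUMNS, "feature")
    table[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, FEATURE_COLUMNS, "feature")
    return df


def write_predictions(table: pd.DataFrame, path: Path) -> None:
    _require_columns(table, PREDICTION_COLUMNS, "prediction")
    table[PREDICTION_COLUMNS].to_csv(path, index=False)


def read_predictions(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"prediction table not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, PREDICTION_COLUMNS, "prediction")
    return df


def write_bank(bank: ModelBank, directory: Path) -> None:
    """Bank as a JSON directory: manifest plus one model file per cell."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells = []
    for (gender, label), model in sorted(bank.models.items()):
        fname = f"model_g{gender}_{label.replace(' ', '_').replace('<', 'lt').replace('=', 'e')}.json"
        (directory / fname).write_text(json.dumps(gpr.model_to_dict(model)))
        cells.append({"gender": gender, "bin": label, "file": fname})
    manifest = {
        "format_version": BANK_FORMAT_VERSION,
        "target": bank.target,
        "edges": list(bank.scheme.edges),
        "bin_width": bank.scheme.bin_width,
        "cells": cells,
        "provenance": bank.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_bank(directory: Path) -> ModelBank:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise MissingArtifactError(f"bank manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != BANK_FORMAT_VERSION:
        raise FormatVersionError(f"unsupported bank format version {version!r}")
    scheme = AgeBinScheme(edges=tuple(manifest["edges"]), bin_width=manifest.get("bin_width"))
    models = {}
    for cell in manifest["cells"]:
        payload = json.loads((directory / cell["file"]).read_text())
        models[(int(cell["gender"]), cell["bin"])] = gpr.model_from_dict(payload)
    return ModelBank(
        target=manifest["target"],
        scheme=scheme,
        models=models,
        provenance=manifest.get("provenance", {}),
    )


def _stats_to_dict(stats: DeltaBPStats) -> dict:
    return dataclasses.asdict(stats)


def report_to_dict(report: EvalReport) -> dict:
    payload = {
        "stats": _stats_to_dict(report.stats),
        "bhs_per_threshold": list(report.bhs_per_threshold),
        "bhs_grade": report.bhs_grade,
        "aami_pass": report.aami_pass,
        "ba_lower": report.ba_lower,
        "ba_upper": report.ba_upper,
        "pearson_r": report.pearson_r,
        "pearson_p": report.pearson_p,
    }
    if report.subgroups is not None:
        sub = {}
        for key, value in report.subgroups.items():
            if isinstance(value, EvalReport):
                sub[key] = report_to_dict(value)
            else:
                sub[key] = value
        payload["subgroups"] = sub
    return payload


def write_report(payload: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
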