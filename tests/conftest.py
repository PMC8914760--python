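"""Shared fixtures: cohorts, ground-truth feature tables, the full study run.

Heavy artifacts are session-scoped so the suite builds each once: the
validation-scale end-to-end run (435 subjects, 306/129 split, seed 1) is
shared by the acceptance tests, and a fast ground-truth feature table
(analytic features, no waveform synthesis) backs the model-bank and
evaluation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgbp import pipeline
from ppgbp.config import PipelineConfig
from ppgbp.features import FEATURE_NAMES
from ppgbp.synthetic_cohort import (
    SubjectProfile,
    SyntheticConfig,
    ground_truth_features,
    sample_cohort,
)


def ground_truth_table(
    profiles, config: SyntheticConfig, jitter_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Feature table built from the analytic oracle (no waveforms).

    Optionally perturbs the morphology columns with small relative noise
    so regression problems are realistic but cheap to construct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        fv = ground_truth_features(p, config)
        row = {"subject_id": p.subject_id, "window_id": 0}
        row.update({k: getattr(fv, k) for k in FEATURE_NAMES})
        if jitter_sd > 0:
            for k in FEATURE_NAMES[:8]:
                row[k] *= 1.0 + rng.normal(0.0, jitter_sd)
            row["a1_ratio"] = min(max(row["a1_ratio"], 0.05), 0.95)
            row["a2_ratio"] = 1.0 - row["a1_ratio"]  # keep the complement invariant
        row["sbp"] = p.sbp_true
        row["dbp"] = p.dbp_true
        rows.append(row)
    return pd.DataFrame(rows)


def balanced_profiles(per_cell: int, edges, seed: int = 0) -> list[SubjectProfile]:
    """Profiles covering every (gender, age-bin) cell with ``per_cell`` subjects."""
    rng = np.random.default_rng(seed)
    bounds = list(edges) + [95]
    profiles = []
    i = 0
    for gender in (0, 1):
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            for _ in range(per_cell):
                age = int(rng.integers(lo, hi))
                sbp = float(np.clip(105 + 0.45 * (age - 15) + rng.normal(0, 10), 80, 250))
                dbp = float(np.clip(65 + rng.normal(0, 7), 40, sbp - 15))
                profiles.append(
                    SubjectProfile(
                        subject_id=f"B{i:04d}",
                        age=age,
                        gender=gender,
                        sbp_true=round(sbp, 1),
                        dbp_true=round(dbp, 1),
                        heart_rate=float(np.clip(rng.normal(72, 8), 50, 100)),
                    )
                )
                i += 1
    return profiles


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig.with_seed(1)


@pytest.fixture(scope="session")
def e2e_result(default_config):
    """The validation-scale study run: 435 subjects, 306/129 split, seed 1."""
    return pipeline.run_end_to_end(default_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    config = SyntheticConfig(n_subjects=100, seed=3).noise_free()
    return sample_cohort(config), config
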