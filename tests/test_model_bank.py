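"""Age-bin schemes, bank training, feedback calibration."""

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_profiles, ground_truth_table
from ppgbp import gpr, model_bank
from ppgbp.errors import (
    EmptyBankError,
    InvalidConfigError,
    MissingModelError,
    OutOfRangeAgeError,
)
from ppgbp.features import FEATURE_NAMES, FeatureVector
from ppgbp.model_bank import (
    AgeBinScheme,
    assign_group,
    augment_model,
    calibrate_select,
    predict_calibrated,
    predict_uncalibrated,
    train_bank,
)
from ppgbp.synthetic_cohort import SyntheticConfig

FIT = gpr.FitOptions(seed=0, n_restarts=3)
SBP_SCHEME = AgeBinScheme.from_width(30)
DBP_SCHEME = AgeBinScheme.from_width(15)


def _table(per_cell=6, edges=(15, 30, 60), seed=0, jitter=0.01):
    profiles = balanced_profiles(per_cell, edges, seed)
    config = SyntheticConfig(n_subjects=1, seed=1).noise_free()
    return ground_truth_table(profiles, config, jitter_sd=jitter, seed=seed)


def _fv(row) -> FeatureVector:
    return FeatureVector.from_array(row[list(FEATURE_NAMES)].to_numpy(dtype=float))


class TestAgeBinScheme:
    def test_sbp_default_bins(self):
        assert SBP_SCHEME.labels == ("Age < 30", "30 <= Age < 60", "60 <= Age")

    def test_dbp_default_bins(self):
        assert DBP_SCHEME.labels == (
            "Age < 30",
            "30 <= Age < 45",
            "45 <= Age < 60",
            "60 <= Age < 75",
            "75 <= Age",
        )

    def test_no_grouping_is_single_bin(self):
        assert len(AgeBinScheme.from_width(100).labels) == 1

    def test_assign_lower_inclusive(self):
        assert assign_group(25, SBP_SCHEME) == "Age < 30"
        assert assign_group(30, DBP_SCHEME) == "30 <= Age < 45"
        assert assign_group(94, DBP_SCHEME) == "75 <= Age"

    def test_out_of_range_age_rejected(self):
        with pytest.raises(OutOfRangeAgeError):
            assign_group(10, SBP_SCHEME)
        with pytest.raises(OutOfRangeAgeError):
            assign_group(95, SBP_SCHEME)


class TestTrainBank:
    def test_six_sbp_cells(self):
        bank = train_bank(_table(edges=SBP_SCHEME.edges), SBP_SCHEME, "SBP", FIT)
        assert len(bank.models) == 6

    def test_ten_dbp_cells(self):
        table = _table(per_cell=6, edges=DBP_SCHEME.edges)
        bank = train_bank(table, DBP_SCHEME, "DBP", FIT)
        assert len(bank.models) == 10

    def test_single_gender_cohort(self):
        table = _table(edges=SBP_SCHEME.edges)
        table = table[table["gender"] == 1].reset_index(drop=True)
        bank = train_bank(table, SBP_SCHEME, "SBP", FIT)
        assert set(g for g, _ in bank.models) == {1}
        fv = _fv(table.iloc[0])
        with pytest.raises(MissingModelError):
            bank.lookup(0, assign_group(fv.age, SBP_SCHEME))

    def test_undersized_cells_skipped(self):
        table = _table(per_cell=6, edges=SBP_SCHEME.edges)
        keep = ~((table["gender"] == 0) & (table["age"] >= 60))
        thinned = pd.concat(
            [table[keep], table[~keep].head(2)], ignore_index=True
        )
        bank = train_bank(thinned, SBP_SCHEME, "SBP", FIT)
        assert (0, "60 <= Age") not in bank.models
        assert any(c["gender"] == 0 for c in bank.provenance["skipped_cells"])

    def test_empty_bank_rejected(self):
        table = _table(per_cell=2, edges=SBP_SCHEME.edges)
        with pytest.raises(EmptyBankError):
            train_bank(table, SBP_SCHEME, "SBP", FIT, min_cell_size=50)

    def test_order_independent(self):
        table = _table(edges=SBP_SCHEME.edges)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = train_bank(table, SBP_SCHEME, "SBP", FIT)
        b = train_bank(shuffled, SBP_SCHEME, "SBP", FIT)
        for key in a.models:
            assert a.models[key].params == b.models[key].params
            np.testing.assert_array_equal(a.models[key].alpha, b.models[key].alpha)


class TestPrediction:
    def test_constant_target_bank(self):
        table = _table(edges=(15,))
        table["sbp"] = 120.0
        bank = train_bank(table, AgeBinScheme.from_width(100), "SBP", FIT)
        fv = _fv(table.iloc[0])
        assert predict_uncalibrated(bank, fv) == pytest.approx(120.0, abs=0.5)

    def test_deterministic(self):
        table = _table(edges=SBP_SCHEME.edges)
        bank = train_bank(table, SBP_SCHEME, "SBP", FIT)
        fv = _fv(table.iloc[0])
        assert predict_uncalibrated(bank, fv) == predict_uncalibrated(bank, fv)

    def test_finite_error_on_test_split(self):
        table = _table(per_cell=8, edges=SBP_SCHEME.edges)
        subjects = sorted(table["subject_id"].unique())
        held_out = subjects[::8][:6]  # one subject from each of six cells
        train_t = table[~table["subject_id"].isin(held_out)]
        bank = train_bank(train_t, SBP_SCHEME, "SBP", FIT)
        errors = []
        for sid in held_out:
            row = table[table["subject_id"] == sid].iloc[0]
            errors.append(abs(predict_uncalibrated(bank, _fv(row)) - row["sbp"]))
        assert np.isfinite(np.mean(errors))


@pytest.fixture(scope="module")
def table():
    return _table(per_cell=10, edges=SBP_SCHEME.edges, jitter=0.02)


@pytest.fixture(scope="module")
def bank(table):
    return train_bank(table, SBP_SCHEME, "SBP", FIT)


class TestCalibration:

    def test_selected_bin_is_argmin(self, bank, table):
        row = table.iloc[5]
        state = calibrate_select(bank, [_fv(row)], [row["sbp"]], int(row["gender"]))
        assert state.scores[state.selected_bin] == min(state.scores.values())

    def test_single_bin_bank_always_selected(self):
        table = _table(edges=(15,))
        bank = train_bank(table, AgeBinScheme.from_width(100), "SBP", FIT)
        row = table.iloc[0]
        state = calibrate_select(bank, [_fv(row)], [999.0], int(row["gender"]))
        assert state.selected_bin == bank.scheme.labels[0]

    def test_missing_gender_rejected(self, table):
        male_only = table[table["gender"] == 1]
        bank = train_bank(male_only, SBP_SCHEME, "SBP", FIT)
        row = male_only.iloc[0]
        with pytest.raises(MissingModelError):
            calibrate_select(bank, [_fv(row)], [row["sbp"]], gender=0)

    def test_tie_breaks_toward_chronological_then_younger(self, bank, table):
        shared = bank.models[(1, "Age < 30")]
        tied = model_bank.ModelBank(
            target="SBP",
            scheme=SBP_SCHEME,
            models={
                (1, "Age < 30"): shared,
                (1, "30 <= Age < 60"): shared,
                (1, "60 <= Age"): shared,
            },
        )
        row = table[(table["gender"] == 1) & (table["age"] >= 30) & (table["age"] < 60)].iloc[0]
        state = calibrate_select(tied, [_fv(row)], [row["sbp"]], 1)
        assert state.selected_bin == "30 <= Age < 60"  # chronological wins the tie
        two_way = model_bank.ModelBank(
            target="SBP",
            scheme=SBP_SCHEME,
            models={(1, "Age < 30"): shared, (1, "60 <= Age"): shared},
        )
        state = calibrate_select(two_way, [_fv(row)], [row["sbp"]], 1)
        assert state.selected_bin == "Age < 30"  # chronological absent: younger

    def test_empty_calibration_rejected(self, bank):
        with pytest.raises(InvalidConfigError):
            calibrate_select(bank, [], [], 0)


class TestAugmentation:
    def _interp_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 10))
        y = rng.normal(120, 10, size=10)
        std = gpr.Standardizer(np.zeros(10), np.ones(10), 0.0, 1.0)
        params = gpr.KernelParams(sigma_f=10.0, sigma_l=20.0, sigma_n2=1e-12)
        return gpr.GPRModel(training=gpr.TrainingSet(X, y), params=params, standardizer=std)

    def _fv_from(self, arr) -> FeatureVector:
        morph = np.abs(arr[:8])
        morph[0] = 0.4
        morph[1] = 0.6
        return FeatureVector.from_array(np.concatenate([morph, [40.0, 1.0]]))

    def test_calibration_point_interpolated(self):
        model = self._interp_model()
        bank = model_bank.ModelBank(
            target="SBP", scheme=SBP_SCHEME, models={(1, "30 <= Age < 60"): model}
        )
        fv = self._fv_from(np.random.default_rng(1).normal(size=10))
        state = calibrate_select(bank, [fv], [140.0], 1)
        augment_model(state, bank)
        assert predict_calibrated(state, bank, fv) == pytest.approx(140.0, abs=1e-4)

    def test_variance_shrinks_at_calibration_point(self):
        model = self._interp_model()
        bank = model_bank.ModelBank(
            target="SBP", scheme=SBP_SCHEME, models={(1, "30 <= Age < 60"): model}
        )
        fv = self._fv_from(np.random.default_rng(2).normal(size=10))
        _, var_before = gpr.predict(model, fv.to_array())
        state = calibrate_select(bank, [fv], [140.0], 1)
        personal = augment_model(state, bank)
        _, var_after = gpr.predict(personal, fv.to_array())
        assert var_after < var_before

    def test_bank_model_untouched(self):
        model = self._interp_model()
        bank = model_bank.ModelBank(
            target="SBP", scheme=SBP_SCHEME, models={(1, "30 <= Age < 60"): model}
        )
        n_before = bank.models[(1, "30 <= Age < 60")].training.n
        fv = self._fv_from(np.random.default_rng(3).normal(size=10))
        state = calibrate_select(bank, [fv], [140.0], 1)
        augment_model(state, bank)
        assert bank.models[(1, "30 <= Age < 60")].training.n == n_before

    def test_same_bin_without_augmentation_matches_uncalibrated(self):
        table = _table(per_cell=8, edges=SBP_SCHEME.edges)
        bank = train_bank(table, SBP_SCHEME, "SBP", FIT)
        row = table.iloc[0]
        fv = _fv(row)
        state = model_bank.CalibrationState(
            subject_id="x",
            target="SBP",
            selected_bin=assign_group(fv.age, SBP_SCHEME),
            selected_gender=int(row["gender"]),
            calibration_pairs=[(fv, float(row["sbp"]))],
        )
        assert predict_calibrated(state, bank, fv) == pytest.approx(
            predict_uncalibrated(bank, fv), abs=1e-12
        )

    def test_missing_state_is_loud(self):
        table = _table(edges=SBP_SCHEME.edges)
        bank = train_bank(table, SBP_SCHEME, "SBP", FIT)
        with pytest.raises(MissingModelError):
            predict_calibrated(None, bank, _fv(table.iloc[0]))
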