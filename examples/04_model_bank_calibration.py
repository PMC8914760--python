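"""Train gender x age-bin banks and calibrate one subject with a cuff reading.

Demonstrates the feedback-calibration loop: every age-bin model of the
subject's gender predicts the calibration window, the bin with minimal
error against the cuff reference is selected, and the reading is absorbed
into a personal copy of that model.
"""

from ppgbp import (
    PipelineConfig,
    SyntheticConfig,
    augment_model,
    calibrate_select,
    predict_calibrated,
    predict_uncalibrated,
)
from ppgbp.features import FEATURE_NAMES, FeatureVector
from ppgbp.pipeline import build_feature_table, split_subjects, train_banks

config = PipelineConfig.with_seed(
    5,
    synthetic=SyntheticConfig(n_subjects=120, seed=5, duration=60.0),
    n_train=90,
    n_test=30,
)
_, table = build_feature_table(config)
train_table, test_table = split_subjects(table, 90, 30, config.seed)
banks = train_banks(config, train_table)
bank = banks["SBP"]
print(f"SBP bank: {len(bank.models)} (gender, age-bin) models, bins {bank.scheme.labels}")

subject = test_table[test_table.subject_id == sorted(test_table.subject_id.unique())[0]]
calib_row = subject.iloc[0]
fv = FeatureVector.from_array(calib_row[list(FEATURE_NAMES)].to_numpy(dtype=float))
reference = float(calib_row["sbp"])

state = calibrate_select(bank, [fv], [reference], int(calib_row["gender"]))
print(f"cuff reference {reference:.1f} mmHg; per-bin calibration errors:")
for label, score in state.scores.items():
    mark = " <- selected" if label == state.selected_bin else ""
    print(f"  {label:<18} {score:6.2f} mmHg{mark}")
augment_model(state, bank)

print(f"{'window':>6} {'actual':>8} {'uncalibrated':>13} {'calibrated':>11}")
for _, row in subject.iterrows():
    wfv = FeatureVector.from_array(row[list(FEATURE_NAMES)].to_numpy(dtype=float))
    print(
        f"{int(row.window_id):>6} {row.sbp:>8.1f} "
        f"{predict_uncalibrated(bank, wfv):>13.1f} {predict_calibrated(state, bank, wfv):>11.1f}"
    )
# Calibrated predictions hug the subject's actual BP; the uncalibrated ones
# carry the population model's inter-subject spread.
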