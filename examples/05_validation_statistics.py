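"""Grade an estimator with the device-validation statistics.

Uses the printed worked-example numbers of the clinical comparison:
BHS letter grades from cumulative error percentages, the AAMI bound,
and Bland-Altman limits of agreement.
"""

from ppgbp import DeltaBPStats, aami_check, bhs_grade, bland_altman_limits

cases = {
    "SBP without calibration": (37.421, 58.379, 70.974, -0.1809, 10.7177),
    "SBP with calibration": (71.834, 96.382, 99.225, -0.1776, 4.7361),
    "DBP without calibration": (37.936, 63.637, 78.072, 0.5539, 7.8138),
    "DBP with calibration": (60.723, 88.372, 98.191, -0.3846, 6.3688),
}

for name, (c5, c10, c15, mean, sd) in cases.items():
    per, overall = bhs_grade(c5, c10, c15)
    stats = DeltaBPStats(mean=mean, sd=sd, n=516, cum5=c5, cum10=c10, cum15=c15)
    lo, hi = bland_altman_limits(stats)
    verdict = "pass" if aami_check(stats) else "fail"
    print(
        f"{name:<26} BHS {''.join(per)} -> {overall} | AAMI {verdict} "
        f"({mean:+.4f} ± {sd:.4f}) | LoA [{lo:.4f}, {hi:.4f}] mmHg"
    )
# Calibration lifts both targets from grade D / AAMI fail to grade A / pass;
# the limits of agreement reproduce the published Bland-Altman bounds.
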