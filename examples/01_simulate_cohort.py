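"""Generate a small synthetic cohort and inspect its BP distribution.

The generator mirrors a device-validation population: young-skewed ages
15-94, SBP rising with age, DBP peaking near 60 years, and enough
hypo-/hypertensive readings to exercise the distribution tails.
"""

import numpy as np

from ppgbp import SyntheticConfig, sample_cohort

config = SyntheticConfig(n_subjects=300, seed=42)
cohort = sample_cohort(config)

sbp = np.array([p.sbp_true for p in cohort])
dbp = np.array([p.dbp_true for p in cohort])
age = np.array([p.age for p in cohort])

print(f"subjects: {len(cohort)}, ages {age.min()}-{age.max()} (mean {age.mean():.1f})")
print(f"SBP mean {sbp.mean():.1f} mmHg, SD {sbp.std():.1f}")
print(f"fraction SBP <= 100 mmHg: {np.mean(sbp <= 100):.3f} (validation floor 0.05)")
print(f"fraction SBP >= 160 mmHg: {np.mean(sbp >= 160):.3f} (validation floor 0.05)")
for lo in (15, 35, 55, 75):
    mask = (age >= lo) & (age < lo + 20)
    print(
        f"ages {lo}-{lo + 19}: n={mask.sum():3d}  "
        f"SBP {sbp[mask].mean():6.1f}  DBP {dbp[mask].mean():5.1f} mmHg"
    )
# SBP climbs monotonically with the age bins; DBP rises then falls after 60.
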