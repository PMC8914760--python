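# ppgbp — cuffless blood pressure from PPG morphology with feedback calibration

`ppgbp` implements a data-driven blood-pressure estimator for wrist-worn
photoplethysmography (PPG): morphological features of the pulse waveform
feed exponential-kernel Gaussian-process-regression (GPR) models trained
per gender and age group, and a *feedback calibration* step personalises
the estimator from a single reference cuff reading. It is aimed at
biomedical-signal researchers who want a tested, reproducible software
pipeline for PPG-based BP estimation — from raw waveform to
device-validation statistics — without access to a clinical database: a
synthetic cohort generator with known ground truth stands in for the
clinical data, so every stage is verifiable end to end.

## The method

A 15-s pulsatile PPG segment is band-pass filtered (0.5–10 Hz,
zero-phase), delineated foot-to-foot, and summarised by eight
morphological parameters (Fig.-style notation: systolic/diastolic areas
A1, A2, pulse amplitude AC):

A1/(A1+A2), A2/(A1+A2), A1/AC, A2/AC, max slope, systolic time,
diastolic time, mean RR interval — plus age and gender, giving the
10-input feature vector **x**.

BP is modelled as a zero-mean Gaussian process over standardized
features with the exponential kernel

    k(x_i, x_j) = σ_f² · exp( −‖x_i − x_j‖² / σ_l ),

observation noise σ_n², and predictive mean/variance

    f̄(x*) = k(X, x*)ᵀ (K + σ_n² I)⁻¹ y
    V(x*)  = k(x*, x*) − k(X, x*)ᵀ (K + σ_n² I)⁻¹ k(X, x*).

Hyperparameters (log σ_l, log σ_f, log σ_n²) maximise the marginal
likelihood (seeded multi-start L-BFGS-B, analytic gradients). One GPR is
trained per (gender, age-bin) cell: 30-year bins for SBP (<30, 30–60,
≥60) and 15-year bins for DBP (<30, 30–45, 45–60, 60–75, ≥75).

**Feedback calibration**: given one cuff reading, every age-bin model of
the subject's gender predicts the calibration window; the bin with
minimal mean absolute error against the reference is selected (ties break
to the chronological bin), and the reading is absorbed into a personal
copy of that model (hyperparameters frozen, posterior recomputed).
Estimates are graded with the field's device standards: ΔBP = actual −
estimated summaries, BHS letter grades (A: 60/85/95 % within 5/10/15
mmHg), the AAMI bound (|mean| ≤ 5, SD ≤ 8 mmHg), Bland–Altman limits of
agreement, Pearson correlation, Shapiro–Wilk normality, and
hypo-/normo-/hypertension interval breakdowns.

## Worked example

`examples/06_full_study.py` runs the validation-scale study — 435
synthetic subjects, 306 training / 129 validation, seed 1 — and prints:

```
SBP uncalibrated  ΔBP  -1.940 ± 10.890 mmHg | <=5/10/15:  40.5/ 65.3/ 84.1% | BHS D | AAMI fail | r=0.879
SBP calibrated    ΔBP  -1.485 ±  4.724 mmHg | <=5/10/15:  77.3/ 94.0/ 98.4% | BHS A | AAMI pass | r=0.979
DBP uncalibrated  ΔBP  -0.658 ±  6.937 mmHg | <=5/10/15:  50.8/ 83.2/ 97.7% | BHS B | AAMI pass | r=0.786
DBP calibrated    ΔBP  -0.678 ±  2.751 mmHg | <=5/10/15:  87.6/ 99.8/100.0% | BHS A | AAMI pass | r=0.972
age-bin selection recovery on regime-representative subjects: 80%
```

Read: population (uncalibrated) models carry the inter-subject spread
(SBP SD ≈ 11 mmHg, BHS grade D), while one cuff reading per subject cuts
the SD by more than half and lifts both targets to BHS grade A and AAMI
compliance — the with/without-calibration contrast the method is built
around. The last line reports how often model selection identifies the
age group a subject's morphology was generated from.

The other examples are single-capability scripts: cohort simulation
(`01`), waveform → feature extraction (`02`), the GPR core on a toy
problem (`03`), bank training + calibration for one subject (`04`), and
the BHS/AAMI/Bland–Altman graders on published worked-example numbers
(`05`).

A thin CLI mirrors the pipeline for shell use:

```bash
ppgbp simulate --out run/           # cohort + waveforms
ppgbp train    --out run/           # features, split, GPR banks
ppgbp predict  --out run/           # calibrated + uncalibrated predictions
ppgbp evaluate --out run/           # Total + Interval mode report JSON
ppgbp sweep    --out run/           # age-grouping-width sweep
```

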