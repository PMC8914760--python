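# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of `ppgbp`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Problem and pipeline

Cuffless blood-pressure estimation from a single wrist PPG channel:
morphology of the pulse wave carries information about arterial pressure
(steeper systolic upstroke and an earlier, larger reflected wave at
higher pressure and stiffer arteries), but the mapping varies strongly
between subjects and with age. The pipeline therefore (i) extracts
window-averaged morphology features, (ii) trains a *bank* of GP
regressions per gender × age group, and (iii) personalises the estimator
per subject by *feedback calibration* against one reference cuff
reading.

Stages: band-pass filter 0.5–10 Hz → foot-to-foot pulse delineation →
per-pulse morphology → 15-s window averages → 10-input feature vector
(8 morphology values + age + gender) → exponential-kernel GPR →
selection/augmentation against the cuff reference → BHS/AAMI/Bland–
Altman evaluation.

## 2. The regression model

Zero-mean GP over z-scored features with covariance

    k(x_i, x_j) = σ_f² exp(−‖x_i − x_j‖² / σ_l)        (default)
    k(x_i, x_j) = σ_f² exp(−‖x_i − x_j‖ / σ_l)         (distance="euclidean")

The default uses the *squared* distance over a single σ_l — the form the
printed covariance equation specifies even though "exponential kernel"
conventionally means the unsquared distance; both forms are exposed
behind one switch, and an ARD variant (per-feature length scales) is
available. Note σ_l in the default form has units of squared
standardized distance (the equivalent RBF length scale is √(σ_l/2)).

Observation noise is i.i.d. N(0, σ_n²). Fitting maximises the log
marginal likelihood over (θ₁, θ₂, log σ_n²) = (log σ_l, log σ_f,
log σ_n²) with L-BFGS-B, analytic gradients, and 5 seeded starts (one
heuristic start at the median inter-point distance plus 4 uniform
draws). Bounds: θ₁, θ₂ ∈ [−5, 5] (scales in e⁻⁵…e⁵); log σ_n² ∈
[−10, 5] — wider below so near-interpolating solutions (needed when a
personal model absorbs an exact calibration pair) remain reachable.
Cholesky factorisations add an escalating jitter from 1e-10 to 1e-4 of
the mean diagonal before declaring the kernel singular. Predictive
variance is clipped into [0, σ_f²] in standardized space. Features and
the target are z-scored on the training split only; constant columns
(e.g. gender inside a single-gender cell) pass through with unit scale.

**One training row per subject.** `train_bank` averages each subject's
window rows into a single training row before fitting. With several
near-identical windows per subject sharing one cuff target, the marginal
likelihood collapses σ_n² to the within-subject noise level and the
length scale shrinks until the GP memorises subject clusters —
held-out error then equals the cell SD (no cross-subject learning).
Aggregation matches the clinical design (one averaged 15-s reading per
participant in the reference database) and restores sensible
hyperparameters.

## 3. Model bank and feedback calibration

Age bins partition [15, 95): SBP uses 30-year bins (<30, 30–60, ≥60),
DBP 15-year bins (<30, 30–45, 45–60, 60–75, ≥75) — DBP spans a narrower
range, so finer grouping pays off. For a general width *w* the bin
boundaries are the multiples of *w* inside (15, 95), with the last
boundary capped so the top bin spans at least min(w, 20) years; this
reproduces both default schemes and keeps every sweep width distinct
from "no grouping" (width 100 = one bin). Cells with fewer than 5
subjects are skipped and recorded in the bank's provenance; rows are
sorted canonically before fitting, so training is order-independent.

Calibration: all age-bin models of the subject's gender predict the
calibration feature vector(s); the score per bin is the mean absolute
error against the cuff reference(s); the arg-min bin is selected, with
exact ties broken toward the chronological bin and then toward the
younger bin. The selected model is copied, the calibration pairs are
appended to its training set (hyperparameters and standardizer frozen,
posterior recomputed), and all subsequent predictions for that subject
come from the personal copy. The bank itself is never mutated. The
interpretation of the "optimized" calibrated inputs is that reference
readings are absorbed into the personal model — not fed in as runtime
features, which would make the estimator circular.

## 4. Synthetic study conditions

The clinical database (435 participants, ages 15–94, ≥1 min of PPG at
256 Hz each, reference cuff BP) is available only on request, so a
generator emulates it. Defaults are the study conditions and are frozen:

* **Cohort**: n = 435; young-skewed ages on [15, 94] (Beta(1.5, 3.5)
  scaled; mean ≈ 38.5 y, matching the reported cohort mean); male
  fraction 244/435; SBP = 105 + 0.45·(age−15) + 3·male + N(0, 12) mmHg;
  DBP rises 0.25 mmHg/y to a plateau at 60 y then falls 0.20 mmHg/y,
  + 2·male + N(0, 8). A hypotensive component (probability 0.07,
  −|N(18, 6)| SBP) and an age-increasing hypertensive component
  (probability 0.04 + 0.0035·(age−15), +|N(45, 15)| SBP) put ≥5% of
  readings at SBP ≤ 100 and ≥5% at SBP ≥ 160 mmHg, the device-validation
  population requirement; the Gaussian age trend alone leaves the high
  tail under 1%, so the mixture is necessary, and it matches the
  described hypertensive/hypotensive subgroups of the clinical
  database. The diastolic part of the hypertensive offset fades with age
  (isolated systolic hypertension / widening pulse pressure), keeping
  the elderly DBP decline. Heart rate ~ N(72, 8) clipped to [50, 100].
* **Waveform**: each beat is a systolic plus a diastolic Gaussian on a
  strictly periodic train at the profile's heart rate; unit systolic
  amplitude. The *morphology link* maps (SBP, DBP, age, HR) to beat
  shape: higher SBP narrows the systolic Gaussian (steeper upstroke)
  with an age gain exp(0.015·(age−50)) — the coupling roughly doubles
  from the young to the old bin, a stand-in for adult-life arterial
  stiffening; higher DBP raises the diastolic wave amplitude with its
  own age gain exp(0.010·(age−50)); the reflected wave arrives earlier
  with age. All links are monotone and invertible, so the
  feature → BP problem is well-posed (verified by a nearest-neighbour
  injectivity test). Additive white noise (SD 0.02 of the unit pulse)
  and a 0.25 Hz sinusoidal baseline wander (amplitude 0.05) model
  measurement noise and respiration.
* **Inter-subject variability**: each subject carries a fixed morphology
  jitter expressed in BP-equivalent units — the waveform is generated as
  if SBP were offset by N(0, 9) mmHg and DBP by N(0, 7) mmHg, plus a
  small timing jitter. These magnitudes were set so the *uncalibrated*
  population estimator reproduces the reported clinical error level
  (≈ ±11 mmHg SD for SBP), i.e. roughly half the BP variance is
  unexplainable by PPG morphology, which is exactly the gap feedback
  calibration is meant to close. Expressing the jitter in mmHg keeps the
  signal-to-noise ratio uniform across ages (a relative width jitter
  would drown the young cells, whose coupling gain is smallest).
* **Determinism**: one pipeline seed drives cohort sampling, per-subject
  waveform streams (derived via SeedSequence from the seed and a CRC of
  the subject id), the train/test split, and the optimizer restarts;
  identical config + seed gives bit-identical artifacts end to end.

What the generator does **not** emulate: optical skin physics, motion
artifacts beyond a scalar activity count, arrhythmia/ectopic beats,
dicrotic-notch fine structure, BP drift within a recording, and
cuff-measurement error (the reference reading equals true BP). Passing
tests therefore show the *software* recovers what the model family can
express under realistic noise — not that the device would pass a
clinical trial.

## 5. Feature extraction conventions

The systolic/diastolic split point is the systolic peak, not the
dicrotic notch (unreliable on wrist PPG). Areas integrate the pulse
above the straight baseline joining the onset and end amplitudes
(detrending residual wander inside a beat); units are a.u.·s, so A1/AC
and A2/AC carry seconds. AC is peak minus onset amplitude. Gender is
encoded 0 = female, 1 = male; the feature order is fixed and documented
in `FEATURE_NAMES`.

Foot and peak positions are refined to sub-sample precision by parabolic
interpolation through the three neighbouring samples, and the area split
is corrected for the refined peak time. At 256 Hz, raw index arithmetic
leaves up to ~2% quantisation bias on the timing features whenever the
beat period is commensurate with the sampling grid (every beat then
samples the same phase and the error never averages out); with
refinement the extractor agrees with the analytic noise-free oracle to
0.25% worst-case over 100 random profiles. Windows need ≥3 valid pulses;
degenerate pulses (non-positive amplitude or area) are skipped with a
log entry; partial trailing windows are discarded; activity gating is
boundary-inclusive at the threshold.

## 6. Evaluation conventions

ΔBP = actual − estimated (negative ⇒ overestimation). Cumulative
percentages use inclusive thresholds (|ΔBP| ≤ 5 counts toward the 5-mmHg
column); SDs are sample (n−1) throughout. BHS letter grades per column
(A: 60/85/95, B: 50/75/90, C: 40/65/85, D otherwise) with the overall
grade the worst of the three; the AAMI check is inclusive (|mean| ≤ 5
and SD ≤ 8 mmHg). The Bland–Altman reference lines are limits of
agreement, mean ± 1.96·SD — the published figures label them "95% CIs",
but the printed bounds confirm the 1.96·SD formula. Interval mode
partitions by *actual* BP: SBP <90 / 90–129 / ≥130, DBP <60 / 60–79 /
≥80 mmHg. Pearson correlation and Shapiro–Wilk delegate to scipy.stats;
the test suite cross-checks them against an independently coded
product-moment formula and frozen R `shapiro.test` values.

## 7. Study-scale experiments and problem sizes

The validation-scale run (the acceptance script and the end-to-end
tests) uses the full stated conditions — 435 subjects, 60-s records,
306 train / 129 test, one calibration reading per test subject (the
first 15-s window paired with the cuff reference), evaluation over all
four windows of each test subject — and completes in well under a
minute. Unit and property tests use smaller cohorts (tens of subjects,
15–30 s records) and an analytic-feature shortcut (the ground-truth
oracle plus small jitter) where waveform synthesis would add nothing to
the property under test.

The grouping-year sweep retrains banks per width on the training split
and evaluates uncalibrated error on the test split; in our conditions
the best grouped width beats no-grouping on |mean ΔBP|, while the
ungrouped model attains a slightly lower SD (a single cell sees more
subjects, and our age-modulation is smooth enough for one GP to track it
partially) — the bias benefit of grouping reproduces; the SD benefit
depends on how sharply the regimes differ.

**Selection-recovery experiment.** `selection_recovery_rate` draws
regime-representative subjects — age uniform over the central 70% of a
bin, BP at the age/gender trend + N(0, 4), no mixture, no per-subject
jitter — and asks whether one cuff reading selects the generating bin.
The protocol was fixed before measurement: a subject in a mixture tail
or at a bin boundary is not morphologically "from" that bin's regime,
and the selector is designed to find the best-*fitting* regime, not the
chronological label. Measured recovery is ~75–80%, not the ≥95% one
might hope for: under inter-subject noise matched to the reported
uncalibrated accuracy, the GP's posterior uncertainty at a
regime-typical query (~2–5 mmHg) is comparable to the margin between
the generating bin and its neighbour, so failures are near-ties where
an adjacent bin explains the reading essentially as well. End-to-end
calibrated accuracy is unaffected — whichever near-equivalent bin is
selected serves the subject well.

## 8. Known limitations

* The generator's morphology link is a modelling stand-in, not a claim
  about physiology; only its qualitative structure (monotone links,
  age-modulated gains, unexplained inter-subject variability) is
  motivated by the literature.
* Single-reading calibration absorbs a subject-level offset but cannot
  track within-day BP drift; the package deliberately implements no
  re-calibration scheduling.
* Dense GP solves are O(n³); cohort cells here are ≤ a few hundred
  subjects, far below the point where sparse approximations would be
  needed.
* The ARD kernel variant exists behind the same interface but is not
  the default: on cells of this size it overfits (measurably worse
  held-out error and bin identifiability than the single-length-scale
  form).
* Uncalibrated interval-mode subgroups inherit the training imbalance:
  hypo- and hypertensive tails are under-represented, so their errors
  are larger and biased toward the population mean, mirroring the
  clinical report.
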