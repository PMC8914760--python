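"""Synthetic PPG cohort generator with known ground truth.

The clinical database this pipeline was designed for (435 participants,
ages 15–94, reference cuff BP) is not publicly deposited, so every
downstream stage is exercised on a synthetic cohort whose statistical
shape mirrors the study conditions:

* ages span 15–94 years with a young-skewed distribution (cohort mean
  ~38.5 years);
* SBP rises with age (105 + 0.45·(age−15) mmHg trend, SD 12) while DBP
  rises to a plateau near age 60 and falls thereafter;
* hypertensive and hypotensive mixture components keep the distribution
  tails realistic for a device-validation population: at least 5% of
  readings below 100 mmHg SBP and at least 5% at or above 160 mmHg;
* each beat of the waveform is the sum of a systolic and a diastolic
  Gaussian whose widths, relative amplitude and spacing are deterministic
  functions of (SBP, DBP, age, heart rate) — the *morphology link* — so the
  feature -> BP regression problem is well-posed and its ground truth is
  known in closed form.

The morphology link is deliberately age-dependent: the coupling between
SBP and systolic upstroke steepness strengthens with age (a stand-in for
arterial stiffening), which is precisely the inter-subject variability
that motivates training separate models per age group. A per-subject
morphology jitter, independent of BP, emulates the residual
subject-to-subject variability that no population model can explain and
that the feedback-calibration step is meant to absorb.

The generator makes no claim about optical skin physics; amplitudes are
arbitrary units with the AC pulse height near 1.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidConfigError, InvalidProfileError
from .preprocess import DEFAULT_WINDOW_S, PPGRecord

__all__ = [
    "SubjectProfile",
    "MorphologyLink",
    "SyntheticConfig",
    "sample_cohort",
    "synthesize_ppg",
    "ground_truth_features",
    "age_trend_sbp",
    "age_trend_dbp",
    "regime_profile",
]

GENDER_FEMALE = 0
GENDER_MALE = 1


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth description of one synthetic subject."""

    subject_id: str
    age: int
    gender: int
    sbp_true: float
    dbp_true: float
    heart_rate: float

    def __post_init__(self) -> None:
        if not 15 <= self.age <= 94:
            raise InvalidProfileError(f"age {self.age} outside [15, 94]")
        if self.gender not in (GENDER_FEMALE, GENDER_MALE):
            raise InvalidProfileError(f"gender must be 0 or 1, got {self.gender}")
        if not 80 <= self.sbp_true <= 250:
            raise InvalidProfileError(f"sbp {self.sbp_true} outside [80, 250] mmHg")
        if not 40 <= self.dbp_true <= 150:
            raise InvalidProfileError(f"dbp {self.dbp_true} outside [40, 150] mmHg")
        if self.sbp_true <= self.dbp_true:
            raise InvalidProfileError("sbp must exceed dbp")
        if not 40 <= self.heart_rate <= 180:
            raise InvalidProfileError(f"heart rate {self.heart_rate} outside [40, 180]")


@dataclass(frozen=True)
class MorphologyLink:
    """Coefficients mapping (SBP, DBP, age, HR) to two-Gaussian beat shape.

    All timing quantities are fractions of the beat period (RR interval);
    the systolic Gaussian has unit amplitude. Monotone by construction:
    higher SBP narrows the systolic Gaussian (steeper upstroke, larger
    maximal slope); higher DBP raises the diastolic wave's relative
    amplitude; older age strengthens the SBP coupling and advances the
    diastolic wave.
    """

    sys_peak_frac: float = 0.18        # systolic peak position / RR
    sys_width_base: float = 0.075      # systolic Gaussian sigma / RR at SBP 120
    sys_width_per_mmhg: float = 0.0022  # relative narrowing per mmHg above 120
    stiffness_per_year: float = 0.015  # log-slope of the age gain on SBP coupling
    dia_delay_base: float = 0.26       # diastolic-systolic peak spacing / RR
    dia_delay_per_year: float = 0.0012  # earlier reflected wave with age
    dia_amp_base: float = 0.30         # diastolic/systolic amplitude at DBP 70
    dia_amp_per_mmhg: float = 0.0045
    dia_amp_age_gain: float = 0.010    # log-slope of the age gain on DBP coupling
    dia_width: float = 0.14            # diastolic Gaussian sigma / RR

    def stiffness_gain(self, age: float) -> float:
        """Multiplicative age gain on the SBP -> upstroke coupling.

        exp(0.015·(age−50)) spans ~0.6 at age 15 to ~1.9 at 94 — the
        feature->BP map genuinely differs between age groups (the premise
        of age-grouped model banks) while no group's coupling collapses.
        """
        return float(np.exp(self.stiffness_per_year * (age - 50.0)))

    def beat_shape(
        self,
        profile: SubjectProfile,
        sbp_jitter_mmhg: float = 0.0,
        dbp_jitter_mmhg: float = 0.0,
        delay_jitter: float = 0.0,
    ) -> dict[str, float]:
        """Beat-shape parameters in seconds for one subject.

        The jitters are per-subject, BP-independent perturbations entering
        the link as if the subject's BP were offset by that many mmHg
        (see :class:`SyntheticConfig`); zero gives the noise-free regime
        shape used by the ground-truth feature oracle.
        """
        rr = 60.0 / profile.heart_rate
        stiffness = self.stiffness_gain(profile.age)
        sbp_dev = profile.sbp_true + sbp_jitter_mmhg - 120.0
        narrowing = 1.0 - self.sys_width_per_mmhg * stiffness * sbp_dev
        w1 = self.sys_width_base * rr * max(narrowing, 0.25)
        m1 = self.sys_peak_frac * rr
        delay = self.dia_delay_base - self.dia_delay_per_year * (profile.age - 50)
        m2 = m1 + (delay + delay_jitter) * rr
        amp_gain = float(np.exp(self.dia_amp_age_gain * (profile.age - 50.0)))
        dbp_dev = profile.dbp_true + dbp_jitter_mmhg - 70.0
        r = self.dia_amp_base + self.dia_amp_per_mmhg * amp_gain * dbp_dev
        r = float(np.clip(r, 0.10, 0.85))
        return {"rr": rr, "m1": m1, "w1": w1, "m2": m2, "w2": self.dia_width * rr, "r": r}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the validation-cohort conditions: 435 subjects,
    at least 60 s of PPG per subject at 256 Hz, analysis windows of 15 s.
    ``noise_sd`` is additive white measurement noise relative to an AC
    pulse amplitude near 1; ``baseline_wander_amplitude`` drives a slow
    (< 0.4 Hz) respiratory/venous baseline oscillation. The
    ``morph_jitter_*`` terms are per-subject, BP-independent shape
    perturbations emulating inter-subject physiological variability.
    """

    n_subjects: int = 435
    seed: int = 1
    duration: float = 60.0
    sampling_rate: float = 256.0
    noise_sd: float = 0.02
    baseline_wander_amplitude: float = 0.05
    baseline_wander_freq: float = 0.25
    morphology_link: MorphologyLink = field(default_factory=MorphologyLink)
    morph_jitter_sbp_mmhg: float = 9.0
    morph_jitter_dbp_mmhg: float = 7.0
    morph_jitter_delay: float = 0.008
    hypertensive_fraction_base: float = 0.04
    hypertensive_fraction_per_year: float = 0.0035
    hypotensive_fraction: float = 0.07
    male_fraction: float = 244.0 / 435.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.sampling_rate <= 20:
            raise InvalidConfigError("sampling_rate must exceed 20 Hz")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be > 0")
        if self.noise_sd < 0 or self.baseline_wander_amplitude < 0:
            raise InvalidConfigError("noise amplitudes must be >= 0")
        if not 0 < self.baseline_wander_freq < 0.4:
            raise InvalidConfigError("baseline wander must stay below 0.4 Hz")

    def noise_free(self) -> "SyntheticConfig":
        """Copy with all stochastic waveform terms switched off."""
        return replace(
            self,
            noise_sd=0.0,
            baseline_wander_amplitude=0.0,
            morph_jitter_sbp_mmhg=0.0,
            morph_jitter_dbp_mmhg=0.0,
            morph_jitter_delay=0.0,
        )


def age_trend_sbp(age: float, gender: int) -> float:
    """Normotensive SBP trend in mmHg: rises monotonically with age."""
    return 105.0 + 0.45 * (age - 15.0) + 3.0 * gender


def age_trend_dbp(age: float, gender: int) -> float:
    """Normotensive DBP trend: rises to a plateau at 60 y, then declines."""
    if age <= 60:
        base = 62.0 + 0.25 * (age - 15.0)
    else:
        base = 62.0 + 0.25 * 45.0 - 0.20 * (age - 60.0)
    return base + 2.0 * gender


def _sample_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    """Young-skewed ages on [15, 94], mean ~38.7 years."""
    ages = 15 + np.floor(80 * rng.beta(1.5, 3.5, size=n)).astype(int)
    return np.clip(ages, 15, 94)


def sample_cohort(config: SyntheticConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles with ground-truth BP.

    Each subject's BP is the age/gender trend plus N(0, 12) (SBP) or
    N(0, 8) (DBP) scatter; a hypotensive component (probability
    ``hypotensive_fraction``) and an age-increasing hypertensive component
    shift a minority of subjects into the distribution tails required of a
    device-validation population. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    ages = _sample_ages(rng, config.n_subjects)
    genders = (rng.random(config.n_subjects) < config.male_fraction).astype(int)
    profiles: list[SubjectProfile] = []
    for i in range(config.n_subjects):
        age, gender = int(ages[i]), int(genders[i])
        sbp = age_trend_sbp(age, gender) + rng.normal(0.0, 12.0)
        dbp = age_trend_dbp(age, gender) + rng.normal(0.0, 8.0)
        p_hyper = min(
            config.hypertensive_fraction_base
            + config.hypertensive_fraction_per_year * (age - 15.0),
            0.5,
        )
        u = rng.random()
        if u < config.hypotensive_fraction:
            sbp -= abs(rng.normal(18.0, 6.0))
            dbp -= abs(rng.normal(10.0, 4.0))
        elif u < config.hypotensive_fraction + p_hyper:
            sbp += abs(rng.normal(45.0, 15.0))
            # Elderly hypertension is predominantly systolic (widened pulse
            # pressure): the diastolic component of the offset fades with age.
            diastolic_weight = float(np.clip(1.0 - (age - 40.0) / 55.0, 0.1, 1.0))
            dbp += abs(rng.normal(20.0, 8.0)) * diastolic_weight
        sbp = float(np.clip(sbp, 80.0, 250.0))
        dbp = float(np.clip(dbp, 40.0, min(150.0, sbp - 15.0)))
        hr = float(np.clip(rng.normal(72.0, 8.0), 50.0, 100.0))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:04d}",
                age=age,
                gender=gender,
                sbp_true=round(sbp, 1),
                dbp_true=round(dbp, 1),
                heart_rate=round(hr, 1),
            )
        )
    return profiles


def _subject_rng(config: SyntheticConfig, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject RNG derived from config seed and id."""
    tag = zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _subject_jitters(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    # Drawn even when the SDs are zero so the waveform noise stream is
    # unchanged between noisy and noise-free morphology configurations.
    js = rng.normal(0.0, 1.0) * config.morph_jitter_sbp_mmhg
    jd_bp = rng.normal(0.0, 1.0) * config.morph_jitter_dbp_mmhg
    jt = rng.normal(0.0, 1.0) * config.morph_jitter_delay
    return js, jd_bp, jt


def _beat_train(
    t: np.ndarray, shape: dict[str, float], rr: float
) -> np.ndarray:
    """Periodic two-Gaussian pulse train evaluated at times ``t``.

    The signal is exactly periodic with period ``rr``; wrap-around tails
    of neighbouring beats are included so the waveform is smooth at the
    beat boundary.
    """
    phase = np.mod(t, rr)
    out = np.zeros_like(phase)
    for k in (-2, -1, 0, 1, 2):
        tc = phase - k * rr
        out += np.exp(-0.5 * ((tc - shape["m1"]) / shape["w1"]) ** 2)
        out += shape["r"] * np.exp(-0.5 * ((tc - shape["m2"]) / shape["w2"]) ** 2)
    return out


def synthesize_ppg(profile: SubjectProfile, config: SyntheticConfig) -> PPGRecord:
    """Synthesize one subject's raw PPG record.

    Each beat is a systolic plus a diastolic Gaussian with shape set by
    the morphology link (and the subject's fixed jitter draw); the beat
    rate equals the profile heart rate exactly. Additive white noise at
    ``noise_sd`` and a sinusoidal baseline wander below 0.4 Hz complete
    the record. Activity counts are zero (the cohort is recorded at rest).
    """
    rng = _subject_rng(config, profile.subject_id)
    jw, ja, jd = _subject_jitters(config, rng)
    shape = config.morphology_link.beat_shape(profile, jw, ja, jd)
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    x = _beat_train(t, shape, shape["rr"])
    if config.baseline_wander_amplitude > 0:
        phi = rng.uniform(0, 2 * np.pi)
        x = x + config.baseline_wander_amplitude * np.sin(
            2 * np.pi * config.baseline_wander_freq * t + phi
        )
    else:
        rng.uniform(0, 2 * np.pi)  # keep the stream aligned
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=n)
    n_windows = int(n // round(DEFAULT_WINDOW_S * config.sampling_rate))
    return PPGRecord(
        samples=x,
        sampling_rate=config.sampling_rate,
        subject_id=profile.subject_id,
        activity_counts=np.zeros(max(n_windows, 1)),
    )


def ground_truth_features(
    profile: SubjectProfile, config: SyntheticConfig
) -> "FeatureVector":
    """Noise-free oracle for the morphology features of the ideal pulse.

    Evaluates one period of the ideal (jitter- and noise-free) periodic
    pulse on a 16x-oversampled grid, locates the pulse foot and systolic
    peak, and integrates the systolic/diastolic areas against the straight
    baseline between the two feet — the same mathematical definitions the
    feature extractor applies, computed here by direct dense quadrature
    independent of the filtering/segmentation pipeline.
    """
    from .features import FeatureVector  # local import to avoid a cycle

    shape = config.morphology_link.beat_shape(profile)
    rr = shape["rr"]
    fs_fine = 16.0 * config.sampling_rate
    m = int(round(rr * fs_fine))
    phase = np.arange(m) / fs_fine
    x = _beat_train(phase, shape, rr)
    foot = int(np.argmin(x))
    x = np.roll(x, -foot)  # beat now runs foot .. next foot
    peak = int(np.argmax(x))
    baseline = x[0]  # periodic: onset and end amplitude coincide
    corrected = x - baseline
    dt = 1.0 / fs_fine
    # Closed foot-to-foot cycle: append the wrap-around end point.
    cyc = np.concatenate([corrected, corrected[:1]])
    a1 = float(np.trapezoid(cyc[: peak + 1], dx=dt))
    a2 = float(np.trapezoid(cyc[peak:], dx=dt))
    ac = float(x[peak] - baseline)
    slope = float(np.max(np.gradient(x, dt)))
    total = a1 + a2
    return FeatureVector(
        a1_ratio=a1 / total,
        a2_ratio=a2 / total,
        a1_over_ac=a1 / ac,
        a2_over_ac=a2 / ac,
        max_slope=slope,
        systolic_time=peak * dt,
        diastolic_time=(m - peak) * dt,
        mean_rr=rr,
        age=profile.age,
        gender=profile.gender,
    )


def regime_profile(
    rng: np.random.Generator,
    age_range: tuple[int, int],
    gender: int,
    bp_scatter_sd: float = 4.0,
    index: int = 0,
) -> SubjectProfile:
    """A subject drawn representative of one age bin's BP regime.

    Used by selection-recovery experiments: age is uniform over the
    central 70% of the bin, BP sits at the age/gender trend plus a small
    within-regime scatter, and no hypertensive/hypotensive mixture is
    applied — the subject's morphology genuinely belongs to the bin.
    """
    lo, hi = age_range
    span = hi - lo
    a_lo = int(np.ceil(lo + 0.15 * span))
    a_hi = int(np.floor(hi - 0.15 * span))
    age = int(rng.integers(a_lo, a_hi + 1))
    sbp = age_trend_sbp(age, gender) + rng.normal(0.0, bp_scatter_sd)
    dbp = age_trend_dbp(age, gender) + rng.normal(0.0, bp_scatter_sd)
    sbp = float(np.clip(sbp, 80.0, 250.0))
    dbp = float(np.clip(dbp, 40.0, sbp - 15.0))
    hr = float(np.clip(rng.normal(72.0, 8.0), 50.0, 100.0))
    return SubjectProfile(
        subject_id=f"R{index:04d}",
        age=age,
        gender=gender,
        sbp_true=round(sbp, 1),
        dbp_true=round(dbp, 1),
        heart_rate=round(hr, 1),
    )
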