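"""PPG morphology features and the 10-input regression feature vector.

Eight morphological parameters are computed per pulse and averaged over a
15-s analysis window: the systolic and diastolic areas as fractions of the
total pulse area (A1/(A1+A2), A2/(A1+A2)), the same areas normalised by
the pulse amplitude (A1/AC, A2/AC, carrying units of seconds), the maximal
upstroke slope, the systolic and diastolic times, and the mean
peak-to-peak (RR) interval. Age and gender (0 = female, 1 = male) complete
the 10-entry feature vector fed to the regression model.

Conventions
-----------
* The systolic/diastolic split point is the systolic *peak* (not the
  dicrotic notch, which is unreliable on wrist PPG); configurable callers
  can split elsewhere by constructing their own segments.
* Areas are measured against the straight baseline joining the onset and
  end amplitudes, which detrends residual wander inside a beat; units are
  a.u.·s.
* AC is the peak amplitude minus the onset amplitude (a.u.).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DegeneratePulseError,
    InsufficientPulsesError,
    InvalidProfileError,
)
from .preprocess import DEFAULT_WINDOW_S, PPGRecord, PulseSegment

logger = logging.getLogger(__name__)

#: Fixed column order of the 10 regression inputs.
FEATURE_NAMES: tuple[str, ...] = (
    "a1_ratio",
    "a2_ratio",
    "a1_over_ac",
    "a2_over_ac",
    "max_slope",
    "systolic_time",
    "diastolic_time",
    "mean_rr",
    "age",
    "gender",
)

#: Per-pulse morphology keys (mean_rr is a window-level quantity).
PULSE_KEYS: tuple[str, ...] = FEATURE_NAMES[:7]

MIN_PULSES_PER_WINDOW = 3


@dataclass(frozen=True)
class FeatureVector:
    """The 10 regression inputs for one (subject, window)."""

    a1_ratio: float
    a2_ratio: float
    a1_over_ac: float
    a2_over_ac: float
    max_slope: float
    systolic_time: float
    diastolic_time: float
    mean_rr: float
    age: float
    gender: int

    def __post_init__(self) -> None:
        if abs(self.a1_ratio + self.a2_ratio - 1.0) > 1e-9:
            raise InvalidProfileError("a1_ratio + a2_ratio must equal 1")
        for name in ("a1_over_ac", "a2_over_ac", "systolic_time", "diastolic_time", "mean_rr"):
            if getattr(self, name) < 0:
                raise InvalidProfileError(f"{name} must be >= 0")
        if self.gender not in (0, 1):
            raise InvalidProfileError(f"gender must be 0 or 1, got {self.gender}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise InvalidProfileError(
                f"feature vector needs {len(FEATURE_NAMES)} entries, got {values.shape}"
            )
        kwargs = dict(zip(FEATURE_NAMES, values))
        kwargs["gender"] = int(round(kwargs["gender"]))
        return cls(**kwargs)


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of an extremum from three consecutive samples.

    Fits a parabola through (-1, y0), (0, y1), (1, y2); the vertex offset
    is clamped to half a sample. Returns 0 on a degenerate (flat) triple.
    """
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def _refined_extremum(x: np.ndarray, i: int) -> tuple[float, float]:
    """(sub-sample index, interpolated amplitude) of the extremum at ``i``."""
    if 0 < i < x.size - 1:
        d = _parabolic_offset(x[i - 1], x[i], x[i + 1])
        amp = float(x[i] - 0.25 * (x[i - 1] - x[i + 1]) * d)
        return i + d, amp
    return float(i), float(x[i])


def pulse_features(record: PPGRecord, segment: PulseSegment) -> dict[str, float]:
    """The seven per-pulse morphology values for one delineated pulse.

    The foot and peak positions are refined to sub-sample precision by
    parabolic interpolation (the extremum of the quadratic through the
    three neighbouring samples), which removes the quantisation bias that
    sample-grid snapping would otherwise put on the timing features and
    on the systolic/diastolic area split. Areas use the trapezoid rule
    against the straight onset-to-end baseline, with the split corrected
    for the refined peak time.

    Raises :class:`DegeneratePulseError` when the pulse amplitude is
    non-positive or either phase has zero area; callers skip such pulses.
    """
    fs = record.sampling_rate
    x = record.samples
    i0, ip, i1 = segment.onset_index, segment.peak_index, segment.end_index
    if i1 >= x.size:
        raise DegeneratePulseError("segment extends past the record")
    seg = x[i0 : i1 + 1]
    t0, amp0 = _refined_extremum(x, i0)
    tp, amp_p = _refined_extremum(x, ip)
    t1, _ = _refined_extremum(x, i1)
    ac = float(amp_p - amp0)
    if ac <= 0:
        raise DegeneratePulseError(f"non-positive pulse amplitude AC={ac:.3g}")
    baseline = np.linspace(x[i0], x[i1], seg.size)
    corrected = seg - baseline
    p = ip - i0
    dt = 1.0 / fs
    a1 = float(np.trapezoid(corrected[: p + 1], dx=dt))
    a2 = float(np.trapezoid(corrected[p:], dx=dt))
    # Move the sliver between the grid peak and the refined peak time to
    # the correct side of the split (integrand ~ constant near the peak).
    sliver = float(corrected[p]) * (tp - ip) * dt
    a1, a2 = a1 + sliver, a2 - sliver
    if a1 <= 0 or a2 <= 0:
        raise DegeneratePulseError("non-positive systolic or diastolic area")
    total = a1 + a2
    return {
        "a1_ratio": a1 / total,
        "a2_ratio": a2 / total,
        "a1_over_ac": a1 / ac,
        "a2_over_ac": a2 / ac,
        "max_slope": float(np.max(np.diff(seg)) * fs),
        "systolic_time": (tp - t0) * dt,
        "diastolic_time": (t1 - tp) * dt,
    }


def window_features(
    pulse_values: Sequence[dict[str, float]],
    peak_times: Sequence[float],
) -> dict[str, float]:
    """Average per-pulse morphology over one analysis window.

    ``peak_times`` are the systolic-peak times (s) of the window's valid
    pulses; the mean RR interval is the mean of their successive
    differences. Requires at least :data:`MIN_PULSES_PER_WINDOW` pulses.
    """
    if len(pulse_values) < MIN_PULSES_PER_WINDOW:
        raise InsufficientPulsesError(
            f"window holds {len(pulse_values)} valid pulses; need >= {MIN_PULSES_PER_WINDOW}"
        )
    if len(peak_times) != len(pulse_values):
        raise InsufficientPulsesError("peak_times must align with pulse_values")
    out = {k: float(np.mean([pv[k] for pv in pulse_values])) for k in PULSE_KEYS}
    out["mean_rr"] = float(np.mean(np.diff(np.asarray(peak_times, dtype=float))))
    return out


def assemble_feature_vector(morphology: dict[str, float], profile) -> FeatureVector:
    """Append the personal-information inputs to a window's morphology."""
    missing = [k for k in FEATURE_NAMES[:8] if k not in morphology]
    if missing:
        raise InvalidProfileError(f"window morphology missing {missing}")
    age = getattr(profile, "age", None)
    gender = getattr(profile, "gender", None)
    if age is None or gender is None:
        raise InvalidProfileError("profile must provide age and gender")
    if gender not in (0, 1):
        raise InvalidProfileError(f"gender must be 0 or 1, got {gender}")
    return FeatureVector(
        **{k: morphology[k] for k in FEATURE_NAMES[:8]},
        age=float(age),
        gender=int(gender),
    )


def extract_window_features(
    record: PPGRecord,
    segments: Sequence[PulseSegment],
    window_s: float = DEFAULT_WINDOW_S,
    accepted_windows: Optional[Iterable[int]] = None,
) -> dict[int, dict[str, float]]:
    """Window-averaged morphology for every complete analysis window.

    Pulses are assigned to windows by onset index; degenerate pulses and
    windows with fewer than :data:`MIN_PULSES_PER_WINDOW` valid pulses are
    skipped with a log entry. Returns ``{window_id: morphology}``.
    """
    fs = record.sampling_rate
    win_len = int(round(window_s * fs))
    n_win = record.samples.size // win_len
    accepted = set(range(n_win)) if accepted_windows is None else set(accepted_windows)
    per_window: dict[int, list] = {i: [] for i in range(n_win) if i in accepted}
    for seg in segments:
        wid = seg.onset_index // win_len
        if wid not in per_window:
            continue
        try:
            values = pulse_features(record, seg)
        except DegeneratePulseError as exc:
            logger.info("skipping degenerate pulse at %d: %s", seg.onset_index, exc)
            continue
        per_window[wid].append((values, seg.peak_index / fs))
    out: dict[int, dict[str, float]] = {}
    for wid, entries in per_window.items():
        try:
            out[wid] = window_features([v for v, _ in entries], [t for _, t in entries])
        except InsufficientPulsesError as exc:
            logger.info("dropping window %d of %s: %s", wid, record.subject_id, exc)
    return out
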