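"""PPG preprocessing: band-pass filtering, pulse delineation, activity gating.

The wearable pipeline this package models acquires a single-channel
reflective PPG signal, band-pass filters it to the 0.5–10 Hz band that
contains the cardiac pulse (heart rates up to 180 bpm are 3 Hz; harmonics
carrying the pulse shape sit below 10 Hz), delineates individual pulses
foot-to-foot, and rejects analysis windows recorded during motion using a
scalar activity count from the on-board accelerometer.

Filtering is a 4th-order Butterworth applied forward-backward
(zero-phase), so the timing features extracted downstream (systolic /
diastolic time, peak-to-peak intervals) are not shifted by the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

#: Minimum inter-peak distance in seconds (caps detectable rate at 180 bpm).
MIN_PEAK_SPACING_S = 0.33

#: Length of the analysis window, seconds. Pulse features are averaged over
#: this window before entering the regression model.
DEFAULT_WINDOW_S = 15.0


@dataclass
class PPGRecord:
    """A raw or filtered PPG waveform.

    Parameters
    ----------
    samples : ndarray
        Waveform amplitude in arbitrary units.
    sampling_rate : float
        Sampling rate in Hz, > 0.
    subject_id : str
        Identifier linking the record to a subject profile.
    activity_counts : ndarray, optional
        One scalar accelerometer activity count per analysis window,
        aligned 1:1 with consecutive windows of ``DEFAULT_WINDOW_S``.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    activity_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be > 0")
        if self.samples.size == 0:
            raise InvalidConfigError("samples must be non-empty")
        if self.activity_counts is not None:
            self.activity_counts = np.asarray(self.activity_counts, dtype=float)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    def n_windows(self, window_s: float = DEFAULT_WINDOW_S) -> int:
        """Number of complete analysis windows (partial tails discarded)."""
        return int(self.samples.size // round(window_s * self.sampling_rate))


@dataclass(frozen=True)
class PulseSegment:
    """One delineated cardiac pulse: foot -> systolic peak -> next foot."""

    onset_index: int
    peak_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (self.onset_index < self.peak_index < self.end_index):
            raise InvalidConfigError(
                "pulse segment requires onset < peak < end, got "
                f"({self.onset_index}, {self.peak_index}, {self.end_index})"
            )


def bandpass_filter(record: PPGRecord, low: float = 0.5, high: float = 10.0) -> PPGRecord:
    """Zero-phase Butterworth band-pass of a PPG record.

    A 4th-order Butterworth design is applied forward and backward
    (``sosfiltfilt``), giving ~unit passband gain, strong stopband
    attenuation and exactly zero phase shift, so beat timing is preserved.

    Parameters
    ----------
    record : PPGRecord
    low, high : float
        Band edges in Hz; require ``0 < low < high < sampling_rate / 2``.

    Returns
    -------
    PPGRecord
        New record with filtered samples; metadata carried over.
    """
    fs = record.sampling_rate
    if not (0 < low < high < fs / 2):
        raise InvalidConfigError(
            f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}"
        )
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered)


def _smooth(x: np.ndarray, fs: float, width_s: float = 0.04) -> np.ndarray:
    """Moving-average smoothing used only for peak picking."""
    n = max(1, int(round(width_s * fs)))
    if n <= 1:
        return x
    kernel = np.full(n, 1.0 / n)
    return np.convolve(x, kernel, mode="same")


def detect_pulses(record: PPGRecord) -> list[PulseSegment]:
    """Delineate cardiac pulses on a (filtered) PPG record.

    Systolic peaks are located on a lightly smoothed copy of the signal
    with a minimum spacing of :data:`MIN_PEAK_SPACING_S` (<= 180 bpm) and a
    prominence threshold tied to the signal's amplitude range. The pulse
    foot (onset) is the minimum between consecutive peaks; each segment
    runs foot-to-foot, so the first and last partial beats are dropped.

    Returns an empty list when no pulses are detectable (flat signal).
    """
    x = record.samples
    fs = record.sampling_rate
    amplitude_range = float(np.percentile(x, 95) - np.percentile(x, 5))
    if not np.isfinite(amplitude_range) or amplitude_range <= 0:
        return []
    smooth = _smooth(x, fs)
    peaks, _ = _signal.find_peaks(
        smooth,
        distance=max(1, int(round(MIN_PEAK_SPACING_S * fs))),
        prominence=0.25 * amplitude_range,
    )
    if peaks.size < 2:
        return []
    # Feet: raw-signal minimum between consecutive smoothed peaks.
    feet = np.array(
        [p0 + int(np.argmin(x[p0 : p1 + 1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    )
    segments: list[PulseSegment] = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        # Refine the peak on the raw signal inside the beat.
        peak = f0 + int(np.argmax(x[f0 : f1 + 1]))
        if f0 < peak < f1:
            segments.append(PulseSegment(int(f0), int(peak), int(f1)))
    return segments


def gate_by_activity(
    record: PPGRecord,
    threshold: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> list[int]:
    """Indices of analysis windows accepted as motion-free.

    A window is accepted when its activity count is less than or equal to
    ``threshold`` (boundary inclusive). When the record carries no activity
    counts every complete window is accepted and a warning is logged,
    mirroring a device stream without an accelerometer.
    """
    if threshold < 0:
        raise InvalidConfigError("activity threshold must be >= 0")
    n_win = record.n_windows(window_s)
    if record.activity_counts is None:
        logger.warning(
            "record %s has no activity counts; accepting all %d windows",
            record.subject_id,
            n_win,
        )
        return list(range(n_win))
    counts = record.activity_counts[:n_win]
    return [i for i, c in enumerate(counts) if c <= threshold]
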