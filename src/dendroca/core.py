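"""Shared containers for fluorescence time series and behavioral session logs.

Conventions used throughout the package: times are seconds as floats, frame
indices are 0-based, and pixel coordinates are 0-based row-major (row = y,
column = x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceTrace", "BehaviorLog"]


def _as_sorted_times(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite timestamps")
    if arr.size and np.any(arr < 0):
        raise ValueError(f"{name} contains negative timestamps")
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{name} must be sorted ascending")
    return arr


@dataclass
class FluorescenceTrace:
    """A sampled fluorescence time series.

    Parameters
    ----------
    samples:
        Raw fluorescence per frame, arbitrary units.
    frame_rate:
        Sampling rate in Hz (30 for in vivo movies, 500 for line scans).
    channel:
        Free-form channel label, e.g. ``"green"`` or ``"red"``.
    """

    samples: np.ndarray
    frame_rate: float
    channel: str = "green"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame i is sampled at i / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def dff(self, f0: float | None = None, percentile: float = 5.0) -> np.ndarray:
        """Fractional fluorescence change relative to a session baseline.

        By default F0 is the mean of the lowest ``percentile`` percent of the
        session's samples, which is robust to the noise floor dominating a
        single minimum sample.
        """
        if f0 is None:
            f0 = baseline_low_percentile(self.samples, percentile)
        if f0 <= 0:
            raise ValueError("baseline F0 must be positive")
        return self.samples / f0 - 1.0


def baseline_low_percentile(samples: np.ndarray, percentile: float = 5.0) -> float:
    """Mean of the lowest ``percentile`` percent of samples (session F0)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty trace has no baseline")
    k = max(1, int(np.ceil(samples.size * percentile / 100.0)))
    return float(np.mean(np.sort(samples)[:k]))


@dataclass
class BehaviorLog:
    """Cue, water-reward, and lick timestamps for one session (seconds)."""

    cue_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    cue_offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    water_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.cue_onsets = _as_sorted_times(self.cue_onsets, "cue_onsets")
        self.cue_offsets = _as_sorted_times(self.cue_offsets, "cue_offsets")
        self.water_times = _as_sorted_times(self.water_times, "water_times")
        self.lick_times = _as_sorted_times(self.lick_times, "lick_times")
        if self.cue_onsets.size != self.cue_offsets.size:
            raise ValueError("cue_onsets and cue_offsets must pair up")
        if self.cue_onsets.size and np.any(self.cue_offsets < self.cue_onsets):
            raise ValueError("each cue_offset must follow its cue_onset")

    @property
    def n_trials(self) -> int:
        return self.cue_onsets.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BehaviorLog):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("cue_onsets", "cue_offsets", "water_times", "lick_times")
        )
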