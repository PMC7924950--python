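"""Core containers shared across the package.

A recording is a uniformly sampled voltage trace (:class:`TimeSeries`);
segmentations of it into Up and Down epochs live in :class:`IntervalSet`.
Both are thin dataclasses over numpy arrays so every analysis stage can
pass them around without copying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TimeSeries", "IntervalSet"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array of float
        Sample values — membrane potential in mV for intracellular
        channels, arbitrary units for LFP.
    rate_hz : float
        Sampling rate in samples per second.
    start_s : float, default 0
        Time of the first sample, seconds.
    meta : dict
        Free-form channel metadata (units, cell id, region, ...).
    """

    values: np.ndarray
    rate_hz: float
    start_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a non-empty 1-D array")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_s + np.arange(self.values.size) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Nearest sample index for a time, clipped to the trace."""
        i = int(round((t_s - self.start_s) * self.rate_hz))
        return min(max(i, 0), self.values.size - 1)

    def slice_seconds(self, t0_s: float, t1_s: float) -> "TimeSeries":
        """Sub-trace covering [t0_s, t1_s) (half-open, sample-aligned)."""
        i0 = int(round((t0_s - self.start_s) * self.rate_hz))
        i1 = int(round((t1_s - self.start_s) * self.rate_hz))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        if i1 <= i0:
            raise ValueError(f"empty slice [{t0_s}, {t1_s})")
        return TimeSeries(self.values[i0:i1], self.rate_hz,
                          start_s=self.start_s + i0 / self.rate_hz,
                          meta=dict(self.meta))


@dataclass
class IntervalSet:
    """Ordered, non-overlapping labeled intervals in seconds.

    Intervals follow the half-open convention [onset, offset).
    """

    intervals: np.ndarray  # shape (n, 2): onset_s, offset_s
    label: str = "up"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if arr.size:
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("every interval needs onset < offset")
            if np.any(np.diff(arr[:, 0]) <= 0) or np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = arr

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def onsets(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def offsets(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def complement(self, t0_s: float, t1_s: float, label: str = "down") -> "IntervalSet":
        """Gaps between the intervals inside [t0_s, t1_s)."""
        gaps = []
        cursor = t0_s
        for a, b in self.intervals:
            if a > cursor:
                gaps.append((cursor, min(a, t1_s)))
            cursor = max(cursor, b)
        if cursor < t1_s:
            gaps.append((cursor, t1_s))
        gaps = [(a, b) for a, b in gaps if b > a]
        return IntervalSet(np.asarray(gaps, dtype=float).reshape(-1, 2), label=label)

    def membership(self, n_samples: int, rate_hz: float, start_s: float = 0.0) -> np.ndarray:
        """Boolean per-sample mask of interval membership."""
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in self.intervals:
            i0 = max(int(round((a - start_s) * rate_hz)), 0)
            i1 = min(int(round((b - start_s) * rate_hz)), n_samples)
            if i1 > i0:
                mask[i0:i1] = True
        return mask
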