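"""Up/Down state segmentation, pairing and propagation statistics.

The detector reproduces the threshold pipeline used for anesthetized
membrane-potential recordings: smooth the trace with a 200 ms moving
average, threshold at the mean plus 0.5 standard deviations of the
smoothed trace, merge Up fragments separated by less than 250 ms, and
discard Up states shorter than 200 ms.  Because the threshold is
referenced to the trace's own mean, detection is invariant to constant
voltage offsets.

Pairing of Up states across simultaneously recorded channels uses the
500 ms rule: two onsets belong to the same propagating slow-wave cycle
when they are closer than 500 ms in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import IntervalSet, TimeSeries

__all__ = [
    "UpStatePairing",
    "DirectionalStats",
    "smooth_trace",
    "detect_up_states",
    "pair_up_states",
    "propagation_probability",
    "directional_probability",
]

log = logging.getLogger(__name__)


@dataclass
class UpStatePairing:
    """Matched Up-state onsets of two channels.

    ``pairs`` rows are (onset_a_s, onset_b_s, lag_s) with
    lag = onset_b - onset_a; every |lag| is below the pairing window and
    each onset is used at most once.
    """

    pairs: np.ndarray            # shape (n, 3)
    unpaired_a: int
    unpaired_b: int
    window_s: float = 0.5

    @property
    def lags(self) -> np.ndarray:
        return self.pairs[:, 2] if self.pairs.size else np.empty(0)

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class DirectionalStats:
    """Lead/lag summary of a pairing (which channel's Up state comes first)."""

    p_a_leads: float
    mean_lag_a_leads_s: float    # mean |lag| over pairs where A leads; nan if none
    mean_lag_b_leads_s: float
    n_a_leads: int
    n_b_leads: int
    n_ties: int


def smooth_trace(trace: TimeSeries, window_s: float = 0.2) -> TimeSeries:
    """Centered moving average; edges use shrinking windows.

    The default 200 ms window removes fast synaptic fluctuations while
    preserving the slow-wave envelope used for state segmentation.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(trace)
    w = int(round(window_s * trace.rate_hz))
    w = max(w | 1, 1)            # force odd for a centered window
    if w >= n:
        raise ValueError("smoothing window must be shorter than the trace")
    h = w // 2
    c = np.concatenate([[0.0], np.cumsum(trace.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    out = (c[hi] - c[lo]) / (hi - lo)
    return TimeSeries(out, trace.rate_hz, trace.start_s, dict(trace.meta))


def _runs(mask: np.ndarray) -> np.ndarray:
    """Start/stop index pairs (half-open) of True runs."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return np.column_stack([starts, stops])


def detect_up_states(trace: TimeSeries, k_sd: float = 0.5,
                     merge_gap_s: float = 0.25, min_dur_s: float = 0.2,
                     smooth_window_s: float = 0.2) -> IntervalSet:
    """Segment Up states from a membrane-potential trace.

    Pipeline: smooth -> threshold at mean + ``k_sd``*SD of the smoothed
    trace -> merge Up fragments separated by less than ``merge_gap_s``
    -> discard Up states shorter than ``min_dur_s``.  Down states are
    the complement (see :meth:`IntervalSet.complement`).

    A constant trace (zero variance) yields an empty Up set.
    """
    sm = smooth_trace(trace, smooth_window_s)
    mu, sd = sm.values.mean(), sm.values.std()
    if sd == 0:
        log.warning("zero-variance trace: no Up states")
        return IntervalSet(np.empty((0, 2)), label="up")
    mask = sm.values > mu + k_sd * sd
    runs = _runs(mask)
    if runs.size == 0:
        return IntervalSet(np.empty((0, 2)), label="up")

    rate = trace.rate_hz
    merge_gap = int(round(merge_gap_s * rate))
    merged = [runs[0].tolist()]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = int(round(min_dur_s * rate))
    kept = [(a, b) for a, b in merged if b - a >= min_len]
    iv = trace.start_s + np.asarray(kept, dtype=float).reshape(-1, 2) / rate
    return IntervalSet(iv, label="up")


def pair_up_states(onsets_a: np.ndarray, onsets_b: np.ndarray,
                   window_s: float = 0.5) -> UpStatePairing:
    """Greedy nearest-neighbor matching of Up-state onsets.

    Candidate pairs with |lag| below ``window_s`` are accepted smallest
    |lag| first (ties toward the earlier candidate); each onset is used
    at most once.
    """
    a = np.sort(np.asarray(onsets_a, dtype=float))
    b = np.sort(np.asarray(onsets_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return UpStatePairing(np.empty((0, 3)), a.size, b.size, window_s)
    cands = []
    for i, ta in enumerate(a):
        j0 = np.searchsorted(b, ta - window_s)
        j1 = np.searchsorted(b, ta + window_s, side="right")
        for j in range(j0, j1):
            lag = b[j] - ta
            if abs(lag) < window_s:
                cands.append((abs(lag), ta, b[j], i, j))
    cands.sort(key=lambda c: (c[0], c[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, ta, tb, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((ta, tb, tb - ta))
    pairs_arr = np.asarray(sorted(pairs), dtype=float).reshape(-1, 3)
    return UpStatePairing(pairs_arr, a.size - len(pairs), b.size - len(pairs), window_s)


def propagation_probability(cortex_onsets: np.ndarray, msn_onsets: np.ndarray,
                            window_s: float = 0.5) -> float:
    """Probability that a cortical Up state is followed by an MSN Up state.

    Fraction of cortical onsets whose paired MSN onset lags by a strictly
    positive amount within ``window_s``.
    """
    cortex = np.asarray(cortex_onsets, dtype=float)
    if cortex.size == 0:
        raise ValueError("propagation probability undefined without cortical onsets")
    pairing = pair_up_states(cortex, msn_onsets, window_s)
    if len(pairing) == 0:
        return 0.0
    followed = np.sum((pairing.lags > 0) & (pairing.lags <= window_s))
    return float(followed) / cortex.size


def directional_probability(pairing: UpStatePairing) -> DirectionalStats:
    """Lead probability and conditional mean lags of a pairing.

    ``p_a_leads`` is the fraction of (non-tied) pairs where channel A's
    onset precedes channel B's (lag > 0).  Exact ties are counted in
    neither direction and reported separately.
    """
    if len(pairing) == 0:
        raise ValueError("empty pairing")
    lags = pairing.lags
    pos = lags > 0
    neg = lags < 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    n_ties = lags.size - n_pos - n_neg
    if n_pos + n_neg == 0:
        raise ValueError("all lags are ties; direction undefined")
    return DirectionalStats(
        p_a_leads=n_pos / (n_pos + n_neg),
        mean_lag_a_leads_s=float(np.mean(lags[pos])) if n_pos else float("nan"),
        mean_lag_b_leads_s=float(np.mean(-lags[neg])) if n_neg else float("nan"),
        n_a_leads=n_pos, n_b_leads=n_neg, n_ties=n_ties,
    )
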