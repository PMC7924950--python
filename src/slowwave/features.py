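"""Up-state featurization, passive membrane properties and evoked metrics.

Thirteen features summarize each Up state of a (despiked) membrane
potential trace:

==== =========================================================
f1   mean Vm in the Up state (mV)
f2   SD of Vm in the Up state (mV)
f3   minimum Vm in the Up state (mV)
f4   maximum Vm in the Up state (mV)
f5   amplitude: Up mean minus flanking Down mean (mV)
f6   maximum dV/dt inside the Up state (mV/s)
f7   minimum dV/dt inside the Up state (mV/s)
f8   Down-to-Up transition slope (mV/s, magnitude)
f9   Up-to-Down transition slope (mV/s, magnitude)
f10  slope transition ratio f8/f9
f11  number of peaks in the Up state (count)
f12  peak-to-peak distance f4 - f3 (mV)
f13  Up-state length (s)
==== =========================================================

Peaks (f11) are local maxima of the 200 ms-smoothed Up segment at least
0.3 segment-SDs above the segment mean and at least 160 ms apart.
Transition slopes (f8/f9) are measured in a -100..+200 ms window around
the transition: the window is smoothed (100 ms), its derivative is
thresholded at mean + 0.3 SD (of the absolute derivative) to delimit the
transition, and a least-squares line is fitted to the raw voltage over
the delimited region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .core import IntervalSet, TimeSeries
from .emd import ImfDecomposition, hilbert_analytic, _median_inst_freq
from .states import smooth_trace

__all__ = [
    "FEATURE_NAMES",
    "PassiveProperties",
    "EvokedResponse",
    "remove_spikes",
    "compute_up_features",
    "count_up_peaks",
    "transition_slope",
    "aggregate_cohort",
    "passive_properties",
    "evoked_response_metrics",
    "intrinsic_feature_correlation",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "f1_mean_up_mv", "f2_sd_up_mv", "f3_min_up_mv", "f4_max_up_mv",
    "f5_amplitude_mv", "f6_max_dvdt_mv_per_s", "f7_min_dvdt_mv_per_s",
    "f8_down_up_slope_mv_per_s", "f9_up_down_slope_mv_per_s",
    "f10_slope_ratio", "f11_n_peaks", "f12_peak_to_peak_mv",
    "f13_up_length_s",
]


@dataclass
class PassiveProperties:
    """Input resistance, membrane time constant and capacitance."""

    r_in_mohm: float
    tau_ms: float
    c_pf: float


@dataclass
class EvokedResponse:
    """Trial-averaged evoked-response metrics (onset relative to trigger)."""

    onset_ms: float
    amplitude_mv: float
    slope_mv_per_s: float
    n_trials: int
    responder: bool = True


def remove_spikes(trace: TimeSeries, decomposition: ImfDecomposition,
                  cutoff_hz: float = 50.0, channel: int = 0) -> TimeSeries:
    """Subtract IMFs faster than ``cutoff_hz`` to eliminate spikes.

    An IMF is removed when the median Hilbert instantaneous frequency of
    that mode exceeds the cutoff.  If no IMF is that fast the input is
    returned unchanged (logged).
    """
    fast = []
    for k in range(decomposition.n_imfs):
        if _median_inst_freq(decomposition.imfs[channel, k], decomposition.rate_hz) > cutoff_hz:
            fast.append(k)
    if not fast:
        log.info("no IMF above %.0f Hz: trace returned unchanged", cutoff_hz)
        return trace
    out = trace.values - decomposition.imfs[channel, fast].sum(axis=0)
    return TimeSeries(out, trace.rate_hz, trace.start_s, dict(trace.meta))


def count_up_peaks(up_segment: np.ndarray | TimeSeries, rate_hz: float | None = None,
                   min_height_sd: float = 0.3, min_separation_s: float = 0.16,
                   smooth_window_s: float = 0.2) -> int:
    """Count slow peaks inside one Up-state segment.

    Local maxima of the smoothed segment at least ``min_height_sd``
    segment-SDs above the segment mean and ``min_separation_s`` apart;
    when two candidates are closer, the higher one survives.
    """
    if isinstance(up_segment, TimeSeries):
        rate_hz = up_segment.rate_hz
        x = up_segment.values
    else:
        x = np.asarray(up_segment, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for array input")
    if x.size < 2:
        return 0
    w = max(int(round(smooth_window_s * rate_hz)) | 1, 1)
    if w >= x.size:
        w = (x.size - 1) | 1
    sm = smooth_trace(TimeSeries(x, rate_hz), w / rate_hz).values if w > 1 else x.copy()
    sd = sm.std()
    if sd == 0:
        return 0
    height = sm.mean() + min_height_sd * sd
    distance = max(int(round(min_separation_s * rate_hz)), 1)
    peaks, _ = find_peaks(sm, height=height, distance=distance)
    return int(peaks.size)


def transition_slope(trace: TimeSeries, transition_time_s: float, direction: str,
                     window_s: tuple[float, float] = (-0.1, 0.2),
                     smooth_s: float = 0.1, k_sd: float = 0.3) -> float:
    """Slope of one Down/Up transition, mV/s.

    The -100..+200 ms window around the transition is smoothed, its
    derivative thresholded at mean + ``k_sd`` SD (absolute value) to
    delimit the transition region, and a least-squares line is fitted to
    the raw voltage over that region.  Returns a signed slope: positive
    for ``down_up``, negative for ``up_down``.

    Raises ``ValueError`` when no supra-threshold region exists (the
    state is then excluded from slope features by the caller).
    """
    if direction not in ("down_up", "up_down"):
        raise ValueError("direction must be 'down_up' or 'up_down'")
    t0 = transition_time_s + window_s[0]
    t1 = transition_time_s + window_s[1]
    if t0 < trace.start_s or t1 > trace.end_s:
        raise ValueError("transition window outside the trace")
    seg = trace.slice_seconds(t0, t1)
    sm = smooth_trace(seg, min(smooth_s, (len(seg) - 2) / seg.rate_hz))
    dv = np.gradient(sm.values) * seg.rate_hz
    mag = np.abs(dv)
    thr = mag.mean() + k_sd * mag.std()
    mask = mag > thr
    if not mask.any():
        raise ValueError("no supra-threshold derivative region at this transition")
    # the transition is the run with the largest integrated |dV|
    d = np.diff(mask.astype(np.int8))
    starts = np.r_[0, np.where(d == 1)[0] + 1] if mask[0] else np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    best, best_area = None, -1.0
    for a, b in zip(starts, stops):
        area = mag[a:b].sum()
        if area > best_area:
            best, best_area = (a, b), area
    a, b = best
    if b - a < 2:
        raise ValueError("transition region too short for a line fit")
    tt = np.arange(a, b) / seg.rate_hz
    slope = float(np.polyfit(tt, seg.values[a:b], 1)[0])
    return slope


def compute_up_features(trace_despiked: TimeSeries, up_intervals: IntervalSet,
                        down_intervals: IntervalSet | None = None) -> pd.DataFrame:
    """Compute the 13 Up-state features, one row per Up state.

    ``trace_despiked`` should have spikes removed (see
    :func:`remove_spikes`) when spiking contaminates the recording.
    f5 uses the mean of the two flanking Down states; Up states without
    a flanking Down fall back to the global Down mean (flagged in the
    ``f5_flagged`` column).  Slope failures leave f8/f9/f10 as NaN.
    """
    if down_intervals is None:
        down_intervals = up_intervals.complement(trace_despiked.start_s,
                                                 trace_despiked.end_s)
    rate = trace_despiked.rate_hz
    x = trace_despiked.values
    start = trace_despiked.start_s

    down_means = []
    for a, b in down_intervals:
        i0, i1 = int(round((a - start) * rate)), int(round((b - start) * rate))
        down_means.append(x[max(i0, 0):min(i1, x.size)].mean() if i1 > i0 else np.nan)
    down_iv = down_intervals.intervals
    global_down = float(np.nanmean(down_means)) if down_means else np.nan

    dvdt = np.gradient(x) * rate   # central difference at native rate

    rows = []
    for a, b in up_intervals:
        i0, i1 = int(round((a - start) * rate)), int(round((b - start) * rate))
        seg = x[max(i0, 0):min(i1, x.size)]
        if seg.size < 2:
            continue
        f1, f2 = float(seg.mean()), float(seg.std())
        f3, f4 = float(seg.min()), float(seg.max())
        dseg = dvdt[max(i0, 0):min(i1, x.size)]
        f6, f7 = float(dseg.max()), float(dseg.min())
        f13 = b - a
        f11 = count_up_peaks(seg, rate)
        f12 = f4 - f3

        # flanking Down means for f5
        prev = [m for (da, db), m in zip(down_iv, down_means) if db <= a + 1e-9]
        nxt = [m for (da, db), m in zip(down_iv, down_means) if da >= b - 1e-9]
        flank = ([prev[-1]] if prev else []) + ([nxt[0]] if nxt else [])
        flagged = len(flank) < 2
        ref = float(np.mean(flank)) if flank else global_down
        f5 = f1 - ref

        try:
            f8 = abs(transition_slope(trace_despiked, a, "down_up"))
        except ValueError:
            f8 = np.nan
        try:
            f9 = abs(transition_slope(trace_despiked, b, "up_down"))
        except ValueError:
            f9 = np.nan
        f10 = f8 / f9 if np.isfinite(f8) and np.isfinite(f9) and f9 != 0 else np.nan

        rows.append({"onset_s": a, "offset_s": b,
                     "f1_mean_up_mv": f1, "f2_sd_up_mv": f2, "f3_min_up_mv": f3,
                     "f4_max_up_mv": f4, "f5_amplitude_mv": f5,
                     "f6_max_dvdt_mv_per_s": f6, "f7_min_dvdt_mv_per_s": f7,
                     "f8_down_up_slope_mv_per_s": f8, "f9_up_down_slope_mv_per_s": f9,
                     "f10_slope_ratio": f10, "f11_n_peaks": f11,
                     "f12_peak_to_peak_mv": f12, "f13_up_length_s": f13,
                     "f5_flagged": flagged})
    return pd.DataFrame(rows)


def aggregate_cohort(per_state_tables: dict[str, pd.DataFrame],
                     labels: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean feature vectors with cohort labels.

    ``per_state_tables`` maps cell_id to the per-state feature table of
    that cell; ``labels`` carries cell_id, animal_id, region, pathway.
    Cells without Up states are dropped.
    """
    rows = []
    for cell_id, table in per_state_tables.items():
        if table.empty:
            log.warning("cell %s has no Up states; dropped", cell_id)
            continue
        means = table[FEATURE_NAMES].mean(skipna=True)
        rows.append({"cell_id": cell_id, **means.to_dict(),
                     "n_up_states": len(table)})
    feats = pd.DataFrame(rows)
    return labels.merge(feats, on="cell_id", how="inner")


def passive_properties(protocol) -> PassiveProperties:
    """Passive membrane properties from a current-step protocol.

    Input resistance is the regression slope of the steady-state voltage
    deflection on injected current; the membrane time constant is the
    time to reach 63% of the voltage increment; capacitance is tau
    divided by the input resistance.
    """
    steps = protocol.steps
    if len({i for i, _ in steps}) < 2:
        raise ValueError("need at least 2 distinct step amplitudes")
    on = protocol.step_onset_s
    dur = protocol.step_duration_s
    currents, deflections, taus = [], [], []
    for i_pa, ts in steps:
        rate = ts.rate_hz
        i_on = int(round((on - ts.start_s) * rate))
        i_off = int(round((on + dur - ts.start_s) * rate))
        base = ts.values[:i_on].mean()
        tail0 = i_off - max(int(round(0.2 * dur * rate)), 1)
        vss = ts.values[tail0:i_off].mean()
        dv = vss - base
        currents.append(i_pa)
        deflections.append(dv)
        if abs(dv) > 1e-9:
            target = base + 0.632 * dv
            seg = ts.values[i_on:i_off]
            crossed = np.where((seg - target) * np.sign(dv) >= 0)[0]
            if crossed.size:
                k = crossed[0]
                if k > 0:  # linear interpolation between samples
                    v0, v1 = seg[k - 1], seg[k]
                    frac = (target - v0) / (v1 - v0) if v1 != v0 else 0.0
                    taus.append((k - 1 + frac) / rate)
                else:
                    taus.append(0.0)
    res = linregress(currents, deflections)
    r_mohm = res.slope * 1e3           # mV/pA = GOhm -> MOhm
    if r_mohm <= 0:
        raise ValueError("non-positive fitted input resistance")
    if not taus:
        raise ValueError("no usable step for the time constant")
    tau_ms = float(np.median(taus)) * 1e3
    c_pf = tau_ms / r_mohm * 1e3       # ms / MOhm = nF -> pF
    return PassiveProperties(float(r_mohm), tau_ms, float(c_pf))


def evoked_response_metrics(trials: np.ndarray, t_axis: np.ndarray,
                            trigger_time_s: float = 0.0,
                            baseline_window_s: float | tuple[float, float] = None,
                            k_sd: float = 2.0,
                            sustain_s: float = 0.010) -> EvokedResponse:
    """Onset, amplitude and slope of a trial-averaged evoked response.

    The trial average must exceed baseline mean + ``k_sd`` baseline SDs
    and stay above for ``sustain_s`` to count as a response; onset is
    the first such crossing after the trigger.  Amplitude is the peak of
    the average minus the baseline mean; slope is a line fit from onset
    to peak.  If the average never crosses, a non-responder result is
    returned.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 1:
        raise ValueError("need at least one trial")
    avg = trials.mean(axis=0)
    rate = 1.0 / (t_axis[1] - t_axis[0])
    if baseline_window_s is None:
        baseline_window_s = (t_axis[0], trigger_time_s)
    b0, b1 = baseline_window_s
    bmask = (t_axis >= b0) & (t_axis < b1)
    if b1 <= b0 or not bmask.any():
        # trigger at the first sample: use the pre-onset plateau heuristically
        bmask = t_axis < t_axis[0] + max(0.02, 5 / rate)
    base_mu, base_sd = avg[bmask].mean(), avg[bmask].std()
    thr = base_mu + k_sd * max(base_sd, 1e-12)
    post = t_axis >= trigger_time_s
    above = (avg > thr) & post
    need = max(int(round(sustain_s * rate)), 1)
    onset_idx = None
    runs = np.where(above)[0]
    if runs.size:
        # first index from which `need` consecutive samples stay above
        run_start = None
        count = 0
        for i in range(above.size):
            if above[i]:
                if run_start is None:
                    run_start = i
                count += 1
                if count >= need:
                    onset_idx = run_start
                    break
            else:
                run_start, count = None, 0
    if onset_idx is None:
        return EvokedResponse(float("nan"), 0.0, float("nan"),
                              trials.shape[0], responder=False)
    peak_idx = onset_idx + int(np.argmax(avg[onset_idx:]))
    amplitude = float(avg[peak_idx] - base_mu)
    onset_ms = (t_axis[onset_idx] - trigger_time_s) * 1e3
    if peak_idx > onset_idx + 1:
        slope = float(np.polyfit(t_axis[onset_idx:peak_idx + 1],
                                 avg[onset_idx:peak_idx + 1], 1)[0])
    else:
        slope = float("nan")
    return EvokedResponse(float(onset_ms), amplitude, slope, trials.shape[0])


def intrinsic_feature_correlation(cohort: pd.DataFrame,
                                  intrinsic: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of intrinsic properties with Up-state features.

    ``cohort`` must carry cell_id and the 13 feature columns; ``intrinsic``
    carries cell_id plus one column per intrinsic property.  Returns a
    (properties x features) correlation matrix.
    """
    merged = cohort.merge(intrinsic, on="cell_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched cells")
    props = [c for c in intrinsic.columns if c != "cell_id"]
    out = pd.DataFrame(index=props, columns=FEATURE_NAMES, dtype=float)
    for p in props:
        for f in FEATURE_NAMES:
            out.loc[p, f] = merged[p].corr(merged[f])
    return out
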