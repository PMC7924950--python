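"""Ground-truthed surrogate recordings.

Generates membrane-potential traces with the statistical structure the
analysis stages assume: a bimodal two-state (Up/Down) alternation at a
target slow-wave frequency, piecewise-linear (optionally sigmoidal)
transitions, raised-cosine intra-Up "peaks", band-limited oscillatory
bursts locked to a slow-wave phase, sharp synaptic-like depolarizing and
hyperpolarizing events, optional spike contamination, RC step responses
and evoked-response trials.  Every generator records its ground truth so
detector and featurizer output can be scored without external data.

The Up/Down alternation is modeled as a two-state semi-Markov process
with truncated-Gaussian state durations.  Ground-truth interval onsets
and offsets use the ramp-midpoint convention: the state boundary is the
time at which the transition ramp crosses 50% of its amplitude.

The ground-truth slow-wave phase is the Hilbert phase of the
mean-subtracted noise-free skeleton (0 degrees at the depolarized peak),
which is the quantity the NA-MEMD pipeline recovers from the full trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert as _hilbert
from scipy.signal.windows import tukey

from .core import IntervalSet, TimeSeries

__all__ = [
    "SynthParams",
    "SynthGroundTruth",
    "BandBurst",
    "StepProtocol",
    "generate_trace",
    "generate_paired_traces",
    "generate_cohort",
    "generate_rc_response",
    "generate_evoked_trials",
    "DLS_LIKE_SPEC",
    "DMS_LIKE_SPEC",
]

log = logging.getLogger(__name__)

MIN_UP_DURATION_S = 0.2
MIN_BUMP_SPACING_S = 0.16


@dataclass
class BandBurst:
    """One oscillatory burst injected per Up state.

    ``locked_phase_deg`` is the slow-wave phase (0 at the depolarized
    peak) at which the burst is centered; ``phase_jitter_deg`` is the
    circular SD of a von Mises jitter on that target.
    """

    band_low_hz: float
    band_high_hz: float
    burst_amplitude_mv: float
    locked_phase_deg: float
    phase_jitter_deg: float = 0.0

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.band_low_hz + self.band_high_hz)


@dataclass
class SynthParams:
    """Parameters of the surrogate recording generator.

    Defaults emulate anesthetized corticostriatal recordings: a ~0.7 Hz
    slow-wave alternation between a quiescent Down state near -70 mV and
    a depolarized Up state ~22 mV above it, a few slow intra-Up peaks,
    and ~1 mV instrument/background noise.  The default 1 kHz sampling
    rate keeps tests fast; 20 kHz mimics acquisition.
    """

    rate_hz: float = 1000.0
    duration_s: float = 60.0
    swo_freq_hz: float = 0.7
    down_mean_mv: float = -70.0
    up_amplitude_mv: float = 22.0
    up_sd_mv: float = 0.8                 # slow within-Up fluctuation
    up_duration_s: tuple[float, float] = (0.4, 0.05)   # mean, jitter SD
    down_up_slope_mv_per_s: float = 250.0
    up_down_slope_mv_per_s: float = 150.0
    n_peaks_per_up: tuple[float, float] = (1.0, 0.0)   # mean, dispersion
    bump_height_mv: float = 4.0
    bump_width_s: float = 0.15
    band_bursts: list[BandBurst] = field(default_factory=list)
    event_rates: dict[str, tuple[float, float, float]] | None = None
    #   polarity -> (mean rate Hz, preferred phase deg, von Mises kappa)
    event_amplitude_mv: float = 3.0
    noise_sd_mv: float = 1.0
    spike_rate_hz: float = 0.0
    transition_shape: str = "linear"      # or "sigmoid"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.band_bursts:
            top = max(b.band_high_hz for b in self.band_bursts)
            if self.rate_hz <= 2 * top:
                raise ValueError("rate_hz must exceed twice the highest band frequency")
        if self.up_duration_s[0] < MIN_UP_DURATION_S:
            raise ValueError(f"mean Up duration must be >= {MIN_UP_DURATION_S} s")
        for name in ("up_amplitude_mv", "up_sd_mv", "bump_height_mv",
                     "noise_sd_mv", "event_amplitude_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transition_shape not in ("linear", "sigmoid"):
            raise ValueError("transition_shape must be 'linear' or 'sigmoid'")


@dataclass
class SynthGroundTruth:
    """Everything the generator knows about a trace."""

    true_intervals: IntervalSet
    bump_times_s: list[np.ndarray] = field(default_factory=list)   # per Up state
    true_event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_polarities: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    true_band_phase_deg: dict[float, np.ndarray] = field(default_factory=dict)
    #   band center Hz -> realized burst center phases per Up state
    spike_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_pair_lag_s: np.ndarray | None = None
    true_region_label: str | None = None
    true_phase_rad: np.ndarray | None = None   # skeleton Hilbert phase per sample
    true_feature_values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------

def _draw_state_durations(params: SynthParams, rng: np.random.Generator
                          ) -> list[tuple[float, float]]:
    """Alternating (onset, offset) Up intervals covering the trace."""
    cycle = 1.0 / params.swo_freq_hz
    up_mean, up_sd = params.up_duration_s
    down_mean = cycle - up_mean
    if down_mean <= 0.15:
        raise ValueError("swo_freq_hz and up_duration_s leave no room for Down states")
    if params.duration_s < cycle + up_mean:
        raise ValueError("duration too short to contain one full slow-wave cycle")
    down_sd = up_sd * down_mean / max(up_mean, 1e-9)

    def trunc(mean: float, sd: float, lo: float) -> float:
        if sd == 0:
            return mean
        for _ in range(100):
            d = rng.normal(mean, sd)
            if d >= lo:
                return d
        return lo

    intervals = []
    t = trunc(down_mean / 2, down_sd / 2, 0.1)  # start mid-Down
    while True:
        up = trunc(up_mean, up_sd, MIN_UP_DURATION_S)
        if t + up > params.duration_s - 0.1:
            break
        intervals.append((t, t + up))
        t += up + trunc(down_mean, down_sd, 0.15)
    if not intervals:
        raise ValueError("duration too short to contain one full slow-wave cycle")
    return intervals


def _skeleton(params: SynthParams, intervals: list[tuple[float, float]],
              n: int) -> np.ndarray:
    """Two-state waveform with ramped transitions (ramp-midpoint onsets)."""
    up_level = params.down_mean_mv + params.up_amplitude_mv
    r_up = params.up_amplitude_mv / params.down_up_slope_mv_per_s
    r_dn = params.up_amplitude_mv / params.up_down_slope_mv_per_s
    t = np.arange(n) / params.rate_hz
    knots_t = [0.0]
    knots_v = [params.down_mean_mv]
    for a, b in intervals:
        knots_t += [a - r_up / 2, a + r_up / 2, b - r_dn / 2, b + r_dn / 2]
        knots_v += [params.down_mean_mv, up_level, up_level, params.down_mean_mv]
    knots_t.append(t[-1] + 1.0)
    knots_v.append(params.down_mean_mv)
    kt = np.asarray(knots_t)
    if np.any(np.diff(kt) <= 0):
        raise ValueError("up/down durations too short for the requested ramp slopes")
    x = np.interp(t, kt, np.asarray(knots_v))
    if params.transition_shape == "sigmoid":
        # smooth each linear ramp into a raised-cosine step of equal extent
        for a, b in intervals:
            for t0, t1 in ((a - r_up / 2, a + r_up / 2), (b - r_dn / 2, b + r_dn / 2)):
                i0, i1 = int(round(t0 * params.rate_hz)), int(round(t1 * params.rate_hz))
                i0, i1 = max(i0, 0), min(i1, n)
                if i1 - i0 < 2:
                    continue
                u = (np.arange(i1 - i0)) / (i1 - i0 - 1)
                v0, v1 = x[i0], x[i1 - 1]
                x[i0:i1] = v0 + (v1 - v0) * 0.5 * (1 - np.cos(np.pi * u))
    return x


def _place_bumps(params: SynthParams, intervals: list[tuple[float, float]],
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Raised-cosine bump centers, spacing >= MIN_BUMP_SPACING_S."""
    mean, disp = params.n_peaks_per_up
    out = []
    for a, b in intervals:
        # dispersion = SD of a rounded-normal count (0 -> deterministic)
        k = int(round(rng.normal(mean, disp))) if disp > 0 else int(round(mean))
        k = max(k, 0)
        # keep bump centers clear of the transition ramps so the 200 ms
        # segment smoothing can resolve them as local maxima
        margin = params.bump_width_s / 2 + 0.08
        lo = a + margin
        hi = b - margin
        span = hi - lo
        if span <= 0:
            out.append(np.empty(0))
            continue
        k_max = int(np.floor(span / MIN_BUMP_SPACING_S)) + 1
        k = min(k, k_max)
        if k <= 0:
            out.append(np.empty(0))
            continue
        if k == 1:
            centers = np.array([lo + span * rng.uniform(0.3, 0.7)])
        else:
            spacing = span / (k - 1)
            centers = lo + spacing * np.arange(k)
            jitter = min(0.4 * (spacing - MIN_BUMP_SPACING_S), 0.03)
            if jitter > 0:
                centers = centers + rng.uniform(-jitter, jitter, size=k)
        out.append(centers)
    return out


def _add_bumps(x: np.ndarray, centers: Sequence[float], height: float,
               width: float, rate: float) -> None:
    half = int(round(width / 2 * rate))
    for c in centers:
        ic = int(round(c * rate))
        i0, i1 = max(ic - half, 0), min(ic + half + 1, x.size)
        u = (np.arange(i0, i1) - ic) / max(half, 1)
        x[i0:i1] += height * 0.5 * (1 + np.cos(np.pi * np.clip(u, -1, 1)))


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _kappa_from_sd_deg(sd_deg: float) -> float:
    if sd_deg <= 0:
        return np.inf
    sd_rad = np.radians(sd_deg)
    return 1.0 / (sd_rad * sd_rad)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_trace(params: SynthParams) -> tuple[TimeSeries, SynthGroundTruth]:
    """Generate one surrogate membrane-potential trace with ground truth.

    The trace alternates Down and Up epochs with ramped transitions at
    the requested slopes, carries the requested number of intra-Up
    raised-cosine peaks (>= 160 ms apart), phase-locked band bursts,
    synaptic-like events, optional spikes, and additive Gaussian noise.
    Fully reproducible for a given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    rate = params.rate_hz

    intervals = _draw_state_durations(params, rng)
    x = _skeleton(params, intervals, n)
    phase = np.angle(_hilbert(x - x.mean()))

    # Expected f5 under the ramp-midpoint interval convention: the half
    # ramps inside the Up interval dilute the Up mean by amp/4 weighted by
    # their share of the state, and symmetrically raise the Down mean.
    r_up = params.up_amplitude_mv / params.down_up_slope_mv_per_s
    r_dn = params.up_amplitude_mv / params.up_down_slope_mv_per_s
    dur_up = params.up_duration_s[0]
    dur_down = 1.0 / params.swo_freq_hz - dur_up
    half_ramps = (r_up + r_dn) / 2
    bump_gain = (params.bump_height_mv * params.bump_width_s / 2
                 * params.n_peaks_per_up[0] / dur_up)
    f5_expected = (params.up_amplitude_mv + bump_gain
                   - params.up_amplitude_mv / 4 * half_ramps
                   * (1 / dur_up + 1 / dur_down))

    truth = SynthGroundTruth(
        true_intervals=IntervalSet(np.asarray(intervals), label="up"),
        true_phase_rad=phase,
        true_feature_values={
            "f5_amplitude_mv": params.up_amplitude_mv,
            "f5_expected_mv": f5_expected,
            "f8_down_up_slope_mv_per_s": params.down_up_slope_mv_per_s,
            "f9_up_down_slope_mv_per_s": params.up_down_slope_mv_per_s,
            "f13_up_length_s": params.up_duration_s[0],
            "f11_n_peaks": params.n_peaks_per_up[0],
        },
    )

    bump_centers = _place_bumps(params, intervals, rng)
    truth.bump_times_s = bump_centers
    for centers in bump_centers:
        _add_bumps(x, centers, params.bump_height_mv, params.bump_width_s, rate)

    # band bursts locked to the skeleton phase
    t_axis = np.arange(n) / rate
    for burst in params.band_bursts:
        kappa = _kappa_from_sd_deg(burst.phase_jitter_deg)
        realized = []
        for a, b in intervals:
            target = np.radians(burst.locked_phase_deg)
            if np.isfinite(kappa):
                target = target + rng.vonmises(0.0, kappa)
            i0 = max(int(round((a - 0.15) * rate)), 0)
            i1 = min(int(round((b + 0.15) * rate)), n)
            seg_phase = phase[i0:i1]
            d = np.abs(np.angle(np.exp(1j * (seg_phase - target))))
            ic = i0 + int(np.argmin(d))
            dur = max(4.0 / burst.center_hz, 0.15)
            half = int(round(dur / 2 * rate))
            j0, j1 = max(ic - half, 0), min(ic + half, n)
            if j1 - j0 < 4:
                continue
            env = tukey(j1 - j0, alpha=0.5)
            carrier = np.sin(2 * np.pi * burst.center_hz * (t_axis[j0:j1] - t_axis[ic]))
            x[j0:j1] += burst.burst_amplitude_mv * env * carrier
            realized.append(np.degrees(phase[ic]))
        truth.true_band_phase_deg[burst.center_hz] = np.asarray(realized)

    # synaptic-like events: inhomogeneous Poisson, von Mises phase modulation
    if params.event_rates:
        kernel = _event_kernel(rate)
        times, pols = [], []
        from scipy.special import i0 as bessel_i0
        for pol_name, (rate_ev, pref_deg, kappa) in params.event_rates.items():
            sign = +1 if pol_name.startswith("dep") else -1
            pref = np.radians(pref_deg)
            if kappa > 0:
                lam = rate_ev * np.exp(kappa * np.cos(phase - pref)) / bessel_i0(kappa)
            else:
                lam = np.full(n, rate_ev)
            hits = np.where(rng.random(n) < lam / rate)[0]
            for ic in hits:
                _add_kernel(x, kernel * sign * params.event_amplitude_mv, ic)
            times.append(hits / rate)
            pols.append(np.full(hits.size, sign, dtype=int))
        if times:
            tt = np.concatenate(times)
            pp = np.concatenate(pols)
            order = np.argsort(tt)
            truth.true_event_times_s = tt[order]
            truth.event_polarities = pp[order]

    # spikes: 2 ms triangular 60 mV transients during Up states
    if params.spike_rate_hz > 0:
        mask = truth.true_intervals.membership(n, rate)
        hits = np.where((rng.random(n) < params.spike_rate_hz / rate) & mask)[0]
        half = max(int(round(0.001 * rate)), 1)
        tri = 60.0 * (1 - np.abs(np.arange(-half, half + 1)) / half)
        for ic in hits:
            _add_kernel(x, tri, ic, centered=True)
        truth.spike_times_s = hits / rate

    # within-Up slow fluctuation and broadband noise
    if params.up_sd_mv > 0:
        mask = truth.true_intervals.membership(n, rate).astype(float)
        slow = rng.normal(0, 1, n)
        w = max(int(round(0.05 * rate)), 1)
        slow = np.convolve(slow, np.ones(w) / w, mode="same")
        sd = slow.std()
        if sd > 0:
            x += mask * slow * (params.up_sd_mv / sd)
    if params.noise_sd_mv > 0:
        x += rng.normal(0.0, params.noise_sd_mv, n)

    ts = TimeSeries(x, rate, meta={"units": "mV", "synthetic": True})
    return ts, truth


def _event_kernel(rate: float, tau_rise_s: float = 0.002,
                  tau_decay_s: float = 0.015) -> np.ndarray:
    t = np.arange(0, 6 * tau_decay_s, 1 / rate)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    return k / k.max()


def _add_kernel(x: np.ndarray, kernel: np.ndarray, i0: int, centered: bool = False) -> None:
    if centered:
        i0 = i0 - kernel.size // 2
    j0 = max(i0, 0)
    j1 = min(i0 + kernel.size, x.size)
    if j1 > j0:
        x[j0:j1] += kernel[j0 - i0:j1 - i0]


def generate_paired_traces(params_a: SynthParams, params_b: SynthParams,
                           lag_mean_s: float = 0.05, lag_sd_s: float = 0.03,
                           p_a_leads: float = 1.0, seed: int | None = None
                           ) -> tuple[TimeSeries, TimeSeries, SynthGroundTruth]:
    """Two traces sharing an Up-state skeleton with a stochastic onset lag.

    Trace B's k-th Up state is shifted by a signed lag: positive (A
    leads, B later) with probability ``p_a_leads``; the magnitude is
    drawn from N(lag_mean_s, lag_sd_s) truncated positive.  True lags
    are recorded in the returned ground truth.
    """
    if abs(lag_mean_s) >= 0.5:
        raise ValueError("lag_mean_s must be below the 500 ms pairing window")
    rng = np.random.default_rng(seed)
    pa = SynthParams(**{**params_a.__dict__, "seed": int(rng.integers(2 ** 31))})
    ts_a, truth_a = generate_trace(pa)

    iv_a = truth_a.true_intervals.intervals
    n_states = iv_a.shape[0]
    if lag_sd_s > 0:
        mags = np.abs(lag_mean_s) + lag_sd_s * rng.standard_normal(n_states)
        for _ in range(100):
            bad = mags <= 0
            if not bad.any():
                break
            mags[bad] = np.abs(lag_mean_s) + lag_sd_s * rng.standard_normal(bad.sum())
        mags = np.abs(mags)
    else:
        mags = np.full(n_states, abs(lag_mean_s))
    signs = np.where(rng.random(n_states) < p_a_leads, 1.0, -1.0)
    lags = signs * mags * np.sign(lag_mean_s) if lag_mean_s < 0 else signs * mags
    if np.mean(np.abs(lags) > 0.5) > 0.2:
        log.warning("more than 20%% of pair lags exceed the 500 ms pairing window")

    iv_b = iv_a + lags[:, None]
    # keep B's states ordered and inside the trace
    iv_b[:, 0] = np.maximum(iv_b[:, 0], 0.05)
    keep = np.ones(n_states, dtype=bool)
    for k in range(1, n_states):
        if iv_b[k, 0] <= iv_b[k - 1, 1]:
            keep[k] = False
    iv_b = iv_b[keep]
    lags_kept = lags[keep]

    pb = SynthParams(**{**params_b.__dict__, "seed": int(rng.integers(2 ** 31))})
    rng_b = np.random.default_rng(pb.seed)
    n = int(round(pb.duration_s * pb.rate_hz))
    xb = _skeleton(pb, [tuple(v) for v in iv_b], n)
    phase_b = np.angle(_hilbert(xb - xb.mean()))
    bumps_b = _place_bumps(pb, [tuple(v) for v in iv_b], rng_b)
    for centers in bumps_b:
        _add_bumps(xb, centers, pb.bump_height_mv, pb.bump_width_s, pb.rate_hz)
    if pb.noise_sd_mv > 0:
        xb += rng_b.normal(0.0, pb.noise_sd_mv, n)
    ts_b = TimeSeries(xb, pb.rate_hz, meta={"units": "mV", "synthetic": True})

    truth = SynthGroundTruth(
        true_intervals=truth_a.true_intervals,
        bump_times_s=truth_a.bump_times_s,
        true_phase_rad=truth_a.true_phase_rad,
        true_pair_lag_s=lags_kept,
    )
    truth.true_feature_values["intervals_b"] = iv_b  # type: ignore[assignment]
    return ts_a, ts_b, truth


# region presets mirroring the lateromedial effect directions: lateral-like
# cells show more intra-Up peaks and longer Up states; medial-like cells
# show larger Up amplitude and a steeper Up-to-Down transition.
# The rise slope is drawn as a per-cell multiple of the fall slope
# ("slope_ratio"): cells with fast transitions are fast in both
# directions, and the ratio itself is broadly dispersed, so the region
# signal stays concentrated in the fall slope (f9) rather than leaking
# into the rise slope (f8) or the ratio (f10).  The resting (Down)
# potential spread of ~7 mV across cells matches in vivo variability.
DLS_LIKE_SPEC = {
    "n_peaks_mean": (2.3, 0.3),
    "up_duration_mean_s": (0.65, 0.04),
    "up_amplitude_mv": (20.0, 2.0),
    "up_down_slope_mv_per_s": (90.0, 20.0),
    "slope_ratio": (2.4, 1.3),
    "down_mean_mv": (-70.0, 7.0),
    "bump_height_mv": (5.0, 1.2),
    "up_sd_mv": (1.0, 0.3),
}
DMS_LIKE_SPEC = {
    "n_peaks_mean": (1.4, 0.3),
    "up_duration_mean_s": (0.62, 0.04),
    "up_amplitude_mv": (26.0, 2.0),
    "up_down_slope_mv_per_s": (170.0, 20.0),
    "slope_ratio": (2.4, 1.3),
    "down_mean_mv": (-70.0, 7.0),
    "bump_height_mv": (5.0, 1.2),
    "up_sd_mv": (1.0, 0.3),
}

_SPEC_KEY_MAP = {
    "up_amplitude_mv": "up_amplitude_mv",
    "up_down_slope_mv_per_s": "up_down_slope_mv_per_s",
    "down_up_slope_mv_per_s": "down_up_slope_mv_per_s",
    "down_mean_mv": "down_mean_mv",
    "noise_sd_mv": "noise_sd_mv",
    "up_sd_mv": "up_sd_mv",
    "bump_height_mv": "bump_height_mv",
}


def generate_cohort(region_specs: dict[str, dict], n_cells_per_region: int,
                    n_animals: int, seed: int | None = None,
                    duration_s: float = 60.0, rate_hz: float = 1000.0,
                    base_params: SynthParams | None = None
                    ) -> tuple[list[TimeSeries], pd.DataFrame, list[SynthGroundTruth]]:
    """Generate a labeled multi-animal cohort of surrogate cells.

    ``region_specs`` maps a region label to per-cell parameter
    distributions ``{key: (mean, sd)}`` (see :data:`DLS_LIKE_SPEC`).
    Cells are assigned round-robin to ``n_animals`` animal ids so most
    animals contribute cells to every region, emulating a few cells
    recorded per mouse.

    Returns (traces, cohort table, ground truths); the table carries
    cell_id, animal_id, region, pathway and the true per-cell parameters.
    """
    if len(region_specs) < 2:
        raise ValueError("need at least 2 regions")
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    n_total = len(region_specs) * n_cells_per_region
    if n_total < n_animals:
        raise ValueError("fewer cells than animals")
    rng = np.random.default_rng(seed)
    base = base_params or SynthParams(duration_s=duration_s, rate_hz=rate_hz)

    cells = [(region, i) for region in region_specs for i in range(n_cells_per_region)]
    order = rng.permutation(len(cells))
    animal_of = np.empty(len(cells), dtype=int)
    animal_of[order] = np.arange(len(cells)) % n_animals

    traces, rows, truths = [], [], []
    for idx, (region, i) in enumerate(cells):
        spec = region_specs[region]
        kw = {**base.__dict__}
        kw["duration_s"] = duration_s
        kw["rate_hz"] = rate_hz
        kw["seed"] = int(rng.integers(2 ** 31))
        drawn: dict[str, float] = {}
        slope_ratio = None
        for key, val in spec.items():
            mean, sd = (val if isinstance(val, (tuple, list)) else (val, 0.0))
            v = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
            drawn[key] = v
            if key == "n_peaks_mean":
                kw["n_peaks_per_up"] = (max(v, 0.0), 0.5)
            elif key == "up_duration_mean_s":
                kw["up_duration_s"] = (max(v, MIN_UP_DURATION_S + 0.05),
                                       base.up_duration_s[1])
            elif key == "slope_ratio":
                slope_ratio = max(v, 1.2)
            elif key in _SPEC_KEY_MAP:
                nonneg = key.endswith("slope_mv_per_s") or key in ("up_sd_mv", "bump_height_mv", "noise_sd_mv")
                kw[_SPEC_KEY_MAP[key]] = abs(v) if nonneg else v
            else:
                raise ValueError(f"unknown region spec key: {key}")
        if slope_ratio is not None:
            kw["down_up_slope_mv_per_s"] = slope_ratio * kw["up_down_slope_mv_per_s"]
        # keep each transition ramp under 300 ms so the ramps always fit
        # inside the drawn Up/Down durations
        min_slope = kw["up_amplitude_mv"] / 0.3
        for key in ("up_down_slope_mv_per_s", "down_up_slope_mv_per_s"):
            kw[key] = max(kw[key], min_slope)
        params = SynthParams(**kw)
        ts, truth = generate_trace(params)
        truth.true_region_label = region
        traces.append(ts)
        truths.append(truth)
        rows.append({"cell_id": f"{region}_{i:03d}", "animal_id": f"animal_{animal_of[idx]:02d}",
                     "region": region, "pathway": "unknown",
                     **{f"true_{k}": v for k, v in drawn.items()}})
    table = pd.DataFrame(rows)
    return traces, table, truths


def generate_event_trace(duration_s: float = 60.0, rate_hz: float = 2000.0,
                         swo_amplitude_mv: float = 10.0, swo_freq_hz: float = 0.7,
                         depol_rate_hz: float = 4.0, hyperpol_rate_hz: float = 0.0,
                         event_amplitude_mv: float = 1.5,
                         depol_phase_deg: float | None = None,
                         hyperpol_phase_deg: float | None = None,
                         phase_kappa: float = 8.0,
                         noise_sd_mv: float = 0.03, seed: int | None = None
                         ) -> tuple[TimeSeries, SynthGroundTruth]:
    """Sinusoidal slow-wave background with planted sharp events.

    Dedicated fixture for the synaptic-event detector: the background is
    a pure slow-wave tone (its derivative never exceeds its own 2-SD
    threshold), so the planted difference-of-exponentials deflections
    are the only sharp structures.  Events are Poisson in time, with at
    least 50 ms separation; when a preferred phase is given the event
    times are drawn phase-locked (von Mises with ``phase_kappa``).
    Phase convention: 0 degrees at the depolarized peak of the slow
    wave.  Ground truth records times, polarities and the per-sample
    slow-wave phase.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    # sin(2*pi*f*t - pi/2) peaks where the Hilbert phase is 0
    phase = (2 * np.pi * swo_freq_hz * t) % (2 * np.pi)
    phase = np.angle(np.exp(1j * (phase - np.pi / 2)))  # wrapped, 0 at peak
    x = -65.0 + swo_amplitude_mv * np.cos(phase)
    kernel = _event_kernel(rate_hz)

    def draw_times(rate_ev: float, pref_deg: float | None) -> np.ndarray:
        if rate_ev <= 0:
            return np.empty(0)
        if pref_deg is None:
            raw = np.sort(rng.uniform(0.5, duration_s - 0.5,
                                      rng.poisson(rate_ev * duration_s)))
        else:
            # one candidate window per slow-wave cycle at the target phase
            n_cycles = int(duration_s * swo_freq_hz)
            per_cycle = max(int(round(rate_ev / swo_freq_hz)), 1)
            offs = rng.vonmises(np.radians(pref_deg), phase_kappa,
                                size=(n_cycles, per_cycle))
            cyc = (np.arange(n_cycles)[:, None] + 0.25) / swo_freq_hz
            raw = np.sort((cyc + offs / (2 * np.pi * swo_freq_hz)).ravel())
            raw = raw[(raw > 0.5) & (raw < duration_s - 0.5)]
        kept: list[float] = []
        for r in raw:
            if not kept or r - kept[-1] > 0.05:
                kept.append(float(r))
        return np.asarray(kept)

    times, pols = [], []
    for sign, rate_ev, pref in ((+1, depol_rate_hz, depol_phase_deg),
                                (-1, hyperpol_rate_hz, hyperpol_phase_deg)):
        tt = draw_times(rate_ev, pref)
        for et in tt:
            _add_kernel(x, sign * event_amplitude_mv * kernel, int(round(et * rate_hz)))
        times.append(tt)
        pols.append(np.full(tt.size, sign, dtype=int))
    tt = np.concatenate(times)
    pp = np.concatenate(pols)
    order = np.argsort(tt)
    if noise_sd_mv > 0:
        x += rng.normal(0.0, noise_sd_mv, n)

    truth = SynthGroundTruth(
        true_intervals=IntervalSet(np.empty((0, 2)), label="up"),
        true_event_times_s=tt[order],
        event_polarities=pp[order],
        true_phase_rad=phase,
    )
    return TimeSeries(x, rate_hz, meta={"units": "mV", "synthetic": True}), truth


@dataclass
class StepProtocol:
    """Current-step protocol: one trace per injected step amplitude."""

    steps: list[tuple[float, TimeSeries]]     # (I in pA, voltage trace)
    step_onset_s: float
    step_duration_s: float
    baseline_mv: float


def generate_rc_response(r_mohm: float, c_pf: float,
                         step_amplitudes_pa: Sequence[float],
                         noise_sd_mv: float = 0.0, seed: int | None = None,
                         rate_hz: float = 10000.0, baseline_s: float = 0.05,
                         step_duration_s: float = 0.15,
                         v0_mv: float = -70.0) -> StepProtocol:
    """RC membrane responses to current steps.

    Each response follows V(t) = V0 + I*R*(1 - exp(-t/RC)) during the
    step and relaxes exponentially afterwards.  Units: R in megaohm, C in
    picofarad, I in picoamp; tau = R*C microseconds, steady-state
    deflection I*R microvolts.
    """
    if r_mohm <= 0 or c_pf <= 0:
        raise ValueError("R and C must be positive")
    rng = np.random.default_rng(seed)
    tau_s = r_mohm * c_pf * 1e-6          # MOhm * pF = microseconds
    total_s = baseline_s + step_duration_s + 5 * tau_s + 0.02
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    steps = []
    for i_pa in step_amplitudes_pa:
        dv_mv = i_pa * r_mohm * 1e-3      # pA * MOhm = microvolt
        v = np.full(n, v0_mv)
        on = t >= baseline_s
        during = on & (t < baseline_s + step_duration_s)
        after = t >= baseline_s + step_duration_s
        v[during] += dv_mv * (1 - np.exp(-(t[during] - baseline_s) / tau_s))
        v_end = dv_mv * (1 - np.exp(-step_duration_s / tau_s))
        v[after] += v_end * np.exp(-(t[after] - baseline_s - step_duration_s) / tau_s)
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, n)
        steps.append((float(i_pa), TimeSeries(v, rate_hz, meta={"units": "mV", "i_pa": i_pa})))
    return StepProtocol(steps, baseline_s, step_duration_s, v0_mv)


def generate_evoked_trials(onset_ms: float, amplitude_mv: float,
                           slope_mv_per_s: float, n_trials: int,
                           noise_sd: float = 0.0, seed: int | None = None,
                           rate_hz: float = 10000.0, trial_duration_s: float = 0.5,
                           baseline_mv: float = -70.0,
                           decay_tau_s: float = 0.1
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Evoked-response trials: flat baseline, then a linear ramp.

    Each trial is flat at ``baseline_mv`` until ``onset_ms`` after the
    trigger (trigger at t = 0), ramps at ``slope_mv_per_s`` up to
    ``amplitude_mv``, and decays exponentially.  Returns (trial matrix
    of shape (n_trials, n_samples), trial time axis in s, trigger time).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if amplitude_mv < 0 or slope_mv_per_s <= 0:
        raise ValueError("amplitude must be >= 0 and slope > 0")
    rng = np.random.default_rng(seed)
    n = int(round(trial_duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    onset_s = onset_ms / 1000.0
    ramp_s = amplitude_mv / slope_mv_per_s
    wave = np.full(n, baseline_mv)
    ramp = (t >= onset_s) & (t < onset_s + ramp_s)
    wave[ramp] += slope_mv_per_s * (t[ramp] - onset_s)
    after = t >= onset_s + ramp_s
    wave[after] += amplitude_mv * np.exp(-(t[after] - onset_s - ramp_s) / decay_tau_s)
    trials = np.tile(wave, (n_trials, 1))
    if noise_sd > 0:
        trials = trials + rng.normal(0.0, noise_sd, trials.shape)
    return trials, t, 0.0
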