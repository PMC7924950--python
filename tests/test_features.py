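"""Up-state featurization: oracles, invariances, passive properties."""

import numpy as np
import pandas as pd
import pytest

from conftest import trapezoid_trace
from slowwave.core import IntervalSet, TimeSeries
from slowwave.emd import emd
from slowwave.features import (
    FEATURE_NAMES,
    compute_up_features,
    count_up_peaks,
    evoked_response_metrics,
    intrinsic_feature_correlation,
    passive_properties,
    remove_spikes,
    transition_slope,
)
from slowwave.states import detect_up_states
from slowwave.synthetic import (
    SynthParams,
    generate_evoked_trials,
    generate_rc_response,
    generate_trace,
)


class TestTrapezoidOracle:
    def test_analytic_feature_recovery(self):
        ts, intervals, exp = trapezoid_trace()
        df = compute_up_features(ts, IntervalSet(intervals))
        row = df.iloc[0]
        assert row.f5_amplitude_mv == pytest.approx(exp["f5"], rel=0.05)
        assert row.f8_down_up_slope_mv_per_s == pytest.approx(exp["f8"], rel=0.05)
        assert row.f9_up_down_slope_mv_per_s == pytest.approx(exp["f9"], rel=0.05)
        assert row.f10_slope_ratio == pytest.approx(exp["f10"], rel=0.05)
        assert row.f13_up_length_s == pytest.approx(exp["f13"], rel=0.05)
        assert row.f1_mean_up_mv == pytest.approx(exp["f1"], abs=0.1)

    def test_flat_plateau_degenerate_features(self):
        # restrict the interval to the flat plateau: SD, peak count and
        # peak-to-peak all collapse to zero
        ts, intervals, _ = trapezoid_trace()
        on, off = intervals[0]
        plateau = IntervalSet(np.array([[on + 0.11, off - 0.11]]))
        df = compute_up_features(ts, plateau)
        assert df.f2_sd_up_mv.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert df.f11_n_peaks.iloc[0] == 0
        assert df.f12_peak_to_peak_mv.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_internal_consistency_on_synthetic(self, default_trace):
        ts, _ = default_trace
        df = compute_up_features(ts, detect_up_states(ts))
        assert len(df) > 20
        assert np.allclose(df.f12_peak_to_peak_mv,
                           df.f4_max_up_mv - df.f3_min_up_mv)
        assert np.all(df.f4_max_up_mv >= df.f1_mean_up_mv - 1e-9)
        assert np.all(df.f1_mean_up_mv >= df.f3_min_up_mv - 1e-9)
        assert np.all(df.f13_up_length_s >= 0.2 - 1e-9)
        assert np.all(df.f11_n_peaks >= 0)

    def test_voltage_offset_invariance(self):
        ts, intervals, _ = trapezoid_trace()
        df0 = compute_up_features(ts, IntervalSet(intervals))
        ts2 = TimeSeries(ts.values + 12.5, ts.rate_hz)
        df1 = compute_up_features(ts2, IntervalSet(intervals))
        for col in ("f2_sd_up_mv", "f5_amplitude_mv", "f8_down_up_slope_mv_per_s",
                    "f9_up_down_slope_mv_per_s", "f10_slope_ratio", "f11_n_peaks",
                    "f12_peak_to_peak_mv", "f13_up_length_s"):
            assert np.allclose(df0[col], df1[col], equal_nan=True)
        for col in ("f1_mean_up_mv", "f3_min_up_mv", "f4_max_up_mv"):
            assert np.allclose(df0[col] + 12.5, df1[col])

    def test_time_rescaling(self):
        # gentle slopes so both the original and the 2x-compressed ramps
        # stay inside the slope fit's valid regime
        ts, intervals, _ = trapezoid_trace(rise_mv_per_s=120.0, fall_mv_per_s=80.0)
        fast = TimeSeries(ts.values, ts.rate_hz * 2)   # compress time by 2
        df_slow = compute_up_features(ts, IntervalSet(intervals))
        df_fast = compute_up_features(fast, IntervalSet(intervals / 2))
        r = df_fast.iloc[0]
        s = df_slow.iloc[0]
        assert r.f13_up_length_s == pytest.approx(s.f13_up_length_s / 2)
        assert r.f8_down_up_slope_mv_per_s == pytest.approx(
            2 * s.f8_down_up_slope_mv_per_s, rel=0.05)
        assert r.f9_up_down_slope_mv_per_s == pytest.approx(
            2 * s.f9_up_down_slope_mv_per_s, rel=0.05)
        assert r.f6_max_dvdt_mv_per_s == pytest.approx(
            2 * s.f6_max_dvdt_mv_per_s, rel=0.02)

    def test_parameter_recovery_on_long_trace(self):
        params = SynthParams(duration_s=80, seed=21, up_duration_s=(0.5, 0.04),
                             n_peaks_per_up=(1, 0), noise_sd_mv=0.5, up_sd_mv=0.3)
        ts, truth = generate_trace(params)
        df = compute_up_features(ts, detect_up_states(ts))
        assert len(df) >= 50
        exp = truth.true_feature_values
        assert df.f5_amplitude_mv.mean() == pytest.approx(exp["f5_expected_mv"], rel=0.10)
        assert df.f9_up_down_slope_mv_per_s.mean() == pytest.approx(
            exp["f9_up_down_slope_mv_per_s"], rel=0.10)
        assert df.f13_up_length_s.mean() == pytest.approx(exp["f13_up_length_s"], rel=0.10)
        assert df.f11_n_peaks.mean() == pytest.approx(exp["f11_n_peaks"], rel=0.10)


class TestPeakCounting:
    @staticmethod
    def bump_segment(centers_ms, rate=1000.0, total_ms=800, height=4.0, width_ms=150):
        x = np.full(int(total_ms * rate / 1000), -55.0)
        half = int(width_ms / 2 * rate / 1000)
        for c in centers_ms:
            ic = int(c * rate / 1000)
            i = np.arange(max(ic - half, 0), min(ic + half + 1, x.size))
            u = (i - ic) / half
            x[i] += height * 0.5 * (1 + np.cos(np.pi * np.clip(u, -1, 1)))
        return x

    def test_monotonic_has_no_peaks(self):
        assert count_up_peaks(np.linspace(-70, -50, 500), 1000.0) == 0

    def test_separation_rule(self):
        assert count_up_peaks(self.bump_segment([150, 450]), 1000.0) == 2
        assert count_up_peaks(self.bump_segment([350, 450]), 1000.0) == 1

    def test_three_equal_bumps(self):
        seg = self.bump_segment([100, 400, 700], total_ms=900)
        assert count_up_peaks(seg, 1000.0) == 3

    def test_matches_brute_force_oracle(self):
        from scipy.ndimage import uniform_filter1d
        rng = np.random.default_rng(5)
        rate = 1000.0
        for _ in range(100):
            n = rng.integers(400, 900)
            raw = rng.normal(0, 1, n).cumsum()
            seg = uniform_filter1d(raw, 40)
            got = count_up_peaks(seg, rate)
            # oracle: smooth identically, list all local maxima above the
            # height rule, then greedily keep the highest with >=160 ms gaps
            w = min(int(0.2 * rate) | 1, (n - 1) | 1)
            sm = np.array([seg[max(0, i - w // 2): i + w // 2 + 1].mean()
                           for i in range(n)])
            height = sm.mean() + 0.3 * sm.std()
            cand = [i for i in range(1, n - 1)
                    if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] >= height]
            cand.sort(key=lambda i: -sm[i])
            kept = []
            for i in cand:
                if all(abs(i - j) >= int(0.16 * rate) for j in kept):
                    kept.append(i)
            assert got == len(kept)


class TestTransitionSlope:
    def test_ideal_ramp(self):
        ts, intervals, _ = trapezoid_trace()
        s = transition_slope(ts, intervals[0][0], "down_up")
        assert s == pytest.approx(250.0, rel=0.05)
        s2 = transition_slope(ts, intervals[0][1], "up_down")
        assert s2 == pytest.approx(-125.0, rel=0.05)

    def test_symmetric_transitions_give_unit_ratio(self):
        ts, intervals, _ = trapezoid_trace(rise_mv_per_s=200.0, fall_mv_per_s=200.0)
        up = abs(transition_slope(ts, intervals[0][0], "down_up"))
        dn = abs(transition_slope(ts, intervals[0][1], "up_down"))
        assert up / dn == pytest.approx(1.0, abs=0.05)

    def test_linearity_over_speeds(self):
        # valid regime of the windowed fit: ramp duration at least the
        # 100 ms smoothing window (speed <= amplitude / 0.1 s)
        rng = np.random.default_rng(6)
        for speed in rng.uniform(80, 250, 10):
            ts, intervals, _ = trapezoid_trace(rise_mv_per_s=speed)
            s = transition_slope(ts, intervals[0][0], "down_up")
            assert s == pytest.approx(speed, rel=0.05)

    def test_flat_region_rejected(self):
        ts = TimeSeries(np.full(2000, -70.0), 1000.0)
        with pytest.raises(ValueError):
            transition_slope(ts, 1.0, "down_up")


class TestSpikeRemoval:
    def test_spike_amplitude_reduced(self):
        params = SynthParams(duration_s=30, rate_hz=2000, seed=4,
                             spike_rate_hz=3.0, noise_sd_mv=0.3, up_sd_mv=0.3)
        ts, truth = generate_trace(params)
        assert truth.spike_times_s.size > 5
        clean = remove_spikes(ts, emd(ts))
        idx = (truth.spike_times_s * ts.rate_hz).astype(int)
        w = int(0.2 * ts.rate_hz) | 1
        ker = np.ones(w) / w
        before = np.abs(ts.values - np.convolve(ts.values, ker, "same"))[idx]
        after = np.abs(clean.values - np.convolve(clean.values, ker, "same"))[idx]
        reduction = 1 - after / np.maximum(before, 1e-9)
        assert np.median(reduction) >= 0.8

    def test_slow_trace_unchanged(self):
        params = SynthParams(duration_s=30, seed=5, noise_sd_mv=0, up_sd_mv=0)
        ts, _ = generate_trace(params)
        clean = remove_spikes(ts, emd(ts))
        assert np.max(np.abs(clean.values - ts.values)) < 0.01 * np.ptp(ts.values)

    def test_zero_trace_stays_zero(self):
        t = np.arange(0, 5, 1e-3)
        x = 1e-12 * np.sin(2 * np.pi * 80 * t)   # numerically zero trace
        ts = TimeSeries(x, 1000.0)
        clean = remove_spikes(ts, emd(ts))
        assert np.max(np.abs(clean.values)) < 1e-9


class TestPassiveProperties:
    def test_noiseless_closed_form(self):
        prot = generate_rc_response(300.0, 20.0, [-40, -20, 20, 40], noise_sd_mv=0)
        pp = passive_properties(prot)
        assert pp.r_in_mohm == pytest.approx(300.0, rel=0.01)
        assert pp.tau_ms == pytest.approx(6.0, rel=0.02)
        assert pp.c_pf == pytest.approx(20.0, rel=0.03)

    def test_offset_invariance(self):
        prot = generate_rc_response(150.0, 30.0, [-30, 30], noise_sd_mv=0)
        shifted = type(prot)(
            steps=[(i, TimeSeries(ts.values + 11.0, ts.rate_hz)) for i, ts in prot.steps],
            step_onset_s=prot.step_onset_s, step_duration_s=prot.step_duration_s,
            baseline_mv=prot.baseline_mv + 11.0)
        p0, p1 = passive_properties(prot), passive_properties(shifted)
        assert p0.r_in_mohm == pytest.approx(p1.r_in_mohm)
        assert p0.tau_ms == pytest.approx(p1.tau_ms)

    def test_single_step_rejected(self):
        prot = generate_rc_response(300.0, 20.0, [20.0], noise_sd_mv=0)
        with pytest.raises(ValueError):
            passive_properties(prot)


class TestEvokedMetrics:
    def test_responder_recovery(self):
        trials, t, trig = generate_evoked_trials(55.0, 18.0, 420.0, 50,
                                                 noise_sd=1.0, seed=0)
        resp = evoked_response_metrics(trials, t, trig,
                                       baseline_window_s=(0.0, 0.04))
        assert resp.responder
        assert resp.onset_ms == pytest.approx(55.0, abs=5.0)
        assert resp.amplitude_mv == pytest.approx(18.0, rel=0.10)

    def test_flat_trials_are_nonresponders(self):
        rng = np.random.default_rng(1)
        trials = -70 + rng.normal(0, 0.5, (20, 5000))
        t = np.arange(5000) / 10000.0
        resp = evoked_response_metrics(trials, t, 0.05,
                                       baseline_window_s=(0.0, 0.05))
        assert not resp.responder

    def test_halving_slope_doubles_rise_time(self):
        on_to_peak = {}
        for slope in (400.0, 200.0):
            trials, t, trig = generate_evoked_trials(50.0, 16.0, slope, 5, noise_sd=0)
            r = evoked_response_metrics(trials, t, trig,
                                        baseline_window_s=(0.0, 0.04))
            on_to_peak[slope] = 16.0 / r.slope_mv_per_s
        assert on_to_peak[200.0] / on_to_peak[400.0] == pytest.approx(2.0, rel=0.1)


class TestIntrinsicCorrelation:
    def _cohort(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        data = {f: rng.normal(0, 1, n) for f in FEATURE_NAMES}
        data["cell_id"] = [f"c{i}" for i in range(n)]
        return pd.DataFrame(data), rng

    def test_duplicated_feature_correlates_perfectly(self):
        cohort, _ = self._cohort()
        intrinsic = pd.DataFrame({"cell_id": cohort.cell_id,
                                  "r_in_mohm": cohort.f5_amplitude_mv})
        mat = intrinsic_feature_correlation(cohort, intrinsic)
        assert mat.loc["r_in_mohm", "f5_amplitude_mv"] == pytest.approx(1.0)

    def test_anticorrelated_construction(self):
        cohort, _ = self._cohort(seed=1)
        intrinsic = pd.DataFrame({"cell_id": cohort.cell_id,
                                  "tau_ms": -cohort.f13_up_length_s})
        mat = intrinsic_feature_correlation(cohort, intrinsic)
        assert mat.loc["tau_ms", "f13_up_length_s"] == pytest.approx(-1.0)

    def test_independent_draws_stay_below_threshold(self):
        cohort, rng = self._cohort(seed=2)
        intrinsic = pd.DataFrame({"cell_id": cohort.cell_id,
                                  "r_in_mohm": rng.normal(0, 1, 100),
                                  "tau_ms": rng.normal(0, 1, 100),
                                  "c_pf": rng.normal(0, 1, 100)})
        mat = intrinsic_feature_correlation(cohort, intrinsic)
        # null |r| at n=100 rarely exceeds 0.3; allow one excursion in 39 cells
        assert (np.abs(mat.to_numpy()) > 0.3).sum() <= 1

    def test_too_few_cells_rejected(self):
        cohort, _ = self._cohort(n=2)
        intrinsic = pd.DataFrame({"cell_id": cohort.cell_id,
                                  "r_in_mohm": [1.0, 2.0]})
        with pytest.raises(ValueError):
            intrinsic_feature_correlation(cohort, intrinsic)
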