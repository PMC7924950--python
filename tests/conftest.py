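import numpy as np
import pytest

from slowwave.core import TimeSeries
from slowwave.synthetic import SynthParams, generate_trace


@pytest.fixture(scope="session")
def default_trace():
    """One 60 s surrogate recording with ground truth (default params)."""
    return generate_trace(SynthParams(duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free surrogate recording (no bumps, no noise)."""
    params = SynthParams(duration_s=60.0, seed=12, noise_sd_mv=0.0,
                         up_sd_mv=0.0, n_peaks_per_up=(0.0, 0.0))
    return generate_trace(params)


def trapezoid_trace(rate_hz=1000.0, down_mv=-80.0, up_mv=-55.0,
                    rise_mv_per_s=250.0, fall_mv_per_s=125.0,
                    up_len_s=0.6, onsets=(1.0, 3.0), total_s=6.0):
    """Noiseless trapezoid alternation, mid-ramp interval convention.

    Interval boundaries sit at the 50% point of each transition ramp
    (the package-wide state-boundary convention), so each Up interval
    contains the outer half of both ramps.  Returns the trace, the Up
    intervals, and closed-form expected feature values that account for
    the ramp halves inside each state.
    """
    amp = up_mv - down_mv
    r_up = amp / rise_mv_per_s
    r_dn = amp / fall_mv_per_s
    t = np.arange(0, total_s, 1 / rate_hz)
    kt, kv = [0.0], [down_mv]
    intervals = []
    for on in onsets:
        off = on + up_len_s
        kt += [on - r_up / 2, on + r_up / 2, off - r_dn / 2, off + r_dn / 2]
        kv += [down_mv, up_mv, up_mv, down_mv]
        intervals.append((on, off))
    kt.append(total_s)
    kv.append(down_mv)
    x = np.interp(t, kt, kv)

    # closed form: a half ramp inside a state deviates from the plateau
    # (or floor) by amp/4 on average over its r/2 extent
    dilution_up = (amp / 4) * (r_up / 2 + r_dn / 2) / up_len_s
    f1 = up_mv - dilution_up
    # flanking Down states of the first Up: [0, on0] and [off0, on1]
    d_left = onsets[0] - intervals[0][0] + intervals[0][0]  # = onsets[0]
    left_mean = down_mv + (amp / 4) * (r_up / 2) / d_left
    d_mid = onsets[1] - (onsets[0] + up_len_s)
    mid_mean = down_mv + (amp / 4) * (r_dn / 2 + r_up / 2) / d_mid
    f5 = f1 - (left_mean + mid_mean) / 2
    expected = {"f1": f1, "f5": f5, "f8": rise_mv_per_s, "f9": fall_mv_per_s,
                "f10": rise_mv_per_s / fall_mv_per_s, "f13": up_len_s}
    return TimeSeries(x, rate_hz), np.asarray(intervals), expected
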