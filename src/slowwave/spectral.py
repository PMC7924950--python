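"""Band-energy phase profiles, circular statistics and SWO correlation.

After NA-MEMD decomposition, IMFs are grouped into the physiological
bands (theta 6-10 Hz, beta 10-20 Hz, gamma 20-80 Hz) by their median
Hilbert instantaneous frequency.  The squared instantaneous amplitude
of a band (its energy) is averaged inside slow-wave phase bins over
Up-state samples only, giving the phase profile whose peak locates the
band's preferred position in the Up state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import IntervalSet
from .emd import AnalyticSignal, ImfDecomposition, hilbert_analytic, _median_inst_freq

__all__ = [
    "BANDS",
    "PhaseProfile",
    "phase_bin_centers",
    "band_energy_phase_profile",
    "band_up_state_features",
    "rayleigh_test",
    "swo_cross_correlation",
]

log = logging.getLogger(__name__)

#: canonical frequency bands, Hz
BANDS: dict[str, tuple[float, float]] = {
    "theta": (6.0, 10.0),
    "beta": (10.0, 20.0),
    "gamma": (20.0, 80.0),
}


def phase_bin_centers(n_bins: int) -> np.ndarray:
    """Centers of ``n_bins`` equal bins partitioning (-180, 180] degrees."""
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class PhaseProfile:
    """A circular profile over slow-wave phase bins.

    ``values`` is the profile normalized to its maximum (when positive);
    ``raw_values`` keeps the unnormalized quantity (e.g. mean band
    energy in mV^2) so absolute magnitudes remain available.
    """

    bin_centers_deg: np.ndarray
    values: np.ndarray
    peak_phase_deg: float
    peak_value: float              # raw (unnormalized) peak
    raw_values: np.ndarray = field(default=None)
    flagged_empty: bool = False

    def trough_phase_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmin(self.values))])

    def refined_peak_phase_deg(self) -> float:
        """Sub-bin peak location via three-point parabolic interpolation.

        Interpolates the circular neighbourhood of the maximum bin, the
        standard refinement for peak estimates quantized to a bin grid.
        """
        v = np.asarray(self.values, dtype=float)
        n = v.size
        k = int(np.argmax(v))
        y0, y1, y2 = v[(k - 1) % n], v[k], v[(k + 1) % n]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        width = 360.0 / n
        return float(np.degrees(np.angle(np.exp(
            1j * np.radians(self.bin_centers_deg[k] + shift * width)))))


def band_imf_indices(decomposition: ImfDecomposition, band_hz: tuple[float, float],
                     channel: int = 0) -> list[int]:
    """IMFs whose median instantaneous frequency lies in [low, high)."""
    low, high = band_hz
    out = []
    for k in range(decomposition.n_imfs):
        f = _median_inst_freq(decomposition.imfs[channel, k], decomposition.rate_hz)
        if low <= f < high:
            out.append(k)
    return out


def band_energy_phase_profile(decomposition: ImfDecomposition,
                              band_hz: tuple[float, float],
                              swo_phase: AnalyticSignal,
                              up_intervals: IntervalSet,
                              n_bins: int = 36, channel: int = 0,
                              start_s: float = 0.0,
                              edge_fraction: float = 0.05) -> PhaseProfile:
    """Mean band energy per slow-wave phase bin, Up-state samples only.

    The band signal is the sum of IMFs assigned to the band; its energy
    is the squared Hilbert amplitude.  The profile is normalized to its
    maximum bin; ``peak_value`` keeps the raw peak energy.  A band with
    no IMF yields a zero profile, flagged.

    The first and last ``edge_fraction`` of samples are excluded: the
    spline envelopes of the decomposition are unconstrained beyond the
    outermost extrema, so IMF amplitude (and hence energy) is unreliable
    at the trace edges.
    """
    centers = phase_bin_centers(n_bins)
    idx = band_imf_indices(decomposition, band_hz, channel)
    if not idx:
        log.warning("no IMF in band %s; zero profile", band_hz)
        z = np.zeros(n_bins)
        return PhaseProfile(centers, z, 0.0, 0.0, raw_values=z, flagged_empty=True)
    band = decomposition.imfs[channel, idx].sum(axis=0)
    energy = hilbert_analytic(band, decomposition.rate_hz).amplitude ** 2
    mask = up_intervals.membership(energy.size, decomposition.rate_hz, start_s)
    edge = int(round(edge_fraction * energy.size))
    if edge:
        mask[:edge] = False
        mask[-edge:] = False
    ph = np.degrees(swo_phase.phase_rad)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    which = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
    raw = np.zeros(n_bins)
    for b in range(n_bins):
        sel = mask & (which == b)
        if sel.any():
            raw[b] = energy[sel].mean()
    peak_idx = int(np.argmax(raw))
    norm = raw / raw.max() if raw.max() > 0 else raw
    return PhaseProfile(centers, norm, float(centers[peak_idx]),
                        float(raw[peak_idx]), raw_values=raw)


def band_up_state_features(profiles: dict[str, PhaseProfile]) -> dict[str, float]:
    """Peak energy and peak position per band, for classification.

    Returns ``{band}_peak_energy`` (raw energy units) and
    ``{band}_peak_phase_deg`` for each band; missing (flagged) bands
    yield NaN features.
    """
    out: dict[str, float] = {}
    for name, prof in profiles.items():
        if prof.flagged_empty:
            out[f"{name}_peak_energy"] = float("nan")
            out[f"{name}_peak_phase_deg"] = float("nan")
        else:
            out[f"{name}_peak_energy"] = prof.peak_value
            out[f"{name}_peak_phase_deg"] = prof.peak_phase_deg
    return out


def rayleigh_test(phases_rad: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (z, p) where z = n * Rbar^2 and p uses the standard
    finite-n corrected approximation.  Requires n >= 2 finite phases.
    """
    ph = np.asarray(phases_rad, dtype=float)
    if ph.size < 2:
        raise ValueError("Rayleigh test needs at least 2 phases")
    if not np.all(np.isfinite(ph)):
        raise ValueError("phases must be finite")
    n = ph.size
    rbar = np.abs(np.mean(np.exp(1j * ph)))
    z = n * rbar ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4) / (288 * n ** 2))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def swo_cross_correlation(swo_imf_a: np.ndarray, swo_imf_b: np.ndarray,
                          rate_hz: float | None = None,
                          return_peak_lag: bool = False):
    """Zero-lag Pearson correlation of two SWO IMFs.

    The full lag function is computed internally and the lag of its
    peak is logged (returned when ``return_peak_lag`` is true with
    ``rate_hz`` given).
    """
    a = np.asarray(swo_imf_a, dtype=float)
    b = np.asarray(swo_imf_b, dtype=float)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    ac = a - a.mean()
    bc = b - b.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input")
    r0 = float(np.mean(ac * bc) / (sa * sb))
    xcorr = np.correlate(ac, bc, mode="full") / (a.size * sa * sb)
    peak_shift = int(np.argmax(np.abs(xcorr))) - (a.size - 1)
    if rate_hz:
        log.info("cross-correlation peak at lag %.3f s", peak_shift / rate_hz)
    if return_peak_lag:
        if not rate_hz:
            raise ValueError("rate_hz required for peak lag")
        return r0, peak_shift / rate_hz
    return r0
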