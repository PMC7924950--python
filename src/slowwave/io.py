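"""File formats, run configuration and the end-to-end pipeline.

Native on-disk format is inspectable plain text: a two-column delimited
file (time_s, value_mv) with a JSON sidecar carrying the sampling rate
and channel metadata.  A single-file binary bundle (magic + JSON header
+ float64 array) is provided for large cohorts.  Every pipeline output
records the configuration hash, seed and package version, so identical
config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import IntervalSet, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_bundle",
    "write_bundle",
    "write_intervals",
    "read_intervals",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_BUNDLE_MAGIC = b"SWOB"
_BUNDLE_VERSION = 1


def write_timeseries(path: str | Path, trace: TimeSeries, delimiter: str = "\t") -> None:
    """Write a trace as two-column delimited text plus a JSON sidecar."""
    path = Path(path)
    t = trace.times()
    np.savetxt(path, np.column_stack([t, trace.values]), delimiter=delimiter,
               header="time_s\tvalue", comments="# ")
    sidecar = {"rate_hz": trace.rate_hz, "start_s": trace.start_s,
               "units": trace.meta.get("units", "mV"), **trace.meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a trace from delimited text (with sidecar) or a binary bundle.

    ``#``-prefixed header lines are skipped.  The sampling-rate metadata
    must be present in the sidecar; a non-monotonic time column is
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        if fh.read(4) == _BUNDLE_MAGIC:
            return read_bundle(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing rate metadata: sidecar {sidecar_path.name} not found "
                         "next to the trace file")
    meta = json.loads(sidecar_path.read_text())
    if "rate_hz" not in meta:
        raise ValueError("sidecar lacks the required 'rate_hz' field")
    data = np.loadtxt(path, comments="#", delimiter=None)
    if data.ndim == 1:
        data = data.reshape(-1, 2)
    t, v = data[:, 0], data[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic time column")
    rate = float(meta.pop("rate_hz"))
    start = float(meta.pop("start_s", t[0]))
    return TimeSeries(v, rate, start_s=start, meta=meta)


def write_bundle(path: str | Path, trace: TimeSeries) -> None:
    """Single-file binary bundle: magic, version, JSON header, float64 array."""
    header = json.dumps({"rate_hz": trace.rate_hz, "start_s": trace.start_s,
                         "n": len(trace), **{k: str(v) for k, v in trace.meta.items()}
                         }).encode()
    with open(path, "wb") as fh:
        fh.write(_BUNDLE_MAGIC)
        fh.write(struct.pack("<II", _BUNDLE_VERSION, len(header)))
        fh.write(header)
        fh.write(np.ascontiguousarray(trace.values, dtype="<f8").tobytes())


def read_bundle(path: str | Path) -> TimeSeries:
    with open(path, "rb") as fh:
        if fh.read(4) != _BUNDLE_MAGIC:
            raise ValueError("not a bundle file")
        raw = fh.read(8)
        if len(raw) < 8:
            raise ValueError("truncated bundle header")
        version, hlen = struct.unpack("<II", raw)
        if version != _BUNDLE_VERSION:
            raise ValueError(f"unsupported bundle version {version}")
        header = fh.read(hlen)
        if len(header) < hlen:
            raise ValueError("truncated bundle header")
        meta = json.loads(header.decode())
        n = int(meta.pop("n"))
        payload = fh.read(n * 8)
        if len(payload) < n * 8:
            raise ValueError("truncated bundle payload")
        values = np.frombuffer(payload, dtype="<f8")
    rate = float(meta.pop("rate_hz"))
    start = float(meta.pop("start_s", 0.0))
    return TimeSeries(values.copy(), rate, start_s=start, meta=meta)


def write_intervals(path: str | Path, intervals: IntervalSet,
                    delimiter: str = "\t") -> None:
    """One interval per row: onset_s, offset_s, duration_s."""
    arr = np.column_stack([intervals.onsets, intervals.offsets, intervals.durations])
    np.savetxt(path, arr, delimiter=delimiter,
               header=f"label={intervals.label}\nonset_s\toffset_s\tduration_s",
               comments="# ")


def read_intervals(path: str | Path, label: str = "up") -> IntervalSet:
    data = np.loadtxt(path, comments="#").reshape(-1, 3)
    return IntervalSet(data[:, :2], label=label)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ["simulate", "detect", "features", "decompose", "events",
                 "classify", "stats"]


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_KNOWN_STAGES))
    input_paths: list[str] = field(default_factory=list)
    rate_hz: float | None = None
    n_cells_per_region: int = 8
    n_animals: int = 4
    duration_s: float = 40.0
    sim_rate_hz: float = 1000.0
    k_sd: float = 0.5
    merge_gap_s: float = 0.25
    min_dur_s: float = 0.2
    smooth_window_s: float = 0.2
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in _KNOWN_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for p in cfg.input_paths:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "package_version": __version__}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages end to end on a synthetic cohort.

    simulate -> detect -> features -> (decompose) -> events -> classify
    -> stats.  Outputs land in ``config.out_dir`` with a provenance
    record (config hash, seed, package version) in every JSON artifact.
    Returns a summary dict of what each stage produced.
    """
    from .classify import cross_validate, fit_linear_svm, rfe_rank
    from .emd import hilbert_analytic, na_memd, select_swo_imf
    from .events import detect_events, dh_ratio_profile, pm_differentiate
    from .features import FEATURE_NAMES, aggregate_cohort, compute_up_features
    from .states import detect_up_states
    from .stats import batch_compare
    from .synthetic import DLS_LIKE_SPEC, DMS_LIKE_SPEC, generate_cohort

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"provenance": _provenance(config)}
    stages = config.stages

    try:
        traces, table, truths = generate_cohort(
            {"DLS": DLS_LIKE_SPEC, "DMS": DMS_LIKE_SPEC},
            n_cells_per_region=config.n_cells_per_region,
            n_animals=config.n_animals, seed=config.seed,
            duration_s=config.duration_s, rate_hz=config.sim_rate_hz)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    if "simulate" in stages:
        table.to_csv(out / "cohort_labels.tsv", sep="\t", index=False)
        summary["simulate"] = {"n_cells": len(table)}

    per_state = {}
    intervals = {}
    for cell_id, ts in zip(table["cell_id"], traces):
        try:
            iv = detect_up_states(ts, k_sd=config.k_sd,
                                  merge_gap_s=config.merge_gap_s,
                                  min_dur_s=config.min_dur_s,
                                  smooth_window_s=config.smooth_window_s)
        except Exception as exc:
            raise RuntimeError(f"stage 'detect' failed on {cell_id}: {exc}") from exc
        intervals[cell_id] = iv
        try:
            per_state[cell_id] = compute_up_features(ts, iv)
        except Exception as exc:
            raise RuntimeError(f"stage 'features' failed on {cell_id}: {exc}") from exc
    if "detect" in stages:
        write_intervals(out / "up_intervals_first_cell.tsv",
                        intervals[table["cell_id"].iloc[0]])
        summary["detect"] = {"mean_n_up": float(np.mean([len(v) for v in intervals.values()]))}

    cohort = aggregate_cohort(per_state, table)
    if "features" in stages:
        cohort.to_csv(out / "cohort_features.tsv", sep="\t", index=False)
        summary["features"] = {"n_cells": len(cohort)}

    if "decompose" in stages:
        ts = traces[0]
        try:
            dec = na_memd(ts.values[None, :], seed=config.seed, rate_hz=ts.rate_hz)
            idx, r = select_swo_imf(dec, ts.values)
        except Exception as exc:
            raise RuntimeError(f"stage 'decompose' failed: {exc}") from exc
        summary["decompose"] = {"n_imfs": dec.n_imfs, "swo_imf": idx, "swo_corr": r}
        np.savetxt(out / "imfs_first_cell.tsv", dec.imfs[0].T, delimiter="\t")

    if "events" in stages:
        ts = traces[0]
        try:
            d = pm_differentiate(ts, cutoff_hz=min(200.0, 0.45 * ts.rate_hz))
            train = detect_events(d)
            dec = na_memd(ts.values[None, :], seed=config.seed, rate_hz=ts.rate_hz)
            idx, _ = select_swo_imf(dec, ts.values)
            phase = hilbert_analytic(dec.imfs[0, idx], ts.rate_hz)
            prof = dh_ratio_profile(train.select(+1), train.select(-1), phase)
        except Exception as exc:
            raise RuntimeError(f"stage 'events' failed: {exc}") from exc
        summary["events"] = {"n_events": len(train),
                             "dh_peak_phase_deg": prof.peak_phase_deg}

    if "classify" in stages:
        feats = cohort[FEATURE_NAMES].fillna(cohort[FEATURE_NAMES].mean())
        labels = cohort["region"].to_numpy()
        try:
            k = min(10, min(pd.Series(labels).value_counts()))
            mu, sd, _ = cross_validate(feats, labels, k=k, seed=config.seed)
            rfe = rfe_rank(feats, labels, k=k, seed=config.seed, compute_curve=False)
            model = fit_linear_svm(feats, labels)
            model.to_json(out / "classifier.json")
        except Exception as exc:
            raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
        summary["classify"] = {"cv_accuracy_mean": mu, "cv_accuracy_sd": sd,
                               "rfe_top3": rfe.ranking[:3]}

    if "stats" in stages:
        groups = {r: cohort.loc[cohort["region"] == r, "f11_n_peaks"].to_numpy()
                  for r in cohort["region"].unique()}
        names = list(groups)
        try:
            stats_table = batch_compare({f"{names[0]}_vs_{names[1]}_n_peaks":
                                         (groups[names[0]], groups[names[1]])})
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
        stats_table.to_csv(out / "stats.tsv", sep="\t", index=False)
        summary["stats"] = {"comparisons": len(stats_table)}

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
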