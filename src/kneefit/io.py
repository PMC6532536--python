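"""File formats: trial archives, level-response tables, spike rasters, results.

All formats are plain text.  A trial archive is a directory holding one CSV
per stimulus intensity (rows = trials, columns = samples) plus a
no-stimulus CSV, tied together by ``manifest.json``.  Level-response tables
are two-column CSVs with a ``.noise.json`` sidecar carrying the measured
noise floor.  Result JSON documents carry ``schema_version`` for forward
compatibility.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .exceptions import DataFormatError, MissingNoiseDataError
from .fitting import FitResult
from .models import (
    HardSigmoidParams,
    LevelResponseCurve,
    LogisticParams,
    NOISE_MODES,
    NoiseModel,
)
from .resampling import ThresholdDistribution
from .experiments import SweepResult
from .signal import SpikeRaster
from .simulate import TrialBlock

SCHEMA_VERSION = 1
MANIFEST_NAME = "manifest.json"
_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


# ---------------------------------------------------------------------------
# trial archives

def write_trial_archive(
    blocks: Sequence[TrialBlock], path: Union[str, Path], units: str = "mV"
) -> Path:
    """Write blocks to a directory archive; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stim = [b for b in blocks if not b.is_no_stimulus]
    no_stim = [b for b in blocks if b.is_no_stimulus]
    if len(no_stim) != 1:
        raise DataFormatError(
            f"archive requires exactly one no-stimulus block, got {len(no_stim)}"
        )
    rates = {b.sampling_rate for b in blocks}
    windows = {b.window for b in blocks}
    if len(rates) > 1 or len(windows) > 1:
        raise DataFormatError("blocks disagree on sampling rate or analysis window")
    entries = []
    for i, blk in enumerate(stim):
        fname = f"stim_{i:03d}.csv"
        np.savetxt(path / fname, blk.traces, fmt=_FLOAT_FMT, delimiter=",")
        entries.append(
            {"intensity_db": blk.intensity, "file": fname, "phase": blk.phase}
        )
    np.savetxt(path / "no_stimulus.csv", no_stim[0].traces, fmt=_FLOAT_FMT, delimiter=",")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": float(next(iter(rates))),
        "units": units,
        "window_ms": list(next(iter(windows))),
        "blocks": entries,
        "no_stimulus": "no_stimulus.csv",
    }
    mpath = path / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def _read_trace_csv(fpath: Path) -> np.ndarray:
    rows: List[List[float]] = []
    with open(fpath, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise DataFormatError(f"{fpath.name}, row {lineno}: {exc}") from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise DataFormatError(
                    f"{fpath.name}, row {lineno}: ragged row of {len(rows[-1])} "
                    f"values (expected {len(rows[0])})"
                )
    if not rows:
        raise DataFormatError(f"{fpath.name}: empty trace file")
    return np.asarray(rows)


def read_trial_archive(path: Union[str, Path]) -> List[TrialBlock]:
    """Read a trial archive; the no-stimulus block comes last."""
    path = Path(path)
    mpath = path / MANIFEST_NAME if path.is_dir() else path
    if not mpath.exists():
        raise DataFormatError(f"no manifest found at {mpath}")
    manifest = json.loads(mpath.read_text())
    root = mpath.parent
    rate = float(manifest["sampling_rate"])
    window = tuple(manifest["window_ms"])
    seen = set()
    blocks = []
    for entry in manifest["blocks"]:
        key = (entry["intensity_db"], entry.get("phase", 0))
        if key in seen:
            raise DataFormatError(
                f"duplicate intensity {entry['intensity_db']} dB (phase "
                f"{entry.get('phase', 0)}) in manifest"
            )
        seen.add(key)
        fpath = root / entry["file"]
        if not fpath.exists():
            raise DataFormatError(f"missing trial file {fpath}")
        blocks.append(
            TrialBlock(
                intensity=float(entry["intensity_db"]),
                traces=_read_trace_csv(fpath),
                sampling_rate=rate,
                window=window,
                phase=int(entry.get("phase", 0)),
            )
        )
    if "no_stimulus" not in manifest or manifest["no_stimulus"] is None:
        raise MissingNoiseDataError(
            "manifest has no no-stimulus entry: the noise floor sigma must be "
            "measured from a no-stimulus recording (it is never fitted)"
        )
    ns_path = root / manifest["no_stimulus"]
    if not ns_path.exists():
        raise DataFormatError(f"missing no-stimulus file {ns_path}")
    blocks.append(
        TrialBlock(
            intensity=None, traces=_read_trace_csv(ns_path),
            sampling_rate=rate, window=window,
        )
    )
    return blocks


# ---------------------------------------------------------------------------
# level-response tables

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".noise.json")


def write_level_response_csv(curve: LevelResponseCurve, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intensity_db", "response"])
        for x, y in zip(curve.intensities, curve.responses):
            writer.writerow([_FLOAT_FMT % x, _FLOAT_FMT % y])
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "sigma": curve.noise.sigma,
        "mode": curve.noise.mode,
        "meta": curve.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_level_response_csv(
    path: Union[str, Path],
    sigma: Optional[float] = None,
    mode: Optional[str] = None,
) -> LevelResponseCurve:
    """Read an (intensity, response) table; rows are sorted and duplicate
    intensities averaged.

    The noise floor comes from explicit arguments, falling back to the
    ``.noise.json`` sidecar; with neither, reading fails — sigma is a
    measured input, never inferred from the curve.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        sc = json.loads(sidecar.read_text())
        sigma = sc["sigma"] if sigma is None else sigma
        mode = sc.get("mode") if mode is None else mode
        meta = sc.get("meta", {})
    if sigma is None:
        raise MissingNoiseDataError(
            f"no noise floor for {path.name}: pass sigma explicitly or provide "
            f"the {sidecar.name} sidecar (sigma is measured, never fitted)"
        )
    if mode is None:
        mode = "quadrature"
    if mode not in NOISE_MODES:
        raise DataFormatError(f"unknown noise mode {mode!r}")
    xs, ys = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["intensity_db", "response"]:
            raise DataFormatError(
                f"{path.name}: expected header 'intensity_db,response', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise DataFormatError(f"{path.name}, row {lineno}: expected 2 columns")
            try:
                xs.append(float(row[0]))
                ys.append(float(row[1]))
            except ValueError as exc:
                raise DataFormatError(f"{path.name}, row {lineno}: {exc}") from None
    return LevelResponseCurve(np.asarray(xs), np.asarray(ys), NoiseModel(mode, float(sigma)), meta)


# ---------------------------------------------------------------------------
# spike rasters

def write_spike_raster_csv(raster: SpikeRaster, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intensity_db", "trial", "spike_time_ms"])
        for x, tr, tm in zip(raster.intensity, raster.trial, raster.time_ms):
            writer.writerow(["" if not np.isfinite(x) else _FLOAT_FMT % x, tr, _FLOAT_FMT % tm])
    return path


def read_spike_raster_csv(
    path: Union[str, Path],
    n_trials: int,
    analysis_window=(0.0, 200.0),
    spontaneous_window=None,
) -> SpikeRaster:
    """Read (intensity_db, trial, spike_time_ms) events.

    An empty intensity cell marks a no-stimulus trial.
    """
    path = Path(path)
    xs, trs, tms = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        expect = ["intensity_db", "trial", "spike_time_ms"]
        if header is None or [h.strip().lower() for h in header[:3]] != expect:
            raise DataFormatError(
                f"{path.name}: expected header {','.join(expect)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise DataFormatError(f"{path.name}, row {lineno}: expected 3 columns")
            try:
                xs.append(float("nan") if row[0].strip() == "" else float(row[0]))
                trs.append(int(row[1]))
                tms.append(float(row[2]))
            except ValueError as exc:
                raise DataFormatError(f"{path.name}, row {lineno}: {exc}") from None
    return SpikeRaster(
        intensity=np.asarray(xs), trial=np.asarray(trs), time_ms=np.asarray(tms),
        n_trials=n_trials, analysis_window=tuple(analysis_window),
        spontaneous_window=None if spontaneous_window is None else tuple(spontaneous_window),
    )


# ---------------------------------------------------------------------------
# results

def params_to_dict(params) -> dict:
    d = asdict(params)
    d["family"] = "logistic" if isinstance(params, LogisticParams) else "hard_sigmoid"
    return d


def params_from_dict(d: dict):
    family = d.get("family")
    if family == "logistic":
        return LogisticParams(a=d["a"], b=d["b"], c=d["c"])
    if family == "hard_sigmoid":
        return HardSigmoidParams(t=d["t"], s=d["s"], h=d["h"])
    raise DataFormatError(f"unknown model family {family!r}")


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model": fit.model,
        "params": params_to_dict(fit.params),
        "noise": {"mode": fit.noise.mode, "sigma": fit.noise.sigma},
        "rss": fit.rss,
        "converged": fit.converged,
        "extrapolated": fit.extrapolated,
        "n_points": fit.n_points,
    }


def distribution_to_dict(dist: ThresholdDistribution) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "values": [None if not np.isfinite(v) else float(v) for v in dist.values],
        "n_defined": dist.n_defined,
        "summary": {k: (None if not np.isfinite(v) else float(v)) for k, v in dist.summary.items()},
    }


def sweep_to_dict(sweep: SweepResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "axis": [float(v) for v in sweep.axis],
        "config": sweep.config,
        "distributions": [distribution_to_dict(d) for d in sweep.distributions],
    }


def write_result_json(obj: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    if "schema_version" not in obj:
        obj = {"schema_version": SCHEMA_VERSION, **obj}
    path.write_text(json.dumps(obj, indent=1))
    return path
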