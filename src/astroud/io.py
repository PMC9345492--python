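"""File I/O: tabular CSV outputs with JSON sidecars carrying full provenance.

Every data file ``<path>`` is written together with ``<path>.json`` holding
the parameters, seed and package version needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rate_model import RateParams, RateTrajectory
from .segmentation import PhaseSegmentation, PhaseStats, RateSeries
from .spiking_model import SpikeRaster, SpikingParams

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_raster",
    "read_raster",
    "write_series",
    "read_series",
    "write_intervals",
    "write_stats",
    "write_manifest",
]

_POP_NAMES = np.array(["E", "I", "A"])


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _sidecar(path: Path, payload: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=1, default=str)


def write_trajectory(traj: RateTrajectory, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"t_ms": traj.t, "r_E": traj.r_E, "r_I": traj.r_I, "r_A": traj.r_A, "a": traj.a}
    )
    df.to_csv(path, index=False)
    _sidecar(path, {"kind": "rate-trajectory", "dt": traj.dt, "seed": traj.seed, "params": traj.params})


def read_trajectory(path) -> RateTrajectory:
    path = Path(path)
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    params = RateParams(**meta["params"]) if meta.get("params") else None
    t = df["t_ms"].to_numpy()
    dt = meta.get("dt", float(t[1] - t[0]) if len(t) > 1 else 1.0)
    return RateTrajectory(
        dt=dt,
        t=t,
        r_E=df["r_E"].to_numpy(),
        r_I=df["r_I"].to_numpy(),
        r_A=df["r_A"].to_numpy(),
        a=df["a"].to_numpy(),
        xi=np.zeros((len(df), 3)),
        params=params,
        seed=meta.get("seed"),
    )


def write_raster(raster: SpikeRaster, path, params: SpikingParams | None = None, seed=None, connectivity=None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "population": _POP_NAMES[raster.population],
            "cell_id": raster.cell,
            "t_ms": raster.t_ms,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "kind": "spike-raster",
        "n_E": raster.n_E,
        "n_I": raster.n_I,
        "n_A": raster.n_A,
        "duration": raster.duration,
        "seed": seed,
        "params": params,
    }
    if connectivity is not None:
        meta["connectivity"] = {
            "n_glio_E": connectivity.n_glio_E,
            "n_glio_I": connectivity.n_glio_I,
            "n_astro_in": connectivity.n_astro_in,
        }
    _sidecar(path, meta)


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    codes = {"E": 0, "I": 1, "A": 2}
    pop = df["population"].map(codes).to_numpy(dtype=np.int8)
    return SpikeRaster(
        population=pop,
        cell=df["cell_id"].to_numpy(dtype=np.int32),
        t_ms=df["t_ms"].to_numpy(dtype=float),
        n_E=meta["n_E"],
        n_I=meta["n_I"],
        n_A=meta["n_A"],
        duration=meta["duration"],
    )


def write_series(series: RateSeries, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"t_ms": series.times, "rate_hz": series.values}).to_csv(path, index=False)
    meta = {"kind": "rate-series", "step": series.step, "t0": series.t0, "provenance": series.provenance}
    meta.update(extra_meta or {})
    _sidecar(path, meta)


def read_series(path) -> RateSeries:
    path = Path(path)
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return RateSeries(
        step=meta["step"],
        values=df["rate_hz"].to_numpy(),
        t0=meta.get("t0", 0.0),
        provenance=meta.get("provenance", ""),
    )


def write_intervals(seg: PhaseSegmentation, path) -> None:
    path = Path(path)
    rows = [
        {"label": iv.label, "start_ms": iv.start, "end_ms": iv.end, "retained": iv.retained}
        for iv in seg.intervals
    ]
    pd.DataFrame(rows, columns=["label", "start_ms", "end_ms", "retained"]).to_csv(path, index=False)
    _sidecar(path, {"kind": "phase-intervals", "threshold": seg.threshold, "step": seg.step, "span": seg.span})


def write_stats(stats: PhaseStats, path) -> None:
    payload = {}
    for label in ("up", "down"):
        s = getattr(stats, label)
        payload[label] = {
            "count": s.count,
            "mean_ms": s.mean,
            "std_ms": s.std,
            "cv": s.cv,
            "durations_ms": s.durations,
        }
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=1)


def write_manifest(path, **entries) -> None:
    """Run manifest: everything needed to reproduce the outputs of one run."""
    from . import __version__

    payload = {"astroud_version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=1, default=str)
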