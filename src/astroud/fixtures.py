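"""Synthetic test fixtures with known ground truth.

Three fixture kinds back the segmentation and I/O tests: square-wave rate
traces (known phase boundaries), homogeneous Poisson rasters (known rate)
and single-event rasters.  Each generator returns the data together with a
ground-truth record, and is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import RateSeries
from .spiking_model import SpikeRaster

__all__ = [
    "FixtureSpec",
    "square_wave_trace",
    "poisson_raster",
    "single_event_raster",
    "generate_fixture",
]


@dataclass
class FixtureSpec:
    kind: str  # "square-wave" | "poisson-raster" | "single-event"
    seed: int = 0
    params: dict = field(default_factory=dict)


def square_wave_trace(
    period_ms: float = 2000.0,
    duty: float = 0.5,
    high_hz: float = 5.0,
    low_hz: float = 0.0,
    n_cycles: int = 10,
    step_ms: float = 1.0,
    lead_ms: float | None = None,
) -> tuple[RateSeries, dict]:
    """Square wave alternating ``high_hz`` (fraction ``duty`` of the period)
    and ``low_hz``, preceded and followed by a half-period of the low level
    so the interior phases are retained by the segmentation.

    Ground truth lists the interior Up/Down durations in ms.
    """
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    up_ms = duty * period_ms
    down_ms = (1 - duty) * period_ms
    if lead_ms is None:
        lead_ms = down_ms
    n_lead = int(round(lead_ms / step_ms))
    n_up = int(round(up_ms / step_ms))
    n_down = int(round(down_ms / step_ms))
    chunks = [np.full(n_lead, low_hz)]
    for _ in range(n_cycles):
        chunks.append(np.full(n_up, high_hz))
        chunks.append(np.full(n_down, low_hz))
    values = np.concatenate(chunks)
    truth = {
        "up_durations_ms": [n_up * step_ms] * n_cycles,
        "down_durations_ms": [n_down * step_ms] * (n_cycles - 1),
        "n_cycles": n_cycles,
        "high_hz": high_hz,
        "low_hz": low_hz,
        "step_ms": step_ms,
    }
    return RateSeries(step=step_ms, values=values, provenance="fixture square-wave"), truth


def poisson_raster(
    rate_hz: float = 3.0,
    n_neurons: int = 100,
    duration_ms: float = 10_000.0,
    seed: int = 0,
    n_E: int | None = None,
) -> tuple[SpikeRaster, dict]:
    """Homogeneous Poisson spikes at ``rate_hz`` per neuron.

    Neurons are split between the E and I populations (``n_E`` defaults to
    80%); no astrocyte events.
    """
    rng = np.random.default_rng(seed)
    if n_E is None:
        n_E = int(round(0.8 * n_neurons))
    n_I = n_neurons - n_E
    lam = rate_hz * 1e-3 * duration_ms
    counts = rng.poisson(lam, size=n_neurons)
    cells = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0.0, duration_ms, size=counts.sum())
    pops = np.where(cells < n_E, 0, 1).astype(np.int8)
    cell_ids = np.where(cells < n_E, cells, cells - n_E).astype(np.int32)
    order = np.argsort(times)
    raster = SpikeRaster(
        population=pops[order],
        cell=cell_ids[order],
        t_ms=times[order],
        n_E=n_E,
        n_I=n_I,
        n_A=0,
        duration=duration_ms,
    )
    truth = {
        "rate_hz": rate_hz,
        "expected_total_spikes": rate_hz * n_neurons * duration_ms * 1e-3,
        "actual_total_spikes": int(counts.sum()),
    }
    return raster, truth


def single_event_raster(
    population: str = "E",
    cell: int = 0,
    t_ms: float = 100.0,
    n_E: int = 10,
    n_I: int = 5,
    n_A: int = 5,
    duration_ms: float = 1000.0,
) -> tuple[SpikeRaster, dict]:
    """Raster with exactly one event."""
    codes = {"E": 0, "I": 1, "A": 2}
    raster = SpikeRaster(
        population=np.array([codes[population]], dtype=np.int8),
        cell=np.array([cell], dtype=np.int32),
        t_ms=np.array([t_ms]),
        n_E=n_E,
        n_I=n_I,
        n_A=n_A,
        duration=duration_ms,
    )
    return raster, {"population": population, "cell": cell, "t_ms": t_ms}


def generate_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns (data, ground_truth)."""
    if spec.kind == "square-wave":
        return square_wave_trace(**spec.params)
    if spec.kind == "poisson-raster":
        return poisson_raster(seed=spec.seed, **spec.params)
    if spec.kind == "single-event":
        return single_event_raster(**spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
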