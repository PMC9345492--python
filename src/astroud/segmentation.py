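"""Automatic segmentation of Up and Down phases.

Pipeline used to quantify both simulators: (1) estimate the mean population
rate from a spike raster with a 10 ms sliding window counting E and I spikes
only; (2) smooth with a running median over +/- 50 points; (3) threshold at
1.0 Hz - an upward crossing opens an Up phase, a downward crossing a Down
phase; (4) discard the first and last phases and compute duration statistics
of the retained ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RateSeries",
    "PhaseInterval",
    "PhaseSegmentation",
    "PhaseStats",
    "LabelStats",
    "raster_to_rate",
    "median_smooth",
    "segment_phases",
    "phase_statistics",
    "series_from_trajectory",
    "segment_series",
]


@dataclass
class RateSeries:
    """Uniformly sampled mean population rate (Hz per neuron)."""

    step: float  # ms
    values: np.ndarray
    t0: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.step <= 0:
            raise ValueError("step must be positive")
        if np.any(self.values < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(len(self.values))


@dataclass
class PhaseInterval:
    label: str  # "Up" or "Down"
    start: float  # ms
    end: float  # ms
    retained: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PhaseSegmentation:
    intervals: list[PhaseInterval]
    threshold: float
    step: float
    span: tuple[float, float]

    def retained(self, label: str | None = None) -> list[PhaseInterval]:
        out = [iv for iv in self.intervals if iv.retained]
        if label is not None:
            out = [iv for iv in out if iv.label == label]
        return out

    def durations(self, label: str) -> np.ndarray:
        return np.array([iv.duration for iv in self.retained(label)])


@dataclass
class LabelStats:
    count: int
    mean: float
    std: float
    cv: float
    durations: np.ndarray = field(repr=False, default=None)
    hist_counts: np.ndarray = field(repr=False, default=None)
    hist_edges: np.ndarray = field(repr=False, default=None)


@dataclass
class PhaseStats:
    up: LabelStats
    down: LabelStats


def raster_to_rate(raster, window: float = 10.0, step: float = 1.0) -> RateSeries:
    """Mean population rate from a spike raster, neurons only.

    ``rate(t)`` counts the spikes of all E and I cells in
    ``[t - window/2, t + window/2)`` divided by ``window * (N_E + N_I)``,
    reported in Hz per neuron.  Astrocyte release events are excluded.
    An empty raster gives an all-zero series.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    neuronal = raster.t_ms[raster.population < 2]
    times = np.sort(neuronal)
    grid = np.arange(0.0, raster.duration + 0.5 * step, step)
    lo = np.searchsorted(times, grid - window / 2.0, side="left")
    hi = np.searchsorted(times, grid + window / 2.0, side="left")
    n_norm = raster.n_E + raster.n_I
    rate = (hi - lo) / (window * 1e-3 * n_norm)
    return RateSeries(step=step, values=rate, provenance=f"raster window={window}ms")


def median_smooth(series: RateSeries, half_width: int = 50) -> RateSeries:
    """Centered running median over +/- ``half_width`` points.

    The window is truncated at the series boundaries (no padding), so a
    constant series is returned unchanged and the filter is idempotent on it.
    """
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    if half_width == 0 or len(series.values) == 0:
        return RateSeries(series.step, series.values.copy(), series.t0, series.provenance)
    smoothed = (
        pd.Series(series.values)
        .rolling(window=2 * half_width + 1, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return RateSeries(series.step, smoothed, series.t0, series.provenance + "|median")


def segment_phases(series: RateSeries, threshold: float = 1.0) -> PhaseSegmentation:
    """Threshold segmentation of a (smoothed) rate series.

    A sample with value >= ``threshold`` is in the Up state (equality counts
    as Up).  A change of state between consecutive samples places the phase
    boundary at the first sample of the new state.  The first and last
    phases are kept in the interval list but flagged ``retained=False``.
    """
    v = series.values
    n = len(v)
    t0 = series.t0
    step = series.step
    span = (t0, t0 + n * step)
    if n == 0:
        return PhaseSegmentation([], threshold, step, span)
    up = v >= threshold
    change = np.flatnonzero(up[1:] != up[:-1]) + 1  # index of first sample of new phase
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    intervals = []
    for k, (i, j) in enumerate(zip(starts, ends)):
        intervals.append(
            PhaseInterval(
                label="Up" if up[i] else "Down",
                start=t0 + i * step,
                end=t0 + j * step,
                retained=(k != 0 and k != len(starts) - 1),
            )
        )
    return PhaseSegmentation(intervals, threshold, step, span)


def _label_stats(durations: np.ndarray, bin_width: float) -> LabelStats:
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        return LabelStats(0, np.nan, np.nan, np.nan, durations, np.array([]), np.array([]))
    mean = float(np.mean(durations))
    std = float(np.std(durations))  # population convention (divisor n)
    cv = std / mean if mean > 0 else np.nan
    hi = max(bin_width, durations.max())
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(durations, bins=edges)
    return LabelStats(len(durations), mean, std, cv, durations, counts, edges)


def phase_statistics(seg: PhaseSegmentation, bin_width: float = 100.0) -> PhaseStats:
    """Duration statistics (count, mean, std, CV, histogram) per label."""
    return PhaseStats(
        up=_label_stats(seg.durations("Up"), bin_width),
        down=_label_stats(seg.durations("Down"), bin_width),
    )


def series_from_trajectory(traj, resample_ms: float = 1.0) -> RateSeries:
    """r_E of a rate-model trajectory as a RateSeries at ~``resample_ms`` step.

    The trajectory is decimated (no interpolation); ``resample_ms`` must be a
    multiple of the trajectory sampling step.
    """
    stride = max(1, int(round(resample_ms / traj.dt)))
    vals = np.maximum(traj.r_E[::stride], 0.0)
    return RateSeries(step=traj.dt * stride, values=vals, t0=traj.t[0], provenance="rate-model r_E")


def segment_series(
    series: RateSeries, half_width: int = 50, threshold: float = 1.0
) -> tuple[PhaseSegmentation, PhaseStats]:
    """Smooth + segment + statistics in one call."""
    seg = segment_phases(median_smooth(series, half_width), threshold)
    return seg, phase_statistics(seg)
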