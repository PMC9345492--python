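"""Segmentation tests: rate estimation, median smoothing, thresholding and
duration statistics, with constructed-truth fixtures as oracles."""

import numpy as np
import pytest

from astroud.fixtures import poisson_raster, single_event_raster, square_wave_trace
from astroud.segmentation import (
    RateSeries,
    median_smooth,
    phase_statistics,
    raster_to_rate,
    segment_phases,
    segment_series,
)


class TestRasterToRate:
    def test_empty_raster_gives_zero_series(self):
        raster, _ = poisson_raster(rate_hz=0.0, n_neurons=50, duration_ms=1000.0, seed=0)
        series = raster_to_rate(raster)
        assert np.all(series.values == 0.0)
        assert len(series.values) == 1001

    def test_poisson_rate_recovered(self):
        raster, truth = poisson_raster(rate_hz=3.0, n_neurons=400, duration_ms=20_000.0, seed=1)
        series = raster_to_rate(raster)
        # interior samples (full windows); sampling error ~ sqrt(rate/(N*T))
        interior = series.values[10:-10]
        assert interior.mean() == pytest.approx(3.0, rel=0.05)

    def test_astrocyte_events_excluded(self):
        raster, _ = poisson_raster(rate_hz=2.0, n_neurons=100, duration_ms=2000.0, seed=2)
        with_astro = raster
        # append astrocyte release events on top
        n_extra = 500
        rng = np.random.default_rng(3)
        pop = np.concatenate([raster.population, np.full(n_extra, 2, dtype=np.int8)])
        cell = np.concatenate([raster.cell, rng.integers(0, 10, n_extra, dtype=np.int32)])
        t = np.concatenate([raster.t_ms, rng.uniform(0, 2000.0, n_extra)])
        from astroud.spiking_model import SpikeRaster

        noisy = SpikeRaster(pop, cell, t, raster.n_E, raster.n_I, 10, raster.duration)
        assert np.array_equal(raster_to_rate(with_astro).values, raster_to_rate(noisy).values)

    def test_single_event_window_normalisation(self):
        raster, _ = single_event_raster(t_ms=100.0, n_E=10, n_I=5)
        series = raster_to_rate(raster, window=10.0, step=1.0)
        # the event contributes 1/(0.01 s * 15 cells) inside its 10 ms window
        assert series.values.max() == pytest.approx(1 / (0.010 * 15))
        assert np.sum(series.values > 0) == 10


class TestMedianSmooth:
    def test_constant_series_unchanged(self):
        s = RateSeries(step=1.0, values=np.full(500, 2.5))
        assert np.array_equal(median_smooth(s).values, s.values)

    def test_single_spike_removed(self):
        v = np.zeros(300)
        v[150] = 100.0
        out = median_smooth(RateSeries(step=1.0, values=v))
        assert np.all(out.values == 0.0)

    def test_matches_brute_force_truncated_median(self, rng):
        v = rng.gamma(2.0, 2.0, size=200)
        hw = 7
        out = median_smooth(RateSeries(step=1.0, values=v), half_width=hw)
        brute = np.array(
            [np.median(v[max(0, i - hw): i + hw + 1]) for i in range(len(v))]
        )
        assert np.allclose(out.values, brute)

    def test_step_edge_shift_bounded(self):
        v = np.concatenate([np.zeros(300), np.full(300, 5.0)])
        out = median_smooth(RateSeries(step=1.0, values=v), half_width=50)
        crossing = np.argmax(out.values >= 2.5)
        assert abs(crossing - 300) <= 50 + 1


class TestSegmentPhases:
    def test_all_zero_series_has_no_retained_phases(self):
        seg = segment_phases(RateSeries(step=1.0, values=np.zeros(1000)))
        assert len(seg.retained()) == 0
        assert len(seg.intervals) == 1 and not seg.intervals[0].retained

    def test_square_wave_durations_exact(self):
        series, truth = square_wave_trace(period_ms=2000.0, duty=0.5, high_hz=5.0, n_cycles=10)
        seg, stats = segment_series(series)
        assert stats.up.count == 10
        assert stats.up.durations == pytest.approx(truth["up_durations_ms"])
        assert stats.down.count == 9
        assert stats.down.mean == pytest.approx(1000.0)

    def test_first_and_last_phases_flagged_discarded(self):
        series, _ = square_wave_trace(n_cycles=3)
        seg = segment_phases(series)
        assert not seg.intervals[0].retained
        assert not seg.intervals[-1].retained
        assert all(iv.retained for iv in seg.intervals[1:-1])

    def test_equality_counts_as_up(self):
        v = np.array([0.0, 1.0, 1.0, 0.0])
        seg = segment_phases(RateSeries(step=1.0, values=v), threshold=1.0)
        labels = [iv.label for iv in seg.intervals]
        assert labels == ["Down", "Up", "Down"]

    @pytest.mark.parametrize("k", range(15))
    def test_randomized_square_waves_recovered_within_one_step(self, k):
        rng = np.random.default_rng(1000 + k)
        period = rng.uniform(600.0, 4000.0)
        duty = rng.uniform(0.25, 0.75)
        series, truth = square_wave_trace(
            period_ms=period, duty=duty, high_hz=rng.uniform(2.0, 20.0),
            n_cycles=int(rng.integers(4, 9)),
        )
        seg, stats = segment_series(series)
        assert stats.up.count == truth["n_cycles"]
        assert np.allclose(stats.up.durations, truth["up_durations_ms"], atol=series.step)
        assert np.allclose(stats.down.durations, truth["down_durations_ms"], atol=series.step)

    def test_tiling_and_alternation(self, rng):
        v = np.abs(rng.normal(1.0, 1.0, size=5000))
        seg = segment_phases(median_smooth(RateSeries(step=1.0, values=v)))
        total = sum(iv.duration for iv in seg.intervals)
        assert total == pytest.approx(seg.span[1] - seg.span[0])
        labels = [iv.label for iv in seg.intervals]
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_threshold_monotonicity(self, rng):
        v = np.abs(rng.normal(1.0, 1.0, size=3000))
        s = median_smooth(RateSeries(step=1.0, values=v))
        up_time = []
        for th in (0.5, 1.0, 1.5, 2.0):
            seg = segment_phases(s, threshold=th)
            up_time.append(sum(iv.duration for iv in seg.intervals if iv.label == "Up"))
        assert all(a >= b for a, b in zip(up_time, up_time[1:]))


class TestPhaseStatistics:
    def test_constant_durations(self):
        series, _ = square_wave_trace(period_ms=2000.0, duty=0.5, n_cycles=3)
        _, stats = segment_series(series)
        assert stats.up.mean == pytest.approx(1000.0)
        assert stats.up.cv == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        # durations {500, 1500}: mean 1000, population std 500, CV 0.5
        v = np.concatenate(
            [np.zeros(300), np.full(500, 5.0), np.zeros(400), np.full(1500, 5.0), np.zeros(300)]
        )
        seg = segment_phases(RateSeries(step=1.0, values=v))
        stats = phase_statistics(seg)
        assert stats.up.count == 2
        assert stats.up.mean == pytest.approx(1000.0)
        assert stats.up.std == pytest.approx(500.0)
        assert stats.up.cv == pytest.approx(0.5)

    def test_empty_stats_have_zero_count(self):
        seg = segment_phases(RateSeries(step=1.0, values=np.zeros(100)))
        stats = phase_statistics(seg)
        assert stats.up.count == 0 and np.isnan(stats.up.mean)
        assert stats.down.count == 0

    def test_histogram_covers_durations(self):
        series, _ = square_wave_trace(period_ms=2000.0, duty=0.5, n_cycles=5)
        _, stats = segment_series(series)
        assert stats.up.hist_counts.sum() == stats.up.count
        assert stats.up.hist_edges[-1] >= max(stats.up.durations)
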