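"""Phase maps, depolarization times, wave axes and their variability."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from islet3d import (
    depolarization_times,
    early_late_time_lag,
    generate_islet,
    phase_map,
    rotate_axis,
    segment_dataset,
    wave_axis,
    wave_axis_variability,
)
from islet3d.segmentation import OscillationSegment
from conftest import small_config


def _whole_trace_segment(n_frames, period=None):
    seg = OscillationSegment(
        index=0, peak_frame=n_frames // 2, window_start=0, window_end=n_frames - 1,
        depol_start=0, depol_end=1, repol_start=n_frames - 2, repol_end=n_frames - 1,
    )
    if period is not None:
        seg.period = period
    return seg


def _bump(t, center, width=8.0):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestPhaseMap:
    def test_delayed_copy_gets_positive_phase(self):
        fs = 2.0
        t = np.arange(240) / fs
        base = _bump(t, 60.0)
        traces = np.vstack([np.tile(base, (20, 1)), np.roll(base, 6)[None, :]])
        pm = phase_map(traces, _whole_trace_segment(240, period=60.0), fs)
        assert pm.phase[-1] == pytest.approx(6 / fs)
        np.testing.assert_allclose(pm.phase[:-1], 0.0)

    def test_advanced_copy_gets_negated_phase(self):
        fs = 2.0
        t = np.arange(240) / fs
        base = _bump(t, 60.0)
        traces = np.vstack([np.tile(base, (20, 1)), np.roll(base, -6)[None, :]])
        pm = phase_map(traces, _whole_trace_segment(240, period=60.0), fs)
        assert pm.phase[-1] == pytest.approx(-6 / fs)

    def test_identical_cells_all_zero_phase(self, rng):
        base = rng.normal(size=100).cumsum()
        traces = np.tile(base, (5, 1))
        pm = phase_map(traces, _whole_trace_segment(100, period=20.0), 1.0)
        np.testing.assert_array_equal(pm.phase, 0.0)

    def test_noiseless_phases_match_imposed_lags(self, noiseless_islet):
        dataset, truth = noiseless_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        for seg in segments:
            if seg.incomplete:
                continue
            pm = phase_map(dataset.traces, seg, dataset.sampling_rate)
            rec = pm.phase - pm.phase.mean()
            imp = truth.lags[seg.index] - truth.lags[seg.index].mean()
            assert np.max(np.abs(rec - imp)) <= 1.0 / dataset.sampling_rate

    def test_zero_variance_cell_flagged(self, rng):
        base = _bump(np.arange(120) / 2.0, 30.0)
        traces = np.vstack([np.tile(base, (5, 1)), np.zeros(120)])
        with pytest.warns(UserWarning, match="zero-variance"):
            pm = phase_map(traces, _whole_trace_segment(120, period=30.0), 2.0)
        assert np.isnan(pm.phase[-1])
        assert 5 not in np.concatenate([pm.early_set, pm.late_set])

    def test_early_set_leads_late_set(self, noiseless_islet):
        dataset, _ = noiseless_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        pm = phase_map(dataset.traces, segments[1], dataset.sampling_rate)
        lag = early_late_time_lag(pm)
        assert lag >= 0
        idx_early = np.isin(pm.cell_ids, pm.early_set)
        idx_late = np.isin(pm.cell_ids, pm.late_set)
        assert np.nanmean(pm.phase[idx_early]) <= np.nanmean(pm.phase[idx_late])


class TestDepolarizationTimes:
    def test_square_pulse_crossing_time(self):
        fs = 2.0
        t = np.arange(120) / fs
        trace = (t >= 10.0).astype(float)
        times, _ = depolarization_times(trace[None, :], _whole_trace_segment(120), fs)
        assert times[0] == pytest.approx(10.0, abs=0.5 / fs)

    def test_linear_ramp_crosses_at_midpoint(self):
        fs = 1.0
        trace = np.concatenate([np.linspace(0, 1, 21), np.ones(10)])
        times, _ = depolarization_times(
            trace[None, :], _whole_trace_segment(trace.size), fs
        )
        assert times[0] == pytest.approx(10.0, abs=1e-9)

    def test_ordering_matches_imposed_lags(self, noiseless_islet):
        dataset, truth = noiseless_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        seg = segments[1]
        times, first = depolarization_times(
            dataset.traces, seg, dataset.sampling_rate
        )
        rho = spearmanr(times, truth.lags[seg.index]).statistic
        assert rho > 0.999
        # earliest 10% coincide with the smallest imposed lags
        k = len(first)
        truly_first = np.argsort(truth.lags[seg.index], kind="stable")[:k]
        assert len(np.intersect1d(first, truly_first)) >= k - 1

    def test_non_crossing_cells_flagged(self):
        fs = 1.0
        t = np.arange(50, dtype=float)
        traces = np.vstack([(t >= 10).astype(float), np.zeros(50)])
        with pytest.warns(UserWarning, match="never cross"):
            times, _ = depolarization_times(traces, _whole_trace_segment(50), fs)
        assert np.isnan(times[1])


class TestWaveAxis:
    def test_polar_clusters_give_axis_early_to_late(self, rng):
        early_pts = np.array([50.0, 0, 0]) + rng.normal(scale=3, size=(8, 3))
        late_pts = np.array([-50.0, 0, 0]) + rng.normal(scale=3, size=(8, 3))
        positions = np.vstack([early_pts, late_pts])
        ids = np.arange(16)
        axis, excluded = wave_axis(positions, ids[:8], ids[8:])
        assert excluded.size == 0
        assert axis[0] < -0.99  # points from the early (+x) toward the late (-x) pole

    def test_outlier_beyond_50um_excluded(self, rng):
        early_pts = np.array([40.0, 0, 0]) + rng.normal(scale=2, size=(6, 3))
        early_pts = np.vstack([early_pts, [120.0, 80.0, 0.0]])  # ~60+ um from COG
        late_pts = np.array([-40.0, 0, 0]) + rng.normal(scale=2, size=(6, 3))
        positions = np.vstack([early_pts, late_pts])
        ids = np.arange(13)
        axis, excluded = wave_axis(positions, ids[:7], ids[7:])
        assert 6 in excluded

    def test_noiseless_axis_recovery_single_islet(self):
        # A single islet's PCA axis carries a few degrees of sampling error
        # from the 10% subpopulation draw; the median over many islets is
        # tighter (see the acceptance suite).
        axis_z = np.tile([0.0, 0.0, 1.0], (2, 1))
        cfg = small_config(
            n_cells=150, islet_radius=45.0, n_oscillations=2,
            wave_axis_schedule=axis_z, seed=29,
        ).noiseless()
        dataset, truth = generate_islet(cfg)
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        pm = phase_map(dataset.traces, segments[0], dataset.sampling_rate)
        axis, _ = wave_axis(dataset.positions, pm.early_set, pm.late_set, dataset.cell_ids)
        angle = np.degrees(np.arccos(np.clip(np.abs(axis @ [0, 0, 1.0]), -1, 1)))
        assert angle < 10.0
        assert axis @ [0, 0, 1.0] > 0  # early cells at low z-projection lead

    def test_positive_phase_gradient_along_axis(self, noiseless_islet):
        dataset, _ = noiseless_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        pm = phase_map(dataset.traces, segments[1], dataset.sampling_rate)
        axis, _ = wave_axis(dataset.positions, pm.early_set, pm.late_set, dataset.cell_ids)
        proj = dataset.positions @ axis
        assert np.corrcoef(proj, pm.phase)[0, 1] > 0

    def test_losing_a_whole_set_raises(self):
        positions = np.array([[0.0, 0, 0], [200.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="no cells"):
            wave_axis(positions, np.array([9]), np.array([2, 3]))


class TestAxisVariability:
    def test_identical_axes_change_zero(self, rng):
        positions = rng.normal(size=(40, 3)) * 30
        axes = np.tile([1.0, 0, 0], (3, 1))
        result = wave_axis_variability(axes, positions, set_size=4, n_resamples=200, seed=1)
        np.testing.assert_array_equal(result.raw_change, 0.0)
        np.testing.assert_array_equal(result.normalized_change, 0.0)

    def test_orthogonal_axes_raw_change_two(self, rng):
        positions = rng.normal(size=(40, 3)) * 30
        axes = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        result = wave_axis_variability(axes, positions, set_size=4, n_resamples=200, seed=1)
        assert result.raw_change[0] == pytest.approx(2.0)
        assert 0.0 <= result.normalized_change[0]

    def test_single_axis_rejected(self, rng):
        with pytest.raises(ValueError, match="2 oscillations"):
            wave_axis_variability(
                np.array([[1.0, 0, 0]]), rng.normal(size=(10, 3)), set_size=2
            )

    def test_resampling_deterministic_in_seed(self, rng):
        positions = rng.normal(size=(50, 3)) * 30
        axes = np.array([[1.0, 0, 0], [0, 0, 1.0]])
        a = wave_axis_variability(axes, positions, set_size=5, n_resamples=300, seed=9)
        b = wave_axis_variability(axes, positions, set_size=5, n_resamples=300, seed=9)
        assert a.normalizer == b.normalizer


class TestWaveSpeedScaling:
    def test_halving_wave_speed_doubles_early_late_lag(self):
        lags = {}
        for speed in (10.0, 5.0):
            cfg = small_config(
                n_cells=120, islet_radius=45.0, wave_speed=speed, seed=31
            ).noiseless()
            dataset, _ = generate_islet(cfg)
            segments, _ = segment_dataset(dataset, min_separation=50.0)
            pm = phase_map(dataset.traces, segments[1], dataset.sampling_rate)
            lags[speed] = early_late_time_lag(pm)
        assert lags[5.0] == pytest.approx(2.0 * lags[10.0], rel=0.10)
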