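"""Functional networks: correlation, fixed-degree calibration, spatial stats."""

import numpy as np
import pytest

from islet3d import (
    build_islet_networks,
    build_network,
    calibrate_threshold,
    generate_islet,
    pairwise_correlation,
    retention_rate,
    segment_dataset,
    spatial_stats,
)
from conftest import small_config


def pearson_oracle(a, b):
    """Textbook covariance / SD formula, term by term."""
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    sa = (sum((x - ma) ** 2 for x in a) / n) ** 0.5
    sb = (sum((y - mb) ** 2 for y in b) / n) ** 0.5
    return cov / (sa * sb)


class TestPairwiseCorrelation:
    def test_identical_and_negated_traces(self, rng):
        base = rng.normal(size=30)
        traces = np.vstack([base, base, -base])
        corr, flagged = pairwise_correlation(traces)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert flagged.size == 0

    def test_matches_textbook_oracle(self, rng):
        traces = rng.normal(size=(5, 20))
        corr, _ = pairwise_correlation(traces)
        for i in range(5):
            for j in range(5):
                assert corr[i, j] == pytest.approx(
                    pearson_oracle(traces[i], traces[j]), abs=1e-12
                )

    def test_zero_variance_cell_flagged_and_zeroed(self, rng):
        traces = np.vstack([rng.normal(size=20), np.full(20, 3.0)])
        corr, flagged = pairwise_correlation(traces)
        assert flagged.tolist() == [1]
        assert corr[0, 1] == 0.0 and corr[1, 1] == 1.0

    def test_short_window_rejected(self, rng):
        with pytest.raises(ValueError, match="3 frames"):
            pairwise_correlation(rng.normal(size=(4, 2)))


class TestCalibration:
    def test_identical_cells_form_complete_graph_degree_7(self, rng):
        base = rng.normal(size=40)
        traces = np.tile(base, (8, 1))
        corr, _ = pairwise_correlation(traces)
        threshold, achieved = calibrate_threshold([corr], target_degree=7)
        assert threshold < 1.0
        net = build_network(corr, threshold)
        assert np.all(net.degree == 7)
        assert achieved == pytest.approx(7.0)

    def test_edge_count_non_increasing_in_threshold(self, rng):
        traces = rng.normal(size=(10, 25))
        corr, _ = pairwise_correlation(traces)
        iu = np.triu_indices(10, k=1)
        candidates = np.sort(np.concatenate([[-1.0], corr[iu], [1.0]]))
        counts = [build_network(corr, t).n_edges for t in candidates]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_calibrated_mean_degree_near_target_on_synthetic(self, noisy_islet):
        dataset, _ = noisy_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        networks, threshold, achieved = build_islet_networks(
            dataset.traces, segments, dataset.cell_ids, target_degree=7
        )
        mean_degree = np.mean([net.degree.mean() for net in networks])
        assert mean_degree == pytest.approx(achieved, abs=1e-9)
        assert abs(achieved - 7.0) <= 1.0
        assert round(achieved) == 7
        # one threshold shared across oscillations
        assert len({net.threshold for net in networks}) == 1

    def test_unreachable_target_warns(self):
        # All correlations identical: only the empty and complete graphs exist.
        corr = np.ones((6, 6))
        with pytest.warns(UserWarning, match="unreachable"):
            threshold, achieved = calibrate_threshold([corr], target_degree=2)
        assert achieved == 0.0  # sparser boundary wins the tie-break rule


class TestBuildNetwork:
    def test_handshake_identity_and_subpop_sizes(self, rng):
        traces = rng.normal(size=(100, 40))
        corr, _ = pairwise_correlation(traces)
        net = build_network(corr, threshold=0.2)
        assert net.degree.sum() == 2 * net.n_edges
        assert len(net.high_set) == 10 and len(net.low_set) == 10
        assert not net.adjacency.diagonal().any()
        assert np.array_equal(net.adjacency, net.adjacency.T)

    def test_degree_ties_break_by_ascending_id(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[2, 3] = corr[3, 2] = 0.9
        net = build_network(corr, threshold=0.5, fraction=0.25)
        # all degrees equal 1; the lowest id wins the single high slot
        assert net.high_set.tolist() == [0]
        assert net.low_set.tolist() == [0]

    def test_degree_invariant_under_common_affine_transform(self, noisy_islet):
        dataset, _ = noisy_islet
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        nets_a, thr, _ = build_islet_networks(dataset.traces, segments)
        nets_b, thr_b, _ = build_islet_networks(2.5 * dataset.traces - 7.0, segments)
        for a, b in zip(nets_a, nets_b):
            assert np.array_equal(a.degree, b.degree)

    def test_high_degree_cells_are_central_with_radial_noise(self):
        cfg = small_config(
            n_cells=120, islet_radius=45.0,
            noise_sd_center=0.03, noise_sd_edge=0.45, shared_noise_sd=0.05,
            seed=17,
        )
        dataset, _ = generate_islet(cfg)
        segments, _ = segment_dataset(dataset, min_separation=50.0)
        networks, _, _ = build_islet_networks(dataset.traces, segments, dataset.cell_ids)
        stats = spatial_stats(
            dataset.positions, [n.high_set for n in networks], dataset.cell_ids
        )
        high = np.mean([stats.mean_normalized_distance(n.high_set) for n in networks])
        low = np.mean([stats.mean_normalized_distance(n.low_set) for n in networks])
        assert high < stats.mean_normalized_distance() < low


class TestSpatialStats:
    def test_cog_matches_coordinate_mean_oracle(self, rng):
        positions = rng.normal(size=(20, 3)) * 30
        ids = np.arange(20)
        subset = ids[:7]
        stats = spatial_stats(positions, [subset, subset], ids)
        oracle = np.array(
            [sum(positions[i][d] for i in subset) / 7 for d in range(3)]
        )
        np.testing.assert_allclose(stats.cog[0], oracle, atol=1e-12)
        assert stats.displacement[0] == 0.0

    def test_symmetric_set_centered_and_farthest_cell_at_one(self):
        positions = np.array(
            [[30.0, 0, 0], [-30.0, 0, 0], [0, 10.0, 0], [0, -10.0, 0]]
        )
        stats = spatial_stats(positions, [np.array([0, 1])])
        np.testing.assert_allclose(stats.cog[0], [0, 0, 0], atol=1e-12)
        assert stats.normalized_distance.max() == 1.0

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            spatial_stats(rng.normal(size=(5, 3)), [np.array([], dtype=int)])


class TestRetention:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [4, 5, 6], 0.0),
            (list(range(10)), [0, 1, 2, 3, 4, 5, 90, 91, 92, 93], 0.6),
        ],
    )
    def test_overlap_fraction(self, a, b, expected):
        assert retention_rate(np.array(a), np.array(b)) == expected

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            retention_rate(np.array([]), np.array([1]))
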