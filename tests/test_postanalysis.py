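"""Clustering, dominant-term, spectral and correlation analyses."""

import numpy as np
import pandas as pd
import pytest

import homeodyn as hd
from homeodyn.dynamics import Trajectory
from homeodyn.postanalysis import dtw_distance


def _make_traj(states: np.ndarray) -> Trajectory:
    days = np.arange(1.0, len(states) + 1.0)
    return Trajectory(days, states, days >= 0)  # all days reported


class TestDTW:
    def test_identical_series_distance_zero(self):
        x = np.sin(np.linspace(0, 10, 50))
        assert dtw_distance(x, x) == 0.0

    def test_warping_beats_euclidean_on_shifted_series(self):
        t = np.linspace(0, 4 * np.pi, 80)
        x, y = np.sin(t), np.sin(t + 0.5)
        assert dtw_distance(x, y) < np.linalg.norm(x - y)

    def test_matches_brute_force_on_tiny_example(self):
        # DP table small enough to enumerate alignments by hand/recursion
        x, y = np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0])
        import itertools

        def brute(x, y):
            best = np.inf
            # all monotone alignments of len<=5 via recursion
            def rec(i, j, acc):
                nonlocal best
                acc = acc + (x[i] - y[j]) ** 2
                if i == len(x) - 1 and j == len(y) - 1:
                    best = min(best, acc)
                    return
                for di, dj in ((1, 0), (0, 1), (1, 1)):
                    if i + di < len(x) and j + dj < len(y):
                        rec(i + di, j + dj, acc)
            rec(0, 0, 0.0)
            return np.sqrt(best)

        assert dtw_distance(x, y) == pytest.approx(brute(x, y))

    def test_three_duplicate_groups_separate_perfectly(self):
        t = np.linspace(0, 6 * np.pi, 60)
        base = [np.sin(t), np.cos(2 * t), np.full_like(t, 0.3)]
        series = np.array([base[i % 3] for i in range(9)])
        res = hd.dtw_kmeans(series, k=3, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        labels = res.labels
        for g in range(3):
            assert len(set(labels[g::3])) == 1

    def test_two_frequencies_plus_constant_recovered(self):
        t = np.linspace(0, 8 * np.pi, 120)
        rng = np.random.default_rng(1)
        groups = [np.sin(t), np.sin(4 * t), np.full_like(t, 0.5)]
        series = np.array(
            [groups[i % 3] + 0.01 * rng.normal(size=t.size) for i in range(12)]
        )
        hits = 0
        for seed in range(10):
            labels = hd.dtw_kmeans(series, k=3, seed=seed).labels
            ok = all(len(set(labels[g::3])) == 1 for g in range(3)) and len(set(labels)) == 3
            hits += ok
        assert hits >= 9

    def test_too_few_distinct_series_rejected(self):
        series = np.tile(np.sin(np.linspace(0, 5, 30)), (5, 1))
        with pytest.raises(ValueError):
            hd.dtw_kmeans(series, k=3, seed=0)


class TestCooccurrence:
    def test_single_labeling_all_together(self):
        table = hd.cluster_cooccurrence([np.zeros(4, dtype=int)])
        assert np.all(table == 1)

    def test_always_separated_pair_counts_zero(self):
        labs = [np.array([0, 1, 0]), np.array([1, 0, 1])]
        table = hd.cluster_cooccurrence(labs)
        assert table[0, 1] == 0 and np.all(np.diag(table) == 2)

    def test_hand_built_fixture(self):
        labs = [np.array([0, 0, 1]), np.array([0, 1, 1]), np.array([0, 0, 0])]
        table = hd.cluster_cooccurrence(labs)
        expected = np.array([[3, 2, 1], [2, 3, 2], [1, 2, 3]])
        np.testing.assert_array_equal(table, expected)
        np.testing.assert_array_equal(table, table.T)


class TestEigenFeatures:
    def test_hand_computed_features_of_diagonal_system(self):
        E = hd.eigensystem(np.diag([-1.0, -2.0]), x0=np.array([1.0, 1.0]))
        f = hd.eigen_features(E)
        assert f["real_min"] == pytest.approx(-2.0)
        assert f["real_max"] == pytest.approx(-1.0)
        assert f["real_mean"] == pytest.approx(-1.5)
        assert f["real_std"] == pytest.approx(0.5)  # population convention
        assert len(f) == 16

    def test_stable_vs_unstable_cluster_centers_ordered(self, rng):
        # two tight families: strongly stable and strongly unstable spectra
        systems = []
        for i in range(6):
            A = rng.normal(0, 0.05, (5, 5))
            shift = np.max(np.linalg.eigvals(A).real)
            systems.append(hd.eigensystem(A - (shift + 1.0) * np.eye(5), x0=np.ones(5)))
        for i in range(6):
            A = rng.normal(0, 0.05, (5, 5))
            shift = np.max(np.linalg.eigvals(A).real)
            systems.append(hd.eigensystem(A - (shift - 1.0) * np.eye(5), x0=np.ones(5)))
        labels, centers = hd.eigen_feature_clustering(systems, k=2, seed=0)
        stable_label = labels[0]
        unstable_label = labels[-1]
        assert stable_label != unstable_label
        assert (
            centers.loc[stable_label, "real_max"] < centers.loc[unstable_label, "real_max"]
        )

    def test_identical_systems_collapse_to_one_cluster(self):
        E = hd.eigensystem(np.diag([-1.0, -2.0]), x0=np.array([1.0, 1.0]))
        with pytest.warns(UserWarning):
            labels, _ = hd.eigen_feature_clustering([E] * 5, k=2, seed=0)
        # all feature vectors identical: grouping is degenerate (inertia 0)
        assert len(set(labels.tolist())) <= 2


class TestDominantTerms:
    def test_diagonal_system_own_mode_dominates(self):
        E = hd.eigensystem(np.diag([-0.01, -0.02, -0.03]), x0=np.ones(3))
        table = hd.dominant_terms_by_magnitude(E, t=100.0)
        np.testing.assert_array_equal(table.flags, np.eye(3, dtype=bool))

    def test_exact_tie_flags_both(self):
        # rotation block: two conjugate modes with equal Re and equal |v|
        E = hd.eigensystem(np.array([[-0.01, 0.05], [-0.05, -0.01]]), x0=np.ones(2))
        table = hd.dominant_terms_by_magnitude(E, t=100.0)
        assert np.all(table.flags)

    def test_magnitude_flags_match_brute_force(self, rng):
        from conftest import random_stable_matrix

        A = random_stable_matrix(rng, 3, margin=0.01)
        E = hd.eigensystem(A, x0=np.ones(3))
        table = hd.dominant_terms_by_magnitude(E, t=100.0, tol=0.05)
        for j in range(3):
            scores = [
                np.exp(E.lambdas[i].real * 100.0) * abs(E.vectors[j, i]) for i in range(3)
            ]
            top = max(scores)
            for i in range(3):
                assert table.flags[i, j] == (scores[i] >= 0.95 * top)

    def test_decay_rate_keeps_only_slow_mode(self):
        E = hd.eigensystem(np.diag([-0.0002, -0.1]), x0=np.ones(2))
        table = hd.dominant_terms_by_decay(E, t_ref=200.0)
        # fast mode is excluded by the slow-mode cutoff for every factor
        assert np.array_equal(table.flags[:, 0], np.array([True, False]))

    def test_decay_requires_stable_system(self):
        E = hd.eigensystem(np.diag([0.01, -0.1]), x0=np.ones(2))
        with pytest.raises(ValueError):
            hd.dominant_terms_by_decay(E)


class TestSpectral:
    def test_eight_day_tone_peaks_at_eighth_cycle(self):
        t = np.arange(200.0)
        x = np.sin(2 * np.pi * t / 8.0)
        freqs, times, psd = hd.spectrogram_psd(x)
        peak_bins = np.argmax(psd, axis=0)
        assert np.all(freqs[peak_bins] == pytest.approx(0.125))

    def test_constant_series_power_concentrates_at_zero_frequency(self):
        freqs, _, psd = hd.spectrogram_psd(np.full(64, 2.5))
        # DC bin dominates every slice; beyond the Hann main lobe (DC +
        # adjacent bin) the power is numerically zero
        assert np.all(np.argmax(psd, axis=0) == 0)
        assert np.max(psd[2:]) <= 1e-20 * psd[0].max()

    def test_windowed_power_tracks_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=512)
        freqs, times, psd = hd.spectrogram_psd(x)
        df = freqs[1] - freqs[0]
        total_power = np.mean(psd.sum(axis=0)) * df
        # Parseval up to the Hann window loss factor (~1 for white noise psd scaling)
        assert total_power == pytest.approx(np.var(x), rel=0.3)

    def test_psd_discrepancy_is_a_metric(self, rng):
        mats = [rng.random((5, 7)) for _ in range(9)]
        for a, b, c in zip(mats[::3], mats[1::3], mats[2::3]):
            assert hd.psd_discrepancy(a, a) == 0.0
            assert hd.psd_discrepancy(a, b) == hd.psd_discrepancy(b, a)
            assert hd.psd_discrepancy(a, c) <= hd.psd_discrepancy(a, b) + hd.psd_discrepancy(b, c)
        with pytest.raises(ValueError):
            hd.psd_discrepancy(np.zeros((2, 2)), np.zeros((3, 2)))


class TestCorrelations:
    def test_xcorr_zero_matches_hand_dot_product(self):
        x = np.array([1.0, 2, 3, 4, 5, 4, 3, 2, 1, 0])
        y = np.array([0.0, 1, 0, -1, 0, 1, 0, -1, 0, 1])
        xc, yc = x - x.mean(), y - y.mean()
        assert hd.xcorr_zero(x, y) == pytest.approx(float(np.sum(xc * yc)))

    def test_self_xcorr_is_max_over_lags(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        xc = x - x.mean()
        full = np.correlate(xc, xc, mode="full")
        assert hd.xcorr_zero(x, x) == pytest.approx(full.max())

    def test_quadrature_sinusoids_orthogonal(self):
        t = np.arange(160.0)
        x, y = np.sin(2 * np.pi * t / 16), np.cos(2 * np.pi * t / 16)
        assert abs(hd.xcorr_zero(x, y)) < 1e-9 * hd.xcorr_zero(x, x)

    def test_pearson_of_phase_shift_is_cos_phi(self):
        t = np.arange(1.0, 161.0)
        states = np.column_stack(
            [np.sin(2 * np.pi * t / 16 + phi) for phi in (0.0, np.pi / 3, np.pi)]
        )
        traj = _make_traj(states)
        table = hd.pearson_pairs(traj, horizons=[160], use_reported=False)
        r = table.set_index(["factor_a", "factor_b"])["r_160d"]
        assert r[("x0", "x0")] == 1.0
        assert r[("x0", "x1")] == pytest.approx(np.cos(np.pi / 3), abs=0.01)
        assert r[("x0", "x2")] == pytest.approx(-1.0, abs=0.01)

    def test_105_pairs_and_nan_for_zero_variance(self, wt_matrix):
        traj = hd.simulate(wt_matrix, t_end=400)
        table = hd.pearson_pairs(traj, horizons=[200, 365])
        assert len(table) == 105
        self_rows = table[table.factor_a == table.factor_b]
        assert (self_rows["r_200d"] == 1.0).all()
        # zero-variance series yields NaN, not 0
        states = np.column_stack([np.ones(100), np.sin(np.arange(100.0))])
        t2 = hd.pearson_pairs(_make_traj(states), horizons=[100], use_reported=False)
        assert np.isnan(t2.set_index(["factor_a", "factor_b"])["r_100d"][("x0", "x1")])

    def test_horizon_beyond_trajectory_rejected(self, wt_matrix):
        traj = hd.simulate(wt_matrix, t_end=200)
        with pytest.raises(ValueError):
            hd.pearson_pairs(traj, horizons=[365])


class TestPairRanking:
    def _ranks(self):
        pairs = ["a|a", "a|b", "b|b", "a|c"]
        psd = pd.Series([0.1, 0.4, 0.2, 0.9], index=pairs)
        xc = pd.Series([5.0, -4.0, 3.0, 0.1], index=pairs)
        pr = pd.Series([0.9, -0.8, 0.5, 0.1], index=pairs)
        return hd.rank_pair_metrics(psd, xc, pr)

    def test_orientation_of_metric_ranks(self):
        psd_r, xc_r, pr_r = self._ranks()
        assert psd_r["a|a"] == 1.0  # lowest discrepancy ranks best
        assert xc_r["a|a"] == 1.0  # largest |xcorr| ranks best
        assert xc_r["a|b"] == 2.0  # sign ignored for xcorr
        assert pr_r["a|a"] == 1.0 and pr_r["a|b"] == 4.0  # signed pearson

    def test_rank_sums_match_hand_computation(self):
        ranking = hd.aggregate_pair_ranking(*self._ranks()).table
        # hand: a|a -> 1+1+1 = 3; b|b -> 2+3+2 = 7; a|b -> 3+2+4 = 9; a|c -> 4+4+3 = 11
        assert ranking.loc["a|a", "rank_sum"] == 3.0
        assert ranking.loc["b|b", "rank_sum"] == 7.0
        assert list(ranking.index) == ["a|a", "b|b", "a|b", "a|c"]
        assert list(ranking["aggregate_rank"]) == [1, 2, 3, 4]

    def test_dominant_pair_ranks_first_and_order_invariance(self):
        psd_r, xc_r, pr_r = self._ranks()
        shuffled = hd.aggregate_pair_ranking(
            psd_r.sample(frac=1, random_state=0), xc_r, pr_r
        ).table
        assert shuffled.loc["a|a", "aggregate_rank"] == 1
        assert list(shuffled.index) == list(hd.aggregate_pair_ranking(psd_r, xc_r, pr_r).table.index)

    def test_incomplete_rankings_rejected(self):
        psd_r, xc_r, pr_r = self._ranks()
        with pytest.raises(ValueError):
            hd.aggregate_pair_ranking(psd_r.iloc[:3], xc_r, pr_r)
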