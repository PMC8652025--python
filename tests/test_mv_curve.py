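import numpy as np
import pytest

from vss import (
    BaseAuxPairs,
    MeanVarianceCurve,
    ReplicateSet,
    SignalTrack,
    ValidationError,
    build_base_aux,
    compute_bin_stats,
    default_hyperparameters,
    fit_sigma_curve,
    select_hyperparameters,
    smooth_bin_sigmas,
)

from _reference import ref_bin_stats, ref_smooth_sigmas
from conftest import make_track


def reps_from_values(*value_lists, signal_type="raw"):
    n = len(value_lists[0])
    starts = np.arange(n, dtype=np.int64) * 10
    tracks = [
        SignalTrack.from_arrays(["chr21"] * n, starts, starts + 10, v) for v in value_lists
    ]
    return ReplicateSet(tracks, signal_type)


class TestBuildBaseAux:
    def test_two_replicates_enumerates_both_orders(self):
        reps = reps_from_values([1, 2, 3], [4, 5, 6])
        pairs = build_base_aux(reps)
        assert pairs.base.tolist() == [1, 2, 3, 4, 5, 6]
        assert pairs.aux.tolist() == [4, 5, 6, 1, 2, 3]

    def test_three_replicates_length_and_order(self):
        reps = reps_from_values([1.0], [2.0], [3.0])
        pairs = build_base_aux(reps)
        # pairs in lexicographic order: 12,13,21,23,31,32
        assert pairs.base.tolist() == [1, 1, 2, 2, 3, 3]
        assert pairs.aux.tolist() == [2, 3, 1, 3, 1, 2]

    def test_identical_replicates_make_base_equal_aux(self):
        reps = reps_from_values([2, 4, 8], [2, 4, 8])
        pairs = build_base_aux(reps)
        np.testing.assert_array_equal(pairs.base, pairs.aux)

    def test_pair_multiset_symmetric_under_replicate_swap(self, rng):
        a, b = rng.poisson(10, 50).astype(float), rng.poisson(10, 50).astype(float)
        p1 = build_base_aux(reps_from_values(a, b))
        p2 = build_base_aux(reps_from_values(b, a))
        tuples1 = sorted(zip(p1.base, p1.aux))
        tuples2 = sorted(zip(p2.base, p2.aux))
        assert tuples1 == tuples2

    def test_unaligned_tracks_rejected(self):
        t1 = make_track(starts=(0, 100), values=(1.0, 2.0))
        t2 = make_track(starts=(50, 150), values=(1.0, 2.0))
        with pytest.raises(ValidationError, match="grid"):
            ReplicateSet([t1, t2], "raw")


class TestComputeBinStats:
    def test_hand_worked_bins(self):
        pairs = BaseAuxPairs([1, 2, 3, 4, 5, 6], [2, 2, 4, 4, 6, 6])
        stats = compute_bin_stats(pairs, b=3, zero_bin=False)
        np.testing.assert_allclose(stats.mu, [8 / 3, 16 / 3])
        np.testing.assert_allclose(stats.sigma ** 2, [8 / 9, 8 / 9])
        assert stats.count.tolist() == [3, 3]

    def test_constant_aux_within_bins_has_zero_sd(self):
        pairs = BaseAuxPairs([1, 2, 3, 4], [5, 5, 7, 7])
        stats = compute_bin_stats(pairs, b=2, zero_bin=False)
        np.testing.assert_array_equal(stats.sigma, [0.0, 0.0])

    def test_zero_bin_separated(self):
        pairs = BaseAuxPairs([0, 0, 5, 5], [1, 3, 4, 6])
        stats = compute_bin_stats(pairs, b=2, zero_bin=True)
        assert stats.zero_mu == 2.0
        assert stats.zero_sigma == 1.0
        assert stats.zero_count == 2
        np.testing.assert_allclose(stats.mu, [5.0])
        np.testing.assert_allclose(stats.sigma ** 2, [1.0])

    def test_final_partial_bin_kept(self):
        pairs = BaseAuxPairs(np.arange(1, 8.0), np.arange(1, 8.0))
        stats = compute_bin_stats(pairs, b=3, zero_bin=False)
        assert stats.count.tolist() == [3, 3, 1]

    def test_fewer_than_b_positions_warns_single_bin(self):
        pairs = BaseAuxPairs([1, 2], [1, 2])
        with pytest.warns(UserWarning, match="single bin"):
            stats = compute_bin_stats(pairs, b=10, zero_bin=False)
        assert stats.n_bins == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_bin_stats(BaseAuxPairs([], []), b=2)
        with pytest.raises(ValidationError, match="non-zero"):
            compute_bin_stats(BaseAuxPairs([0.0, 0.0], [1.0, 2.0]), b=2, zero_bin=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 400))
        base = np.where(rng.random(n) < 0.3, 0.0, rng.poisson(8, n)).astype(float)
        aux = np.where(rng.random(n) < 0.3, 0.0, rng.poisson(8, n)).astype(float)
        b = int(rng.integers(2, 20))
        zb = bool(rng.integers(0, 2)) and np.any(base == 0) and np.any(base != 0)
        stats = compute_bin_stats(BaseAuxPairs(base, aux), b=b, zero_bin=zb)
        ref_bins, ref_zero = ref_bin_stats(base, aux, b, zb)
        np.testing.assert_allclose(stats.mu, [r[0] for r in ref_bins], rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(stats.sigma, [r[1] for r in ref_bins], rtol=1e-12, atol=1e-12)
        assert stats.count.tolist() == [r[2] for r in ref_bins]
        if zb and ref_zero is not None:
            np.testing.assert_allclose(
                [stats.zero_mu, stats.zero_sigma], ref_zero[:2], rtol=1e-12, atol=1e-12
            )


class TestSmoothBinSigmas:
    def test_paper_default_window_collapses_to_identity(self):
        # b=1e5, beta=1e3 (zero-inflated defaults) give w = 0: no cross-bin mixing
        stats = compute_bin_stats(
            BaseAuxPairs(np.arange(1, 13.0), np.arange(1, 13.0) % 4), b=3, zero_bin=False
        )
        smoothed = smooth_bin_sigmas(stats, beta=1e3, b=100_000)
        np.testing.assert_array_equal(smoothed.smoothed_sigma, stats.sigma)

    def test_constant_variance_is_preserved(self):
        stats = compute_bin_stats(
            BaseAuxPairs(np.arange(1, 10.0), np.tile([1.0, 2.0, 3.0], 3)), b=3, zero_bin=False
        )
        assert np.ptp(stats.sigma) == 0
        smoothed = smooth_bin_sigmas(stats, beta=5.0, b=1)
        np.testing.assert_allclose(smoothed.smoothed_sigma, stats.sigma, rtol=1e-12)

    def test_hand_worked_three_bin_window(self):
        # sigma^2 = [1, 4, 1], b=1, beta=1: weights 2^-|k| = [1/2, 1, 1/2]
        stats = compute_bin_stats(
            BaseAuxPairs(np.arange(6.0) + 1, [0, 2, 0, 4, 0, 2]), b=2, zero_bin=False
        )
        np.testing.assert_allclose(stats.sigma ** 2, [1.0, 4.0, 1.0])
        smoothed = smooth_bin_sigmas(stats, beta=1.0, b=1)
        # centre: (0.5*1 + 1*4 + 0.5*1) / 2 = 2.5; edges truncate+renormalize
        # (window w=7 covers all bins: first bin sees offsets 0,1,2)
        np.testing.assert_allclose(smoothed.smoothed_sigma[1] ** 2, 2.5)
        np.testing.assert_allclose(
            smoothed.smoothed_sigma[0] ** 2, (1 + 0.5 * 4 + 0.25 * 1) / 1.75
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_bins = int(rng.integers(1, 30))
        sigma = rng.gamma(2.0, 1.0, n_bins)
        b = int(rng.integers(1, 10))
        beta = float(rng.uniform(0.5, 30.0))
        from vss.mv_curve import BinStats

        stats = BinStats(
            mu=np.arange(float(n_bins)) + 1,
            sigma=sigma,
            count=np.full(n_bins, b),
            b=b,
        )
        out = smooth_bin_sigmas(stats, beta=beta, b=b)
        ref = ref_smooth_sigmas(sigma.tolist(), b, beta)
        np.testing.assert_allclose(out.smoothed_sigma, ref, rtol=1e-12, atol=1e-12)


class TestFitSigmaCurve:
    @staticmethod
    def _stats_from_points(mu, sigma, count=1000, b=1000):
        from vss.mv_curve import BinStats

        mu = np.asarray(mu, float)
        sigma = np.asarray(sigma, float)
        return BinStats(
            mu=mu, sigma=sigma, count=np.full(len(mu), count), b=b, smoothed_sigma=sigma.copy()
        )

    def test_recovers_linear_relationship(self):
        mu = np.linspace(0, 100, 40)
        stats = self._stats_from_points(mu, mu + 1.0)
        curve = fit_sigma_curve(stats)
        interior = np.linspace(5, 95, 50)
        np.testing.assert_allclose(curve(interior), interior + 1.0, rtol=0.01)

    def test_constant_points_fit_constant(self):
        stats = self._stats_from_points(np.linspace(1, 50, 20), np.full(20, 3.0))
        curve = fit_sigma_curve(stats)
        grid = np.linspace(1, 50, 200)
        np.testing.assert_allclose(curve(grid), 3.0, atol=1e-6)

    def test_clamp_keeps_curve_positive(self, rng):
        mu = np.linspace(0, 20, 30)
        noisy = np.abs(np.sin(mu)) * 0.002 + rng.normal(0, 0.001, 30)
        stats = self._stats_from_points(mu, np.abs(noisy))
        curve = fit_sigma_curve(stats, cv=False, p_override=1e-8)
        grid = np.linspace(0, 20, 500)
        assert np.all(curve(grid) >= curve.sigma_floor)
        assert curve.sigma_floor > 0

    def test_constant_extrapolation_outside_domain(self):
        stats = self._stats_from_points(np.linspace(10, 20, 10), np.linspace(2, 4, 10))
        curve = fit_sigma_curve(stats)
        assert curve(0.0) == curve(10.0)
        assert curve(100.0) == curve(20.0)

    def test_too_few_points_rejected(self):
        stats = self._stats_from_points([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="4"):
            fit_sigma_curve(stats)

    def test_zero_bin_point_enters_fit(self):
        # zero bin far below the nonzero trend drags the curve down near 0
        stats = self._stats_from_points(np.linspace(10, 50, 20), np.linspace(10, 50, 20))
        stats_zero = self._stats_from_points(np.linspace(10, 50, 20), np.linspace(10, 50, 20))
        stats_zero.zero_mu, stats_zero.zero_sigma, stats_zero.zero_count = 0.5, 0.7, 20000
        without = fit_sigma_curve(stats)
        with_zero = fit_sigma_curve(stats_zero)
        assert with_zero(0.5) < without(0.5)
        assert with_zero.mu_min == 0.5

    def test_fitted_curve_stable_under_replicate_swap(self, rng):
        a = rng.poisson(20, 4000).astype(float)
        b = rng.poisson(20, 4000).astype(float)
        c1 = _fit_from_pairs(reps_from_values(a, b))
        c2 = _fit_from_pairs(reps_from_values(b, a))
        grid = np.linspace(max(c1.mu_min, c2.mu_min) + 1, min(c1.mu_max, c2.mu_max) - 1, 50)
        np.testing.assert_allclose(c1(grid), c2(grid), rtol=0.01)


def _fit_from_pairs(reps, b=200, beta=200.0):
    stats = compute_bin_stats(build_base_aux(reps), b=b, zero_bin=False)
    return fit_sigma_curve(smooth_bin_sigmas(stats, beta=beta))


class TestSelectHyperparameters:
    def test_single_candidate_returned(self, nb_simulation):
        reps, _ = nb_simulation
        b, beta, report = select_hyperparameters(
            reps, grid=[(500, 1e3)], train_chroms=["chr22"], test_chroms=["chr21"]
        )
        assert (b, beta) == (500, 1e3)
        assert len(report) == 1

    def test_argmax_contract(self, nb_simulation):
        reps, _ = nb_simulation
        b, beta, report = select_hyperparameters(
            reps,
            grid=[(200, 1e3), (1000, 1e3)],
            train_chroms=["chr22"],
            test_chroms=["chr21"],
            metric_bin_size=2000,
        )
        best = report["mean_log_density"].max()
        sel = report[(report.b == b) & (report.beta == beta)]["mean_log_density"].iloc[0]
        assert sel == best

    def test_overlapping_splits_rejected(self, nb_simulation):
        reps, _ = nb_simulation
        with pytest.raises(ValidationError, match="disjoint"):
            select_hyperparameters(reps, grid=[(100, 1.0)], train_chroms=["chr21"], test_chroms=["chr21"])

    def test_signal_type_defaults(self):
        assert default_hyperparameters("raw") == (100_000, 1e3, True)
        assert default_hyperparameters("fe") == (100_000, 1e3, True)
        assert default_hyperparameters("lppv") == (1_000, 1e7, False)


class TestMeanVarianceCurve:
    def test_from_function_and_floor(self):
        curve = MeanVarianceCurve.from_function(lambda u: u - 5.0, (0.0, 10.0), sigma_floor=0.5)
        assert curve(0.0) == 0.5   # clamped
        assert curve(9.0) == 4.0

    def test_from_grid_exact_at_grid_points(self):
        mu = np.linspace(0, 10, 11)
        sigma = np.sqrt(mu + 1)
        curve = MeanVarianceCurve.from_grid(mu, sigma, sigma_floor=1e-4)
        np.testing.assert_array_equal(curve(mu), sigma)
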