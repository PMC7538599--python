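"""Trace idealization: noise estimate, change points, clustering, MDL."""

import itertools

import numpy as np
import pytest

from kymostates.errors import ConfigurationError, InsufficientDataError
from kymostates.simulate import apo_scheme, render_height_trace, simulate_state_sequence
from kymostates.states import (
    IdealizedTrace,
    benchmark_accuracy,
    classify_activity,
    cluster_segments,
    compute_snr,
    detect_change_points,
    estimate_noise,
    idealize,
    idealize_trace,
    select_states_mdl,
    _segment_stats,
)


def staircase(levels, lengths):
    return np.repeat(np.asarray(levels, float), lengths)


class TestEstimateNoise:
    def test_pure_gaussian_recovery(self, rng):
        x = rng.normal(0, 0.1, 10_000)
        assert estimate_noise(x) == pytest.approx(0.1, abs=0.003)

    def test_noiseless_staircase_near_zero(self):
        x = staircase([0, 1, 0, 1], [50, 50, 50, 50])
        assert estimate_noise(x) < 1e-6

    def test_robust_to_steps(self, rng):
        x = staircase([0, 1, 0, 1, 0], [200] * 5) + rng.normal(0, 0.05, 1000)
        assert estimate_noise(x) == pytest.approx(0.05, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_noise(np.zeros(10))


class TestDetectChangePoints:
    def test_single_step_exact_location(self, rng):
        x = staircase([0, 1], [100, 100]) + rng.normal(0, 0.01, 200)
        cps = detect_change_points(x, 0.01)
        np.testing.assert_array_equal(cps, [100])

    def test_constant_trace_no_change_points(self, rng):
        x = np.full(500, 2.0)
        assert detect_change_points(x, 0.1).size == 0

    def test_noiseless_staircase_found_exactly(self):
        x = staircase([0.8, 2.0, 0.8, 1.4, 0.8], [30, 40, 25, 20, 35])
        cps = detect_change_points(x, estimate_noise(x))
        np.testing.assert_array_equal(cps, [30, 70, 95, 115])

    def test_short_return_excursion_detected(self, rng):
        """A brief excursion that returns to the starting level is found
        even though a single split sees equal means on both sides."""
        x = staircase([2.0, 1.4, 2.0], [250, 12, 250]) + rng.normal(0, 0.15, 512)
        cps = detect_change_points(x, 0.15)
        assert cps.size >= 2
        assert min(abs(c - 250) for c in cps) <= 3
        assert min(abs(c - 262) for c in cps) <= 3


def brute_force_best_fit(x, n_cps, min_dwell=2):
    """Exhaustive RSS-optimal placement of ``n_cps`` change points."""
    n = x.size
    best, best_rss = None, np.inf
    positions = range(min_dwell, n - min_dwell + 1)
    for combo in itertools.combinations(positions, n_cps):
        if any(b - a < min_dwell for a, b in zip(combo[:-1], combo[1:])):
            continue
        bounds = [0, *combo, n]
        rss = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x[a:b]
            rss += float(np.sum((seg - seg.mean()) ** 2))
        if rss < best_rss:
            best, best_rss = combo, rss
    return np.array(best if best else [], dtype=int)


class TestBruteForceEquivalence:
    """On small instances at high SNR the detector finds the
    residual-optimal change-point placement among all candidates."""

    @pytest.mark.parametrize("seed", range(6))
    def test_two_change_points(self, seed):
        rng = np.random.default_rng(seed)
        x = staircase([0.8, 2.0, 1.4], [20, 24, 20]) + rng.normal(0, 0.12, 64)
        cps = detect_change_points(x, 0.12)
        assert cps.size == 2
        np.testing.assert_array_equal(cps, brute_force_best_fit(x, 2))

    @pytest.mark.parametrize("seed", range(4))
    def test_one_change_point(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = staircase([0.8, 2.0], [30, 34]) + rng.normal(0, 0.2, 64)
        cps = detect_change_points(x, 0.2)
        assert cps.size == 1
        np.testing.assert_array_equal(cps, brute_force_best_fit(x, 1))

    def test_zero_change_points(self, rng):
        x = np.full(64, 1.0) + rng.normal(0, 0.1, 64)
        assert detect_change_points(x, 0.1).size == 0


class TestClusterSegments:
    def test_two_group_level_splits_close_pairs(self):
        h = cluster_segments(np.array([0.0, 0.01, 1.0, 1.01]))
        labels = h.labels_at(2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_single_segment_trivial(self):
        h = cluster_segments(np.array([1.5]))
        np.testing.assert_array_equal(h.labels_at(1), [0])

    def test_three_separated_clusters_recovered(self, rng):
        means = np.concatenate(
            [rng.normal(0.8, 0.02, 10), rng.normal(1.4, 0.02, 10), rng.normal(2.0, 0.02, 10)]
        )
        truth = np.repeat([0, 1, 2], 10)
        h = cluster_segments(means, np.full(30, 50.0))
        labels = h.labels_at(3)
        np.testing.assert_array_equal(labels, truth)

    def test_labels_ordered_by_mean(self):
        h = cluster_segments(np.array([2.0, 0.5, 1.2]))
        labels = h.labels_at(3)
        np.testing.assert_array_equal(labels, [2, 0, 1])


class TestSelectStatesMDL:
    def test_noiseless_two_level_staircase(self):
        x = staircase([0.8, 2.0, 0.8, 2.0], [40, 40, 40, 40])
        ideal = idealize(x, 0.0033)
        assert ideal.n_states == 2
        np.testing.assert_allclose(ideal.state_heights, [0.8, 2.0])
        np.testing.assert_allclose(ideal.fitted(), x)
        assert ideal.residual_std < 1e-12

    def test_pure_noise_one_state(self, rng):
        x = rng.normal(1.0, 0.5, 5000)
        ideal = idealize(x, 0.0033)
        assert ideal.n_states == 1

    def test_spurious_transition_removed(self, rng):
        """A false change point inside one state leaves no transition."""
        x = staircase([1.0, 1.0], [100, 100]) + rng.normal(0, 0.05, 200)
        cps = np.array([100])
        _, lengths, means, _ = _segment_stats(x, cps)
        h = cluster_segments(means, lengths)
        ideal = select_states_mdl(x, cps, h, 0.05, sampling_period=0.0033)
        assert ideal.n_states == 1
        assert ideal.change_points.size == 0

    def test_unresolvable_states_merged(self, rng):
        """Mean levels closer than the noise floor are a single state."""
        x = staircase([1.0, 1.1, 1.0, 1.1], [2000, 2000, 2000, 2000])
        x = x + rng.normal(0, 0.5, x.size)
        ideal = idealize(x, 0.0033)
        assert ideal.n_states == 1


class TestInvariance:
    def test_offset_invariance(self, apo):
        truth = simulate_state_sequence(apo, 20.0, seed=3)
        trace = render_height_trace(truth, 0.3, seed=4)
        a = idealize_trace(trace)
        b = idealize(trace.heights + 5.0, 0.0033)
        np.testing.assert_array_equal(a.change_points, b.change_points)
        np.testing.assert_allclose(b.state_heights - 5.0, a.state_heights, atol=1e-9)

    def test_scale_equivariance(self, apo):
        truth = simulate_state_sequence(apo, 20.0, seed=5)
        trace = render_height_trace(truth, 0.3, seed=6)
        a = idealize_trace(trace)
        b = idealize(trace.heights * 3.0, 0.0033)
        np.testing.assert_array_equal(a.change_points, b.change_points)
        np.testing.assert_allclose(b.state_heights, 3.0 * a.state_heights, rtol=1e-9)


class TestComputeSnr:
    def _ideal(self, heights, resid):
        return IdealizedTrace(
            change_points=np.array([50]),
            segment_labels=np.array([0, 1]),
            segment_means=np.asarray(heights, float),
            state_heights=np.asarray(heights, float),
            noise_sigma=resid,
            residual_std=resid,
            n_samples=100,
            sampling_period=0.0033,
        )

    def test_direct_arithmetic(self):
        assert compute_snr(self._ideal([0.8, 2.0], 0.6)) == pytest.approx(2.0)

    def test_zero_amplitude(self):
        assert compute_snr(self._ideal([1.0, 1.0], 0.5)) == 0.0

    def test_single_state_undefined(self):
        ideal = IdealizedTrace(
            change_points=np.empty(0, int),
            segment_labels=np.array([0]),
            segment_means=np.array([1.0]),
            state_heights=np.array([1.0]),
            noise_sigma=0.1,
            residual_std=0.1,
            n_samples=100,
            sampling_period=0.0033,
        )
        assert np.isnan(compute_snr(ideal))

    def test_synthetic_high_snr(self, apo):
        truth = simulate_state_sequence(apo, 60.0, seed=9)
        trace = render_height_trace(truth, 0.1, seed=10)
        ideal = idealize_trace(trace)
        assert compute_snr(ideal) == pytest.approx(12.0, abs=0.5)


class TestClassifyActivity:
    def test_flat_trace_inactive(self, rng):
        x = np.full(1000, 2.0) + rng.normal(0, 0.1, 1000)
        assert not classify_activity(idealize(x, 0.0033))

    def test_single_excursion_active(self, rng):
        x = staircase([2.0, 0.8, 2.0], [400, 100, 400]) + rng.normal(0, 0.1, 900)
        assert classify_activity(idealize(x, 0.0033))

    def test_active_fraction_recovered(self):
        """Ensemble at active fraction 0.55: every protomer is classified
        according to its generating activity, so the classified fraction
        tracks 0.55 within binomial sampling error (3 SE at n=120)."""
        from kymostates.simulate import simulate_population

        scheme = apo_scheme(active_fraction=0.55)
        truths = simulate_population(scheme, 120, 30.0, seed=21)
        rng = np.random.default_rng(22)
        classified = []
        for t in truths:
            trace = render_height_trace(t, 0.3, rng=rng)
            classified.append(classify_activity(idealize_trace(trace)))
        assert classified == [t.active for t in truths]
        se = np.sqrt(0.55 * 0.45 / 120)
        assert abs(np.mean(classified) - 0.55) < 3 * se


class TestBenchmarkAccuracy:
    @staticmethod
    def _fit_from_truth(truth, period=0.0033):
        """IdealizedTrace that reproduces the ground truth exactly."""
        from kymostates.containers import n_samples_for

        n = n_samples_for(truth.duration, period)
        times = np.arange(n) * period
        heights = {lab: h for lab, h in zip(truth.state_labels, truth.segment_heights)}
        order = {lab: i for i, lab in enumerate(sorted(heights, key=heights.get))}
        labels = np.array([order[lab] for lab in truth.labels_at(times)])
        cps = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        seg_labels = labels[np.concatenate([[0], cps])]
        state_heights = np.array(sorted(heights.values()))
        return IdealizedTrace(
            change_points=cps,
            segment_labels=seg_labels,
            segment_means=state_heights[seg_labels],
            state_heights=state_heights,
            noise_sigma=0.0,
            residual_std=0.0,
            n_samples=n,
            sampling_period=period,
        )

    def test_perfect_fits_score_one(self, apo):
        fits, truths = [], []
        for seed in range(5):
            truth = simulate_state_sequence(apo, 20.0, seed=seed)
            # drop truths whose 1-sample dwells vanish on the sample grid
            fit = self._fit_from_truth(truth)
            if fit.n_states != 3:
                continue
            idx = truth.transition_sample_indices(0.0033, fit.n_samples)
            if idx.size != len(truth.state_labels) - 1 or np.any(np.diff(idx) == 0):
                continue
            fits.append(fit)
            truths.append(truth)
        assert fits
        rep = benchmark_accuracy(fits, truths)
        assert rep.transition_recall == 1.0
        assert rep.transition_precision == 1.0
        assert rep.state_count_accuracy == 1.0
        assert rep.label_accuracy == 1.0

    def test_length_mismatch_rejected(self, apo):
        truth = simulate_state_sequence(apo, 10.0, seed=0)
        trace = render_height_trace(truth, 0.0)
        fit = idealize_trace(trace)
        with pytest.raises(ConfigurationError):
            benchmark_accuracy([fit], [truth, truth])

    def test_extreme_noise_degrades_metrics(self, apo):
        """At SNR 0.2 the idealizer cannot recover the true structure."""
        fits, truths = [], []
        for seed in range(8):
            truth = simulate_state_sequence(apo, 10.0, seed=seed)
            trace = render_height_trace(truth, apo.amplitude / 0.2, seed=seed)
            fits.append(idealize_trace(trace))
            truths.append(trace.truth)
        rep = benchmark_accuracy(fits, truths)
        assert rep.transition_recall < 0.3
        assert rep.state_count_accuracy < 0.5
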