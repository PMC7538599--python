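"""Synthetic-data generator: state sequences, traces, kymographs, images."""

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.stats import kstest

from kymostates.containers import TraceTruth, n_samples_for
from kymostates.errors import ConfigurationError
from kymostates.simulate import (
    KymoSceneConfig,
    SchemeConfig,
    StateSpec,
    apo_scheme,
    render_height_trace,
    render_kymograph,
    render_topography_image,
    simulate_population,
    simulate_state_sequence,
    three_state_scheme,
    two_state_scheme,
)


class TestSchemeValidation:
    def test_rows_must_be_stochastic(self):
        states = [StateSpec("in", 0.8, ((0.3, 1.0),)), StateSpec("out", 2.0, ((0.3, 1.0),))]
        with pytest.raises(ConfigurationError):
            SchemeConfig(states, np.array([[0.0, 0.9], [1.0, 0.0]]))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            StateSpec("out", 2.0, ((-0.1, 1.0),))

    def test_self_transitions_rejected(self):
        states = [StateSpec("in", 0.8), StateSpec("out", 2.0)]
        with pytest.raises(ConfigurationError):
            SchemeConfig(states, np.array([[0.5, 0.5], [1.0, 0.0]]))

    def test_heights_must_increase(self):
        states = [StateSpec("a", 2.0), StateSpec("b", 0.8)]
        with pytest.raises(ConfigurationError):
            SchemeConfig(states, np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_active_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            two_state_scheme(0.3, 0.3, active_fraction=1.2)


class TestStateSequence:
    def test_same_seed_identical(self, apo):
        a = simulate_state_sequence(apo, 100.0, seed=7)
        b = simulate_state_sequence(apo, 100.0, seed=7)
        np.testing.assert_array_equal(a.change_times, b.change_times)
        assert a.state_labels == b.state_labels

    def test_two_state_scheme_never_visits_intermediate(self, two_state):
        truth = simulate_state_sequence(two_state, 200.0, seed=1)
        assert set(truth.state_labels) <= {"in", "out"}
        # strict alternation
        for a, b in zip(truth.state_labels[:-1], truth.state_labels[1:]):
            assert a != b

    def test_adjacent_labels_differ_and_times_increase(self, apo):
        truth = simulate_state_sequence(apo, 120.0, seed=3)
        assert np.all(np.diff(truth.change_times) > 0)
        assert truth.last_truncated

    def test_mean_dwells_match_mixture_means(self, apo):
        """Sampled mean dwell per state within 3 SE of sum(w_i tau_i)."""
        durs = {"in": [], "int": [], "out": []}
        for seed in range(50):
            t = simulate_state_sequence(apo, 500.0, seed=seed)
            d = t.segment_durations()
            for lab, dur in zip(t.state_labels[1:-1], d[1:-1]):  # uncensored
                durs[lab].append(dur)
        for spec in apo.states:
            vals = np.array(durs[spec.label])
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - spec.mean_dwell) < 3 * se + 1e-12

    def test_dwell_sampler_matches_exponential_cdf(self, rng):
        """KS distance of 1e5 draws from a single-exp component < 0.01."""
        spec = StateSpec("out", 2.0, ((0.3, 1.0),))
        draws = np.array([spec.sample_dwell(rng) for _ in range(100_000)])
        stat = kstest(draws, "expon", args=(0, 0.3)).statistic
        assert stat < 0.01

    def test_occupancy_matches_time_weighted_stationary(self, apo):
        """Long-run time fraction per state converges to the scheme's
        occupancy (jump-chain frequencies weighted by mean dwells)."""
        fractions = []
        for seed in range(20):
            t = simulate_state_sequence(apo, 400.0, seed=100 + seed)
            d = t.segment_durations()
            tot = {lab: 0.0 for lab in apo.labels}
            for lab, dur in zip(t.state_labels, d):
                tot[lab] += dur
            fractions.append([tot[lab] / t.duration for lab in apo.labels])
        fractions = np.array(fractions)
        expect = apo.occupancies()
        for j in range(3):
            se = fractions[:, j].std(ddof=1) / np.sqrt(len(fractions))
            assert abs(fractions[:, j].mean() - expect[j]) < 3 * se + 0.005

    def test_population_mixes_active_and_inactive(self):
        scheme = apo_scheme(active_fraction=0.5)
        truths = simulate_population(scheme, 200, 20.0, seed=9)
        active = sum(t.active for t in truths)
        assert 70 <= active <= 130
        inactive = [t for t in truths if not t.active]
        assert all(t.state_labels == ["out"] for t in inactive)


class TestRenderTrace:
    def test_noiseless_equals_staircase(self, apo):
        truth = simulate_state_sequence(apo, 30.0, seed=2)
        trace = render_height_trace(truth, 0.0)
        np.testing.assert_array_equal(trace.heights, truth.heights_at(trace.times))

    def test_sample_count_convention(self, apo):
        truth = simulate_state_sequence(apo, 60.0, seed=2)
        trace = render_height_trace(truth, 0.0, sampling_period=0.0033)
        assert trace.n_samples == 18182
        assert n_samples_for(1.0, 0.01) == 100

    def test_noise_level_and_snr(self, apo):
        """sigma=0.6 on a 1.2 nm amplitude gives per-segment std ~0.6, SNR ~2."""
        truth = simulate_state_sequence(apo, 60.0, seed=5)
        trace = render_height_trace(truth, 0.6, seed=6)
        resid = trace.heights - truth.heights_at(trace.times)
        assert abs(resid.std() - 0.6) < 0.02
        assert abs(apo.amplitude / resid.std() - 2.0) < 0.05

    def test_same_seed_identical(self, apo):
        truth = simulate_state_sequence(apo, 10.0, seed=2)
        a = render_height_trace(truth, 0.3, seed=4)
        b = render_height_trace(truth, 0.3, seed=4)
        np.testing.assert_array_equal(a.heights, b.heights)


class TestRenderKymograph:
    def test_stationary_protomer_no_noise(self, flat_truth):
        scene = KymoSceneConfig(n_protomers=1, duration=1.0, width=20.0)
        kymo = render_kymograph(scene, [flat_truth])
        assert np.all(kymo.heights == kymo.heights[0])
        assert np.ptp(kymo.heights.max(axis=1)) == 0.0

    def test_x_drift_shifts_peak_linearly(self, flat_truth):
        scene = KymoSceneConfig(
            n_protomers=1, duration=10.0, x_drift=0.5, width=30.0, margin=10.0
        )
        truth = TraceTruth(
            change_times=np.empty(0),
            state_labels=["out"],
            segment_heights=np.array([2.0]),
            duration=10.0,
        )
        kymo = render_kymograph(scene, [truth])
        first = np.argmax(kymo.heights[0])
        last = np.argmax(kymo.heights[-1])
        assert last - first == pytest.approx(5.0 / scene.pixel_size, abs=1)

    def test_seven_protomer_projection_layout(self, apo):
        """Time projection shows 7 maxima ~5.7 nm apart."""
        scene = KymoSceneConfig(n_protomers=7, duration=5.0)
        truths = simulate_population(apo, 7, 5.0, seed=3)
        kymo = render_kymograph(scene, truths, seed=4)
        profile = kymo.heights.mean(axis=0)
        peaks, _ = find_peaks(profile, height=0.5)
        assert peaks.size == 7
        spacings = np.diff(peaks) * scene.pixel_size
        assert np.allclose(spacings, 5.7, atol=1.0)

    def test_peak_column_reproduces_trace(self, apo):
        """Column time series at the apex column matches the height trace."""
        scene = KymoSceneConfig(n_protomers=1, duration=20.0, width=20.0)
        truth = simulate_state_sequence(apo, 20.0, seed=8)
        kymo = render_kymograph(scene, [truth])
        col = int(np.argmax(kymo.heights.mean(axis=0)))
        series = kymo.heights[:, col]
        trace = render_height_trace(truth, 0.0, sampling_period=scene.line_period)
        r = np.corrcoef(series, trace.heights)[0, 1]
        assert r > 0.99

    def test_y_drift_attenuates_apparent_height(self, flat_truth):
        scene = KymoSceneConfig(n_protomers=1, duration=10.0, y_drift=0.2, width=20.0)
        truth = TraceTruth(
            change_times=np.empty(0),
            state_labels=["out"],
            segment_heights=np.array([2.0]),
            duration=10.0,
        )
        kymo = render_kymograph(scene, [truth])
        peak = kymo.heights.max(axis=1)
        assert peak[0] == pytest.approx(2.0)
        assert peak[-1] < 2.0  # 2 nm offset by the end
        assert np.all(np.diff(peak) <= 1e-12)

    def test_protomer_outside_field_rejected(self, flat_truth):
        scene = KymoSceneConfig(n_protomers=1, duration=10.0, x_drift=2.0, width=20.0)
        with pytest.raises(ConfigurationError):
            render_kymograph(scene, [flat_truth])

    def test_truth_count_must_match(self, flat_truth):
        scene = KymoSceneConfig(n_protomers=2, width=30.0)
        with pytest.raises(ConfigurationError):
            render_kymograph(scene, [flat_truth])


class TestTopography:
    def test_zero_fraction_unimodal(self):
        img = render_topography_image(0.0, seed=1)
        assert abs(np.median(img.heights) - 4.5) < 0.05
        assert img.heights.max() < 5.5

    def test_bimodal_modes_near_membrane_and_domain(self):
        img = render_topography_image(0.30, seed=2)
        counts, edges = np.histogram(img.heights, bins=150)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lo = centers[np.argmax(counts * (centers < 6.1))]
        hi = centers[np.argmax(counts * (centers > 6.1))]
        assert abs(lo - 4.5) < 0.1
        assert abs(hi - 7.7) < 0.1

    def test_area_fraction_recovered_by_thresholding(self):
        img = render_topography_image(0.30, seed=3)
        frac = np.mean(img.heights > 6.1)
        assert abs(frac - 0.30) < 0.02

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            render_topography_image(1.5)


class TestReturnProbability:
    def test_failed_excursion_frequency(self):
        """With return probability 2/3, failed:complete excursions ~ 2:1."""
        scheme = three_state_scheme(0.3, 0.15, 0.3, 0.5, return_probability=2 / 3)
        failed = complete = 0
        for seed in range(40):
            t = simulate_state_sequence(scheme, 300.0, seed=seed)
            labs = t.state_labels
            for i in range(1, len(labs) - 1):
                if labs[i] == "int":
                    if labs[i - 1] == labs[i + 1]:
                        failed += 1
                    else:
                        complete += 1
        ratio = failed / complete
        assert abs(ratio - 2.0) < 0.2
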