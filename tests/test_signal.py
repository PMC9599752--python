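import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viewpoint4c.regions import Region
from viewpoint4c.signal import (
    DecayFit,
    SignalParams,
    fit_decay,
    normalize_local_mean,
    process_replicate,
    profile_correct,
    running_mean,
)

from conftest import make_track, track_at_distances


class TestSignalParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"norm_halfwidth": 0},
            {"smooth_window": 0},
            {"smooth_window": 4},
            {"fit_min_distance": 0},
            {"fit_min_distance": 100, "fit_max_distance": 50},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SignalParams(**kwargs)


class TestNormalizeLocalMean:
    def test_constant_window_normalizes_to_one(self):
        track = make_track([3.0] * 9, bait=Region("chr1", 440, 460))
        out = normalize_local_mean(track, SignalParams(norm_halfwidth=10_000))
        np.testing.assert_allclose(out.scores, 1.0)
        assert out.stage == "normalized"

    def test_window_mean_divides_scores(self):
        # only [2, 4, 6] fall in the window (mean 4); outside scores are
        # divided by the same mean
        track = make_track([10.0, 2.0, 4.0, 6.0, 10.0],
                           bait=Region("chr1", 245, 255))
        out = normalize_local_mean(track, SignalParams(norm_halfwidth=105))
        np.testing.assert_allclose(out.scores[1:4], [0.5, 1.0, 1.5])
        np.testing.assert_allclose(out.scores[[0, 4]], [2.5, 2.5])

    def test_in_window_mean_is_exactly_one(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.gamma(2.0, 3.0, 101), bait=Region("chr1", 5040, 5060))
        params = SignalParams(norm_halfwidth=2_000)
        out = normalize_local_mean(track, params)
        in_window = np.abs(out.midpoints - track.bait.midpoint) <= 2_000
        assert abs(out.scores[in_window].mean() - 1.0) < 1e-12

    def test_all_zero_scores_error(self):
        track = make_track([0.0, 0.0, 0.0], bait=Region("chr1", 140, 160))
        with pytest.raises(ValueError, match="zero mean"):
            normalize_local_mean(track, SignalParams(norm_halfwidth=10_000))

    def test_stage_transition_enforced(self):
        track = make_track([1.0, 2.0], stage="normalized",
                           bait=Region("chr1", 90, 110))
        with pytest.raises(ValueError, match="raw"):
            normalize_local_mean(track)


class TestRunningMean:
    def test_window_three_edge_arithmetic(self):
        track = make_track([1, 2, 3, 4, 5], stage="normalized")
        out = running_mean(track, SignalParams(smooth_window=3))
        np.testing.assert_allclose(out.scores, [1.5, 2, 3, 4, 4.5])
        assert out.stage == "smoothed"

    def test_window_wider_than_track_gives_grand_mean(self):
        track = make_track([1, 2, 3, 4, 5], stage="normalized")
        out = running_mean(track, SignalParams(smooth_window=11))
        np.testing.assert_allclose(out.scores, 3.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40),
        st.sampled_from([1, 3, 5, 11]),
        st.floats(0, 100, allow_nan=False),  # scores stay non-negative
    )
    def test_constant_preservation_shift_equivariance_and_length(self, xs, w, shift):
        params = SignalParams(smooth_window=w)
        base = running_mean(make_track(xs, stage="normalized"), params).scores
        assert len(base) == len(xs)
        shifted = running_mean(
            make_track(np.asarray(xs) + shift, stage="normalized"), params
        ).scores
        np.testing.assert_allclose(shifted, base + shift, atol=1e-6, rtol=1e-9)
        const = running_mean(make_track([5.0] * len(xs), stage="normalized"), params)
        np.testing.assert_allclose(const.scores, 5.0)

    def test_smoothing_raw_track_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            running_mean(make_track([1, 2, 3], stage="raw"))


def exact_decay_track(C=100.0, distances=(10, 100, 1000)):
    d = np.asarray(distances, dtype=float)
    return track_at_distances(d, C / d)


class TestFitDecay:
    def test_exact_power_law_intercept(self):
        track = exact_decay_track(C=100.0)
        fit = fit_decay(track, SignalParams(fit_min_distance=1, fit_max_distance=10_000))
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.fixed_slope == -1.0
        assert fit.n_points == 3

    @pytest.mark.parametrize("C", [0.5, 7.0, 1234.5])
    def test_intercept_is_log10_of_amplitude(self, C):
        fit = fit_decay(
            exact_decay_track(C=C),
            SignalParams(fit_min_distance=1, fit_max_distance=10_000),
        )
        assert fit.intercept == pytest.approx(np.log10(C), abs=1e-12)

    def test_lognormal_noise_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        d = np.sort(rng.uniform(5_000, 500_000, 200))
        noise = rng.lognormal(0.0, 0.4, 200)
        track = track_at_distances(d, (100.0 / d) * noise)
        fit = fit_decay(track)
        # log-scale lognormal noise is symmetric: the closed-form intercept
        # estimator is unbiased for log10(100) = 2
        assert abs(fit.intercept - 2.0) <= 3 * fit.stderr

    def test_zero_scores_excluded_from_fit(self):
        d = np.array([10.0, 100.0, 1000.0, 5000.0])
        s = 100.0 / d
        s[1] = 0.0
        fit = fit_decay(
            track_at_distances(d, s),
            SignalParams(fit_min_distance=1, fit_max_distance=10_000),
        )
        assert fit.n_points == 3
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)

    def test_too_few_points_error(self):
        track = exact_decay_track(distances=(10,))
        with pytest.raises(ValueError, match=">= 2"):
            fit_decay(track, SignalParams(fit_min_distance=1, fit_max_distance=20))


class TestProfileCorrect:
    params = SignalParams(fit_min_distance=1, fit_max_distance=10_000)

    def test_exact_decay_corrects_to_all_ones(self):
        track = exact_decay_track()
        fit = fit_decay(track, self.params)
        out = profile_correct(track, fit, self.params)
        np.testing.assert_allclose(out.scores, 1.0, atol=1e-9)
        assert out.stage == "profile_corrected"
        # flatness: regressing log-corrected on log-distance gives slope 0
        slope = np.polyfit(np.log10(out.distances()), np.log10(out.scores), 1)[0]
        assert abs(slope) < 1e-9

    def test_linear_in_observed_at_fixed_fit(self):
        track = exact_decay_track()
        fit = fit_decay(track, self.params)
        once = profile_correct(track, fit, self.params)
        doubled = profile_correct(
            track.with_scores(track.scores * 2, "normalized"), fit, self.params
        )
        np.testing.assert_allclose(doubled.scores, 2 * once.scores)

    def test_planted_peak_ratios_match_closed_form(self):
        d = np.array([10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0])
        s = 100.0 / d
        peak = np.zeros(len(d), dtype=bool)
        peak[2:4] = True
        s[peak] *= 3.0
        track = track_at_distances(d, s)
        fit = fit_decay(track, self.params)
        # closed form: intercept = 2 + (k/n) log10 3 with k=2 peak points
        expected_a = 2.0 + (2 / 6) * np.log10(3.0)
        assert fit.intercept == pytest.approx(expected_a, abs=1e-12)
        assert fit.intercept > 2.0
        out = profile_correct(track, fit, self.params)
        np.testing.assert_allclose(out.scores[~peak], 10 ** (2.0 - expected_a))
        np.testing.assert_allclose(out.scores[peak], 3 * 10 ** (2.0 - expected_a))

    def test_zero_distance_fragment_is_error(self):
        track = track_at_distances([0.0, 100.0], [1.0, 1.0])
        fit = DecayFit(intercept=2.0, n_points=2, fit_range=(1.0, 1e4))
        with pytest.raises(ValueError, match="exclusion"):
            profile_correct(track, fit, self.params)

    def test_zero_scores_stay_zero_and_extrapolation_flagged(self):
        d = np.array([5.0, 10.0, 100.0, 1000.0])
        s = 100.0 / d
        s[2] = 0.0
        track = track_at_distances(d, s)
        params = SignalParams(fit_min_distance=8, fit_max_distance=10_000)
        fit = fit_decay(track, params)
        out = profile_correct(track, fit, params)
        assert out.scores[2] == 0.0
        assert out.extrapolated.tolist() == [True, False, False, False]


class TestProcessReplicate:
    def test_stage_set_and_order(self):
        rng = np.random.default_rng(5)
        d = np.sort(rng.uniform(2_000, 400_000, 300))
        track = track_at_distances(d, rng.poisson(1e6 / d).astype(float), stage="raw")
        stages = process_replicate(
            track,
            excluded=Region("chr1", 999_000, 1_001_000),
            params=SignalParams(fit_min_distance=5_000, fit_max_distance=500_000),
        )
        assert set(stages) == {"raw", "normalized", "smoothed", "profile_corrected"}
        for name, t in stages.items():
            assert t.stage == name
        assert stages["profile_corrected"].meta["decay_fit"].n_points > 2
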