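import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viewpoint4c.regions import Region
from viewpoint4c.signal import SignalParams, process_replicate
from viewpoint4c.stats import (
    StatsParams,
    compare_conditions,
    dagostino_pearson,
    extract_region_scores,
    mann_whitney_u,
)

from conftest import make_track, track_at_distances


def enumeration_two_tailed_p(x, y):
    """Brute-force oracle: exact two-tailed Mann-Whitney p over all
    C(n1+n2, n1) group labelings of the pooled (tie-free) values, with U
    computed by direct pair counting."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_of(idx):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in pooled[sel]
            for b in pooled[~sel]
        )

    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    u_obs = u_of(range(n1))
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return u_obs, min(1.0, 2 * min(lo, hi))


class TestExtractRegionScores:
    def test_leaf_element_region_spans_878_bp(self):
        # printed coordinates of the conserved element measure 878 bp
        region = Region("chr3", 131_019_746, 131_020_624, "Leaf")
        assert region.length == 878

    def test_full_region_returns_all_scores(self):
        track = make_track([1, 2, 3], stage="normalized")
        out = extract_region_scores(track, Region("chr1", 0, 300))
        assert out.tolist() == [1, 2, 3]

    def test_region_between_midpoints_is_empty_with_warning(self):
        track = make_track([1, 2], width=100)  # midpoints 50, 150
        with pytest.warns(UserWarning, match="no retained fragments"):
            out = extract_region_scores(track, Region("chr1", 60, 140))
        assert out.size == 0

    def test_wrong_chromosome_is_error(self):
        track = make_track([1, 2])
        with pytest.raises(ValueError, match="chromosome"):
            extract_region_scores(track, Region("chr2", 0, 100))


class TestDagostinoPearson:
    def test_type_one_error_calibrated_on_normal_data(self):
        rng = np.random.default_rng(42)
        draws = rng.standard_normal((1000, 1000))
        rejections = sum(dagostino_pearson(row).p < 0.05 for row in draws)
        assert abs(rejections / 1000 - 0.05) < 0.02  # ~3 binomial sd

    def test_rejects_strongly_skewed_sample(self):
        rng = np.random.default_rng(7)
        res = dagostino_pearson(rng.exponential(1.0, 200))
        assert res.applicable
        assert res.p < 0.01

    def test_small_sample_not_applicable(self):
        with pytest.warns(UserWarning, match="n >= 8"):
            res = dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0])
        assert not res.applicable
        assert np.isnan(res.p)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dagostino_pearson([2.0] * 20)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p_two_tailed == pytest.approx(0.1, abs=1e-12)  # 2/20 labelings
        assert res.method == "exact"

    def test_identical_singletons_tie(self):
        res = mann_whitney_u([3.0], [3.0])
        assert res.p_two_tailed == 1.0

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.U == 8  # n^2 / 2
        assert res.p_two_tailed >= 0.99

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n1, n2 = rng.integers(1, 7, 2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            u_oracle, p_oracle = enumeration_two_tailed_p(x, y)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.U == pytest.approx(u_oracle)
            assert res.p_two_tailed == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_matches_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(0.4, 1.0, 50)
        res = mann_whitney_u(x, y)
        assert res.method == "asymptotic"
        pooled = np.concatenate([x, y])
        center = len(x) * len(y) / 2

        def u_stat(xs, ys):
            return float(
                np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :])
            )

        u_obs = u_stat(x, y)
        hits = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = u_stat(perm[:50], perm[50:])
            hits += abs(u - center) >= abs(u_obs - center)
        assert abs(res.p_two_tailed - hits / n_perm) < 0.01

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=12),
        st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=12),
    )
    def test_symmetry_and_u_complement(self, x, y):
        rx = mann_whitney_u(x, y)
        ry = mann_whitney_u(y, x)
        assert rx.p_two_tailed == pytest.approx(ry.p_two_tailed, abs=1e-9)
        assert rx.U + ry.U == pytest.approx(len(x) * len(y))

    def test_star_mapping_is_monotone_in_p(self):
        params = StatsParams()
        ps = [5e-5, 1e-4, 5e-4, 5e-3, 0.04, 0.05, 0.5]
        labels = [params.stars(p) for p in ps]
        assert labels == ["****", "****", "***", "**", "*", "ns", "ns"]
        order = {"****": 4, "***": 3, "**": 2, "*": 1, "ns": 0}
        assert sorted((order[l] for l in labels), reverse=True) == [
            order[l] for l in labels
        ]


def _replicates(scores_list, stage_params=None):
    """Build processed replicate dicts from raw count vectors placed on an
    exact-decay layout, for compare_conditions tests."""
    params = stage_params or SignalParams(fit_min_distance=5_000,
                                          fit_max_distance=500_000)
    reps = []
    rng = np.random.default_rng(1)
    d = np.sort(rng.uniform(6_000, 400_000, len(scores_list[0])))
    for scores in scores_list:
        track = track_at_distances(d, np.asarray(scores, float), stage="raw")
        reps.append(process_replicate(track, params=params))
    return reps


class TestCompareConditions:
    region = Region("chr1", 1_000_000, 1_500_000)

    def test_self_comparison_is_not_significant(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, 80).astype(float) + 1
        reps = _replicates([counts, counts * 2])
        results = compare_conditions(reps, reps, self.region)
        assert set(results) == {"normalized", "profile_corrected"}
        for res in results.values():
            assert res.p_two_tailed >= 0.99
            assert res.stars == "ns"

    def test_missing_stage_names_replicate(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, 80).astype(float) + 1
        reps = _replicates([counts])
        broken = [dict(reps[0])]
        del broken[0]["profile_corrected"]
        with pytest.raises(ValueError, match="condition B replicate 0"):
            compare_conditions(reps, broken, self.region)

    def test_too_few_fragments_in_region_is_error(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, 80).astype(float) + 1
        reps = _replicates([counts])
        tiny = Region("chr1", 1_000_000, 1_000_001)
        with pytest.raises(ValueError, match="fewer than 2"), pytest.warns(UserWarning):
            compare_conditions(reps, reps, tiny)
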