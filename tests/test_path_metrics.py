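"""Trace and path quantifications against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cxsteer import (
    OmegaTrace,
    PathTable,
    UndefinedAngleError,
    circular_mean_se,
    directional_error,
    discretise_path,
    preferred_side_proportion,
    signed_rank_exact,
    turn_ratio,
    wrap_deg,
)


class TestTurnRatio:
    def test_all_right_is_one(self):
        t = np.arange(0, 12.1, 0.1)
        assert turn_ratio(OmegaTrace(t, np.full_like(t, 10.0))) == 1.0

    def test_balanced_is_zero(self):
        t = np.arange(0, 12.1, 0.1)
        omega = np.where(t < 6, 10.0, -10.0)
        assert turn_ratio(OmegaTrace(t, omega)) == pytest.approx(0.0, abs=0.02)

    def test_never_turning_returns_zero(self):
        t = np.arange(0, 5.0, 0.1)
        assert turn_ratio(OmegaTrace(t, np.zeros_like(t))) == 0.0

    def test_against_fine_grid_quadrature_oracle(self):
        # omega(t) = sin(t) + 0.3 sampled at 10 Hz over 12 s vs a 2e6-point
        # quadrature of the continuous signal
        t = np.arange(0, 12.0001, 0.1)
        value = turn_ratio(OmegaTrace(t, np.sin(t) + 0.3))
        td = np.linspace(0, 12, 2_000_001)
        w = np.sin(td) + 0.3
        right = np.trapezoid(np.clip(w, 0, None), td)
        left = np.trapezoid(np.clip(-w, 0, None), td)
        assert value == pytest.approx((right - left) / (right + left), abs=1e-3)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 12, 50))
        t = np.unique(t)
        omega = rng.normal(0, 20, len(t))
        v = turn_ratio(OmegaTrace(t, omega))
        assert -1.0 <= v <= 1.0
        assert turn_ratio(OmegaTrace(t, -omega)) == pytest.approx(-v)

    def test_validation(self):
        with pytest.raises(ValueError):
            OmegaTrace(np.array([0.0, 0.0, 1.0]), np.zeros(3))  # non-monotone
        with pytest.raises(ValueError):
            OmegaTrace(np.array([0.0, 1.0]), np.array([1.0, np.nan]))


class TestPreferredSide:
    def test_all_right_is_one(self):
        t = np.arange(0, 12, 0.1)
        assert preferred_side_proportion(OmegaTrace(t, np.ones_like(t))) == 1.0

    def test_three_quarters(self):
        # 9 s right then 3 s left at 10 Hz
        t = np.arange(0, 12, 0.1)
        omega = np.where(t < 9, 5.0, -5.0)
        assert preferred_side_proportion(OmegaTrace(t, omega)) == pytest.approx(0.75, abs=0.01)

    def test_invariant_under_sign_flip(self, rng):
        t = np.arange(0, 10, 0.1)
        omega = rng.normal(0.5, 3, len(t))
        a = preferred_side_proportion(OmegaTrace(t, omega))
        b = preferred_side_proportion(OmegaTrace(t, -omega))
        assert a == pytest.approx(b)
        assert 0.5 <= a <= 1.0

    def test_tie_and_silence_give_half(self):
        t = np.arange(0, 4, 1.0)
        assert preferred_side_proportion(OmegaTrace(t, np.zeros(4))) == 0.5


class TestDiscretisePath:
    def test_straight_path(self):
        t = np.arange(4.0)
        path = PathTable(t, np.array([0.0, 12, 24, 36]), np.zeros(4))
        seg = discretise_path(path, 12.0)
        assert len(seg.vertices) == 4
        np.testing.assert_allclose(seg.turn_angles, 0.0, atol=1e-12)
        np.testing.assert_allclose(seg.bearings, 0.0, atol=1e-12)

    def test_right_angle_elbow(self):
        # arms of 24 each, resampled at 12: one 90-deg junction
        x = np.array([0.0, 24.0, 24.0])
        y = np.array([0.0, 0.0, 24.0])
        seg = discretise_path(PathTable(np.arange(3.0), x, y), 12.0)
        turns = np.round(seg.turn_angles, 9)
        assert np.sum(turns == 90.0) == 1
        assert np.sum(turns == 0.0) == len(turns) - 1

    def test_arc_length_bookkeeping(self, rng):
        # random walk: resampled polyline length = floor(total/L) * L
        steps = rng.normal(0, 1, size=(300, 2))
        xy = np.cumsum(steps, axis=0)
        path = PathTable(np.arange(300.0), xy[:, 0], xy[:, 1])
        total = np.linalg.norm(np.diff(xy, axis=0), axis=1).sum()
        L = 3.7
        seg = discretise_path(path, L)
        # vertices sit at exact multiples of L along the path, but chords can
        # cut corners, so compare the along-path spacing
        n = int(np.floor(total / L))
        assert len(seg.vertices) == n + 1
        chord = np.linalg.norm(np.diff(seg.vertices, axis=0), axis=1)
        assert np.all(chord <= L + 1e-9)

    def test_round_trip_bearings_reconstruct_vertices(self, rng):
        xy = np.cumsum(rng.normal(0, 1, size=(100, 2)), axis=0)
        path = PathTable(np.arange(100.0), xy[:, 0], xy[:, 1])
        seg = discretise_path(path, 2.0)
        chord = np.linalg.norm(np.diff(seg.vertices, axis=0), axis=1)
        rebuilt = [seg.vertices[0]]
        for bearing, c in zip(seg.bearings, chord):
            prev = rebuilt[-1]
            rad = np.deg2rad(bearing)
            rebuilt.append(prev + c * np.array([np.cos(rad), np.sin(rad)]))
        np.testing.assert_allclose(np.array(rebuilt), seg.vertices, atol=1e-9)

    def test_too_short_rejected_with_minimum(self):
        path = PathTable(np.arange(2.0), np.array([0.0, 5.0]), np.zeros(2))
        with pytest.raises(ValueError, match="2 \\* resample_length"):
            discretise_path(path, 12.0)

    def test_turn_angles_bounded(self, rng):
        xy = np.cumsum(rng.normal(0, 1, size=(200, 2)), axis=0)
        seg = discretise_path(PathTable(np.arange(200.0), xy[:, 0], xy[:, 1]), 2.5)
        assert np.all(seg.turn_angles >= 0.0)
        assert np.all(seg.turn_angles <= 180.0)


class TestDirectionalError:
    @pytest.mark.parametrize(
        "end,goal,expected",
        [((10.0, 0.0), 0.0, 0.0), ((-10.0, 0.0), 0.0, 180.0), ((10.0, 10.0), 0.0, 45.0)],
    )
    def test_basic_geometry(self, end, goal, expected):
        path = PathTable(np.arange(2.0), np.array([0.0, end[0]]), np.array([0.0, end[1]]))
        assert directional_error(path, goal) == pytest.approx(expected)

    def test_zero_displacement_rejected(self):
        path = PathTable(np.arange(3.0), np.array([0.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        with pytest.raises(UndefinedAngleError):
            directional_error(path, 0.0)

    @given(rot=st.floats(-180, 180), seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_global_rotation(self, rot, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 1, size=(20, 2)), axis=0)
        goal = float(rng.uniform(-180, 180))
        path = PathTable(np.arange(20.0), xy[:, 0], xy[:, 1])
        rad = np.deg2rad(rot)
        R = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        xyr = xy @ R.T
        rotated = PathTable(np.arange(20.0), xyr[:, 0], xyr[:, 1])
        e1 = directional_error(path, goal)
        e2 = directional_error(rotated, goal + np.rad2deg(rad))
        assert e1 == pytest.approx(e2, abs=1e-6)


class TestCircularMeanSE:
    def test_wraparound_pair(self):
        mean, se = circular_mean_se([10.0, 350.0])
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_identical_angles_zero_se(self):
        mean, se = circular_mean_se([42.0, 42.0, 42.0])
        assert mean == pytest.approx(42.0)
        assert se == pytest.approx(0.0, abs=1e-7)

    def test_antipodal_rejected(self):
        with pytest.raises(UndefinedAngleError):
            circular_mean_se([0.0, 180.0])

    def test_ids_average_within_individuals_first(self):
        angles = [0.0, 0.0, 0.0, 90.0]  # three samples of one id, one of another
        ids = [1, 1, 1, 2]
        mean, _ = circular_mean_se(angles, ids)
        assert mean == pytest.approx(45.0)  # unweighted across the two ids

    def test_von_mises_coverage(self):
        # estimated mean lies within 3 SE of the generating mean in ~99% of
        # replicates
        rng = np.random.default_rng(0)
        true_mean = 30.0
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            sample = np.rad2deg(rng.vonmises(np.deg2rad(true_mean), 4.0, size=20))
            mean, se = circular_mean_se(sample)
            if abs(wrap_deg(mean - true_mean)) < 3 * se:
                hits += 1
        assert hits / n_rep >= 0.99


def brute_force_signed_rank(values, alternative):
    """Oracle: explicit iteration over all 2^n sign assignments."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    n = len(v)
    ws = [
        sum(r for r, pick in zip(ranks, signs) if pick)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs - 1e-12)
    p_less = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestSignedRankExact:
    def test_n6_all_positive(self):
        # the field-experiment sample size: six ants all turning the same
        # way gives exactly 1/64
        p = signed_rank_exact([3.0, 1.2, 0.7, 2.2, 5.0, 0.1], "greater")
        assert p == 0.015625
        assert round(p, 4) == 0.0156

    def test_n1(self):
        assert signed_rank_exact([2.0], "greater") == 0.5

    def test_published_table_n10(self):
        # sample with positive-rank sum 10 at n = 10: one-sided p = 0.0420
        v = [1, 2, 3, 4, -5, -6, -7, -8, -9, -10]
        assert signed_rank_exact(v, "less") == pytest.approx(0.0419921875)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, alternative, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        v = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding creates ties/zeros
        if np.all(v == 0):
            v[0] = 0.5
        assert signed_rank_exact(v, alternative) == pytest.approx(
            brute_force_signed_rank(v, alternative)
        )

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0.5, 1.0, 12)  # continuous, no ties
        for alt_ours, alt_scipy in [
            ("greater", "greater"),
            ("less", "less"),
            ("two_sided", "two-sided"),
        ]:
            ours = signed_rank_exact(v, alt_ours)
            ref = stats.wilcoxon(v, alternative=alt_scipy, mode="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_two_sided_is_doubled_minimum(self, rng):
        for _ in range(10):
            v = rng.normal(0.2, 1.0, 8)
            lo = min(signed_rank_exact(v, "greater"), signed_rank_exact(v, "less"))
            assert signed_rank_exact(v, "two_sided") == pytest.approx(min(1.0, 2 * lo))

    def test_zeros_dropped_all_zero_rejected(self):
        assert signed_rank_exact([0.0, 0.0, 1.0], "greater") == 0.5
        with pytest.raises(ValueError):
            signed_rank_exact([0.0, 0.0], "greater")

    def test_large_n_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_exact(np.ones(26), "greater")
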