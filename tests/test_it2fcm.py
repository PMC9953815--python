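"""Interval type-2 fuzzy c-means core: bounds, Karnik–Mendel, fit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coat2fcm as c2
from coat2fcm.errors import DegenerateClusterError, InvalidArgumentError
from coat2fcm.it2fcm import (
    FuzzifierPair,
    LeftRightMembership,
    MembershipInterval,
    CentroidInterval,
)
from tests.conftest import matched_centroid_error, best_label_agreement


def brute_force_km(xcol, w_low, w_up):
    """Exhaustive 2^N oracle: extreme weighted averages over bound choices."""
    vals = []
    for bits in itertools.product([0, 1], repeat=len(xcol)):
        w = np.where(bits, w_up, w_low)
        if w.sum() > 0:
            vals.append(float((w * xcol).sum() / w.sum()))
    return min(vals), max(vals)


class TestFuzzifierPair:
    def test_orders_pair(self):
        f = FuzzifierPair(3.0, 2.0)
        assert (f.m1, f.m2) == (2.0, 3.0)
        assert f.effective == 2.5

    @pytest.mark.parametrize("m1,m2", [(1.0, 2.0), (2.0, 0.5)])
    def test_rejects_fuzzifier_at_or_below_one(self, m1, m2):
        with pytest.raises(InvalidArgumentError):
            FuzzifierPair(m1, m2)


class TestMembershipBounds:
    def test_equidistant_pattern_gets_half_membership(self):
        mi = c2.membership_bounds(
            np.array([[1.0]]), np.array([[0.0], [2.0]]), FuzzifierPair(2.0, 3.0)
        )
        assert mi.lower == pytest.approx(np.full((1, 2), 0.5))
        assert mi.upper == pytest.approx(np.full((1, 2), 0.5))

    def test_zero_distance_is_crisp(self):
        mi = c2.membership_bounds(
            np.array([[0.0]]), np.array([[0.0], [2.0]]), FuzzifierPair(2.0, 3.0)
        )
        assert mi.lower[0, 0] == mi.upper[0, 0] == 1.0
        assert mi.lower[0, 1] == mi.upper[0, 1] == 0.0

    def test_single_cluster_all_ones(self):
        mi = c2.membership_bounds(
            np.arange(5.0)[:, None], np.array([[2.0]]), FuzzifierPair(2.0, 3.0)
        )
        assert (mi.lower == 1.0).all() and (mi.upper == 1.0).all()

    def test_lower_at_most_upper_random(self):
        rng = np.random.default_rng(4)
        mi = c2.membership_bounds(
            rng.normal(size=(40, 3)), rng.normal(size=(4, 3)), FuzzifierPair(1.5, 4.0)
        )
        assert (mi.lower <= mi.upper + 1e-12).all()
        # each fuzzifier's memberships sum to 1 per row, so the bound
        # row-sums bracket 1 from below and above
        assert (mi.lower.sum(axis=1) <= 1.0 + 1e-9).all()
        assert (mi.upper.sum(axis=1) >= 1.0 - 1e-9).all()


class TestApplyHesitation:
    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_alpha_one_is_identity(self, u):
        mi = MembershipInterval(lower=np.array([[u]]), upper=np.array([[u]]))
        out = c2.apply_hesitation(mi, 1.0)
        assert out.lower[0, 0] == pytest.approx(u, abs=1e-12)

    @pytest.mark.parametrize("u", [0.0, 1.0])
    def test_endpoints_fixed(self, u):
        mi = MembershipInterval(lower=np.array([[u]]), upper=np.array([[u]]))
        out = c2.apply_hesitation(mi, 2.0)
        assert out.lower[0, 0] == pytest.approx(u)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(1.0, 5.0))
    @settings(deadline=None, max_examples=100)
    def test_ordering_and_range_preserved(self, a, b, alpha):
        lo, hi = sorted((a, b))
        mi = MembershipInterval(lower=np.array([[lo]]), upper=np.array([[hi]]))
        out = c2.apply_hesitation(mi, alpha)
        assert out.lower[0, 0] <= out.upper[0, 0] + 1e-12
        assert 0.0 <= out.lower[0, 0] <= 1.0 and 0.0 <= out.upper[0, 0] <= 1.0

    def test_nonpositive_alpha_rejected(self):
        mi = MembershipInterval(lower=np.zeros((1, 1)), upper=np.ones((1, 1)))
        with pytest.raises(InvalidArgumentError):
            c2.apply_hesitation(mi, 0.0)


class TestKarnikMendel:
    def test_crisp_weights_collapse_to_weighted_mean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 1))
        u = rng.uniform(0.1, 1.0, size=(8, 2))
        mi = MembershipInterval(lower=u, upper=u)
        f = FuzzifierPair(2.0, 2.0)
        vl, vr, _ = c2.karnik_mendel(x, mi, f, 0)
        w = u[:, 0] ** 2.0
        expected = (w * x[:, 0]).sum() / w.sum()
        assert vl[0] == pytest.approx(expected, abs=1e-12)
        assert vr[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_instance_gives_opposite_endpoints(self):
        x = np.array([[-1.0], [1.0]])
        mi = MembershipInterval(
            lower=np.array([[0.2], [0.2]]), upper=np.array([[0.8], [0.8]])
        )
        vl, vr, _ = c2.karnik_mendel(x, mi, FuzzifierPair(2.0, 2.0), 0)
        assert vl[0] == pytest.approx(-vr[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        x = rng.normal(size=(n, 1))
        lo = rng.uniform(0.0, 1.0, size=(n, 1))
        hi = lo + rng.uniform(0.0, 1.0 - lo)
        mi = MembershipInterval(lower=lo, upper=hi)
        f = FuzzifierPair(1.8, 3.2)
        vl, vr, _ = c2.karnik_mendel(x, mi, f, 0)
        bl, br = brute_force_km(x[:, 0], lo[:, 0] ** f.effective, hi[:, 0] ** f.effective)
        assert vl[0] == pytest.approx(bl, abs=1e-9)
        assert vr[0] == pytest.approx(br, abs=1e-9)

    def test_left_right_memberships_pick_existing_bounds(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 1))
        lo = rng.uniform(0.0, 0.5, size=(10, 1))
        hi = lo + 0.3
        mi = MembershipInterval(lower=lo, upper=hi)
        _, _, lr = c2.karnik_mendel(x, mi, FuzzifierPair(2.0, 2.0), 0)
        for i in range(10):
            assert lr.left[i] in (lo[i, 0], hi[i, 0])
            assert lr.right[i] in (lo[i, 0], hi[i, 0])

    def test_all_zero_weights_raise(self):
        mi = MembershipInterval(lower=np.zeros((3, 1)), upper=np.zeros((3, 1)))
        with pytest.raises(DegenerateClusterError):
            c2.karnik_mendel(np.arange(3.0)[:, None], mi, FuzzifierPair(2.0, 2.0), 0)


class TestTypeReduceDefuzzify:
    def test_type_reduce_midpoint_and_containment(self):
        ci = CentroidInterval(v_left=np.array([[0.0, 1.0]]), v_right=np.array([[2.0, 1.0]]))
        v = c2.type_reduce(ci)
        assert v == pytest.approx(np.array([[1.0, 1.0]]))
        assert ((ci.v_left <= v) & (v <= ci.v_right)).all()

    def test_defuzzify_midpoint_then_normalize(self):
        lr = LeftRightMembership(left=np.array([[1.0, 0.0]]), right=np.array([[0.0, 1.0]]))
        u = c2.defuzzify_membership(lr)
        assert u == pytest.approx(np.array([[0.5, 0.5]]))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        lr = LeftRightMembership(
            left=rng.uniform(0.01, 1, size=(20, 4)), right=rng.uniform(0.01, 1, size=(20, 4))
        )
        u = c2.defuzzify_membership(lr)
        assert u.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-9)


class TestObjective:
    def test_single_cluster_all_ones_is_total_scatter(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(15, 2))
        v = np.array([[0.5, -0.5]])
        u = np.ones((15, 1))
        got = c2.objective(x, u, v, FuzzifierPair(3.0, 4.0))
        assert got == pytest.approx(((x - v) ** 2).sum())

    def test_perfect_centers_zero_objective(self):
        x = np.array([[0.0], [1.0], [2.0]])
        u = np.eye(3)
        assert c2.objective(x, u, x, FuzzifierPair(2.0, 2.0)) == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 3))
        v = rng.normal(size=(4, 3))
        u = rng.uniform(0, 1, size=(12, 4))
        f = FuzzifierPair(1.7, 2.9)
        naive = sum(
            u[i, j] ** f.effective * ((x[i] - v[j]) ** 2).sum()
            for i in range(12)
            for j in range(4)
        )
        assert c2.objective(x, u, v, f) == pytest.approx(naive, rel=1e-12)


class TestIt2fcmFit:
    def test_degenerates_to_classic_fcm(self, mixture3):
        init = mixture3.true_centers + 0.3
        a = c2.it2fcm_fit(mixture3.points, 3, FuzzifierPair(2.0, 2.0), init_centroids=init)
        b = c2.fcm_fit(mixture3.points, 3, 2.0, init_centroids=init)
        assert np.abs(a.centroids - b.centroids).max() < 1e-6
        assert a.iterations_run == b.iterations_run

    def test_single_cluster_centroid_is_mean(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(30, 2))
        m = c2.it2fcm_fit(x, 1, FuzzifierPair(2.0, 3.0))
        assert m.centroids[0] == pytest.approx(x.mean(axis=0), abs=1e-6)

    def test_recovers_mixture_centers(self, mixture3):
        m = c2.it2fcm_fit(mixture3.points, 3, FuzzifierPair(2.0, 2.5), seed=1)
        assert matched_centroid_error(m.centroids, mixture3.true_centers) < 0.5
        assert best_label_agreement(m.labels(), mixture3.labels, 3) >= 0.95

    def test_objective_monotone_without_hesitation(self, mixture3):
        """FCM-type alternation: objective never increases across iterations."""
        from coat2fcm.it2fcm import _full_iteration, objective as obj

        x = mixture3.points
        f = FuzzifierPair(1.8, 2.6)
        rng = np.random.default_rng(11)
        v = x[rng.choice(len(x), 3, replace=False)]
        prev = None
        for _ in range(12):
            v, u = _full_iteration(x, v, f, None, None)
            val = obj(x, u, v, f)
            if prev is not None:
                assert val <= prev + 1e-8
            prev = val

    def test_centroids_within_data_range(self, mixture3):
        m = c2.it2fcm_fit(
            mixture3.points, 3, FuzzifierPair(1.5, 4.0), hesitation_alpha=2.0, seed=2
        )
        lo, hi = mixture3.points.min(axis=0), mixture3.points.max(axis=0)
        assert ((m.centroids >= lo - 1e-9) & (m.centroids <= hi + 1e-9)).all()

    def test_membership_rows_sum_to_one(self, mixture3):
        m = c2.it2fcm_fit(mixture3.points, 3, FuzzifierPair(2.0, 3.0), seed=3)
        assert m.memberships.sum(axis=1) == pytest.approx(np.ones(600), abs=1e-6)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(InvalidArgumentError):
            c2.it2fcm_fit(np.zeros((3, 1)), 4, FuzzifierPair(2.0, 2.0))
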