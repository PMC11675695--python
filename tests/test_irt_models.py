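import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iftirt import (
    Binary2PLItem,
    ItemSet,
    LinearItem,
    NRMItem,
    RHItem,
    irf,
    irf_2pl,
    irf_derivative,
    irf_nrm,
    irf_rh,
    numerical_derivative,
)
from iftirt.irt_models import HALF_LOGISTIC_SCALE, RHScale, rh_is_nonmonotonic

finite_theta = st.floats(-6, 6, allow_nan=False)
moderate = st.floats(-3, 3, allow_nan=False)
pos_slope = st.floats(0.1, 4, allow_nan=False)


class TestItemTypes:
    def test_linear_standardized_ties_parameters(self):
        it = LinearItem.standardized(0.36)
        assert it.unique_variance == pytest.approx(0.36)
        assert it.loading**2 == pytest.approx(1 - 0.36)

    def test_linear_rejects_nonpositive_unique_variance(self):
        with pytest.raises(ValueError, match="Heywood"):
            LinearItem(0, 1, 0.0)
        with pytest.raises(ValueError, match="Heywood"):
            LinearItem(0, 1, -0.5)

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.1, 1.3])
    def test_linear_standardized_rejects_bad_communality(self, h2):
        with pytest.raises(ValueError):
            LinearItem.standardized(h2)

    def test_2pl_theta_star(self):
        assert Binary2PLItem(1, 2).theta_star == pytest.approx(-0.5)
        with pytest.raises(ValueError):
            Binary2PLItem(1, 0).theta_star

    def test_asymptote_validation(self):
        with pytest.raises(ValueError):
            Binary2PLItem(0, 1, lower_asymptote=-0.1)
        with pytest.raises(ValueError):
            Binary2PLItem(0, 1, lower_asymptote=0.5, upper_asymptote=0.4)
        assert Binary2PLItem(0, 1, 0.2, 0.95).family == "4pl"

    def test_nrm_requires_two_categories_and_sum_to_zero(self):
        with pytest.raises(ValueError, match="K"):
            NRMItem([0.0], [0.0])
        with pytest.raises(ValueError, match="sum-to-zero"):
            NRMItem([1.0, 0.5], [0.0, 0.0])

    def test_nrm_baseline_conversion_preserves_probabilities(self):
        a, g = [0.0, 1.0, -0.5], [0.0, 0.7, 1.1]
        it = NRMItem.from_baseline(a, g)
        assert sum(it.alphas) == pytest.approx(0, abs=1e-12)
        assert sum(it.gammas) == pytest.approx(0, abs=1e-12)
        th = np.linspace(-3, 3, 7)
        # brute-force softmax of the ORIGINAL baseline parameters
        z = np.array(a) + np.outer(th, np.array(g))
        expect = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(irf_nrm(it, th), expect, atol=1e-12)

    def test_itemset_unique_labels_and_single_family(self):
        with pytest.raises(ValueError, match="unique"):
            ItemSet([Binary2PLItem(0, 1)] * 2, ["a", "a"])
        with pytest.raises(ValueError, match="family"):
            ItemSet([Binary2PLItem(0, 1), RHItem(0, 1, 0)])
        with pytest.raises(ValueError):
            ItemSet([])

    def test_itemset_drop(self):
        s = ItemSet([Binary2PLItem(0, 1), Binary2PLItem(0, 2)], ["a", "b"])
        assert s.drop(["a"]).labels == ("b",)
        with pytest.raises(ValueError):
            s.drop(["a", "b"])
        with pytest.raises(KeyError):
            s.drop(["zzz"])


class TestIRF2PL:
    def test_symmetry_at_zero(self):
        assert irf_2pl(Binary2PLItem(0, 1), 0.0) == pytest.approx(0.5)

    def test_half_at_theta_star(self):
        item = Binary2PLItem(1, 2)
        assert irf_2pl(item, item.theta_star) == pytest.approx(0.5)

    def test_hand_evaluated_value(self):
        # exp(2)/(1+exp(2)) computed by hand
        assert irf_2pl(Binary2PLItem(0, 2), 1.0) == pytest.approx(
            0.8807970779778823, abs=1e-15
        )

    def test_rejects_nonfinite_theta(self):
        with pytest.raises(ValueError):
            irf_2pl(Binary2PLItem(0, 1), np.inf)
        with pytest.raises(ValueError):
            irf_2pl(Binary2PLItem(0, 1), [0.0, np.nan])

    def test_4pl_with_trivial_asymptotes_bit_consistent(self, default_grid):
        th = default_grid.values
        a = irf_2pl(Binary2PLItem(0.3, 1.7), th)
        b = irf_2pl(Binary2PLItem(0.3, 1.7, 0.0, 1.0), th)
        assert np.max(np.abs(a - b)) < 1e-12

    @given(eta=moderate, xi=pos_slope, th=finite_theta)
    @settings(max_examples=60, deadline=None)
    def test_probabilities_in_open_unit_interval_and_monotone(self, eta, xi, th):
        item = Binary2PLItem(eta, xi)
        p = irf_2pl(item, th)
        assert 0.0 < p < 1.0
        assert irf_2pl(item, th + 0.1) > p


class TestIRFRH:
    def test_scale_is_one_at_origin(self):
        lam_eta = 1 / (1 + math.exp(-0.7))  # Lambda(eta)
        for delta in (-2.0, 0.0, 3.0):
            assert irf_rh(RHItem(0.7, 1.3, delta), 0.0) == pytest.approx(lam_eta)

    def test_delta_zero_reduces_to_2pl_bitwise(self, default_grid):
        th = default_grid.values
        a = irf_rh(RHItem(0.0, 1.0, 0.0), th)
        b = irf_2pl(Binary2PLItem(0.0, 1.0), th)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_mr3_shape_long_tail(self, default_grid):
        # extreme negative-delta item: saturates near 1 far left, hugs 0.5 right
        th = default_grid.values
        p = irf_rh(RHItem(1.03, -1.29, -2.45), th)
        # decreasing through the bulk of the range (a shallow non-monotone
        # dip past theta ~ 1.2 is a known RH feature, flagged separately)
        assert np.all(np.diff(p[th <= 1.2]) < 0)
        assert p[0] > 0.999
        assert abs(p[-1] - 0.5) < 1e-2
        # drop concentrated near the center: right tail much flatter than core
        core_drop = p[np.searchsorted(th, -1.0)] - p[np.searchsorted(th, 1.0)]
        right_drop = p[np.searchsorted(th, 2.0)] - p[-1]
        assert core_drop > 10 * right_drop

    def test_pluggable_scale(self, default_grid):
        unit = RHScale(
            lambda d, t: np.ones_like(t),
            lambda d, t: np.zeros_like(t),
            lambda d, t: np.zeros_like(t),
        )
        item = RHItem(0.5, 1.0, 5.0, scale=unit)
        th = default_grid.values
        np.testing.assert_allclose(
            irf_rh(item, th), irf_2pl(Binary2PLItem(0.5, 1.0), th), atol=1e-15
        )

    def test_nonmonotonic_flag(self, default_grid):
        th = default_grid.values
        with pytest.warns(UserWarning, match="non-monotonic"):
            assert rh_is_nonmonotonic(RHItem(1.03, -1.29, -2.45), np.linspace(-8, 8, 801))
        assert not rh_is_nonmonotonic(RHItem(0.0, 1.0, 0.0), th)


class TestIRFNRM:
    def test_uniform_under_equal_parameters(self):
        it = NRMItem([0.0] * 4, [0.0] * 4)
        np.testing.assert_allclose(irf_nrm(it, 1.7), [0.25] * 4, atol=1e-15)

    def test_k2_reduction_to_2pl(self, default_grid):
        a, g = 0.8, 1.4
        it = NRMItem([-a / 2, a / 2], [-g / 2, g / 2])
        th = default_grid.values
        p2 = irf_nrm(it, th)[:, 1]
        np.testing.assert_allclose(p2, irf_2pl(Binary2PLItem(a, g), th), atol=1e-12)

    @given(
        th=finite_theta,
        a=st.lists(st.floats(-2, 2), min_size=3, max_size=6),
        g=st.lists(st.floats(-2, 2), min_size=3, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_probabilities_sum_to_one(self, th, a, g):
        k = min(len(a), len(g))
        it = NRMItem.from_baseline(a[:k], g[:k])
        p = irf_nrm(it, th)
        assert np.all(p > 0) and np.all(p < 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestDerivatives:
    def test_2pl_max_first_derivative_is_slope_over_four(self, default_grid):
        th = default_grid.values
        assert irf_derivative(Binary2PLItem(0, 4), th, 1).max() == pytest.approx(1.0)
        assert irf_derivative(Binary2PLItem(0, 5), 0.0, 1) == pytest.approx(1.25)

    def test_2pl_derivative_max_located_at_theta_star(self, default_grid):
        item = Binary2PLItem(1.2, 2.0)
        th = default_grid.values
        d1 = irf_derivative(item, th, 1)
        assert abs(th[np.argmax(d1)] - item.theta_star) <= default_grid.step

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            irf_derivative(Binary2PLItem(0, 1), 0.0, order=3)

    def test_nrm_derivative_sums_vanish(self, rng):
        it = NRMItem.from_baseline(rng.normal(size=5), rng.normal(size=5))
        th = np.linspace(-4, 4, 33)
        for order in (1, 2):
            d = irf_derivative(it, th, order)
            np.testing.assert_allclose(d.sum(axis=-1), 0.0, atol=1e-14)

    def test_linear_derivatives(self):
        it = LinearItem(0.5, 1.7, 0.8)
        th = np.linspace(-2, 2, 5)
        np.testing.assert_allclose(irf_derivative(it, th, 1), 1.7)
        np.testing.assert_allclose(irf_derivative(it, th, 2), 0.0)

    @pytest.mark.parametrize(
        "item",
        [
            Binary2PLItem(0.0, 1.0),
            Binary2PLItem(-1.0, 2.5, 0.15, 0.95),
            RHItem(1.03, -1.29, -2.45),
            RHItem(0.82, 0.47, 0.94),
        ],
        ids=["2pl", "4pl", "rh-neg-delta", "rh-pos-delta"],
    )
    @pytest.mark.parametrize("order", [1, 2])
    def test_analytic_matches_numerical(self, item, order, default_grid):
        th = default_grid.values
        analytic = irf_derivative(item, th, order)
        numeric = numerical_derivative(irf(item, th), th, order)
        # the extreme-delta RH curvature pushes the O(h^2) interior error of
        # the second difference slightly past 1e-4 on the 0.01 grid
        tol = 2e-4 if (order == 2 and getattr(item, "hetero", 0) == -2.45) else 1e-4
        assert np.max(np.abs(analytic - numeric)) < tol

    def test_nrm_analytic_matches_numerical(self, rng, default_grid):
        it = NRMItem.from_baseline(rng.normal(size=4), rng.normal(size=4))
        th = default_grid.values
        p = irf(it, th)
        for order in (1, 2):
            analytic = irf_derivative(it, th, order)
            numeric = numerical_derivative(p, th, order)
            assert np.max(np.abs(analytic - numeric)) < 1e-4


class TestNumericalDerivative:
    def test_constant_curve(self):
        th = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(numerical_derivative(np.ones(11), th, 1), 0.0, atol=1e-12)
        np.testing.assert_allclose(numerical_derivative(np.ones(11), th, 2), 0.0, atol=1e-12)

    def test_linear_curve_slope(self):
        th = np.linspace(-2, 2, 41)
        d = numerical_derivative(3.5 * th + 1, th, 1)
        np.testing.assert_allclose(d, 3.5, atol=1e-10)

    def test_matches_closed_form_on_fine_grid(self, default_grid):
        th = default_grid.values
        item = Binary2PLItem(0, 1)
        d = numerical_derivative(irf_2pl(item, th), th, 1)
        assert np.max(np.abs(d - irf_derivative(item, th, 1))) < 1e-4

    def test_requires_three_points_and_uniform_grid(self):
        with pytest.raises(ValueError, match="3 grid points"):
            numerical_derivative([1.0, 2.0], [0.0, 1.0], 1)
        with pytest.raises(ValueError, match="uniform"):
            numerical_derivative([1.0, 2.0, 3.0], [0.0, 0.5, 2.0], 1)
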