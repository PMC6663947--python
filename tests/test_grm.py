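"""Graded-response-model primitives: trace lines, information, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradedform.data import MISSING, ResponseMatrix
from gradedform.grm import (ItemBank, ItemParameters, ThetaGrid, category_prob,
                            cumulative_prob, expected_total_score, icc_curve,
                            item_information, reliability_from_information,
                            score_respondents)
from gradedform.grm import test_information as tif


def random_item(draw_a, draw_b_vals, item_id="rnd"):
    thresholds = np.sort(np.asarray(draw_b_vals, float))
    thresholds += np.arange(len(thresholds)) * 1e-3  # enforce strict order
    return ItemParameters(item_id=item_id, slope=draw_a, thresholds=thresholds)


item_strategy = st.builds(
    random_item,
    draw_a=st.floats(0.3, 5.0),
    draw_b_vals=st.lists(st.floats(-3.0, 3.0), min_size=1, max_size=6),
)


class TestItemParameters:
    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            ItemParameters("x", slope=0.0, thresholds=np.array([0.0]))

    def test_rejects_unordered_thresholds(self):
        with pytest.raises(ValueError):
            ItemParameters("x", slope=1.0, thresholds=np.array([1.0, 0.5]))

    def test_five_categories_have_four_thresholds(self, toy_item):
        assert toy_item.n_categories == 5
        assert toy_item.thresholds.size == 4


class TestCumulativeProb:
    def test_half_probability_at_threshold(self):
        for a in (0.3, 1.0, 4.46):
            item = ItemParameters("x", slope=a, thresholds=np.array([-0.7, 1.3]))
            assert cumulative_prob(item, 1, -0.7) == pytest.approx(0.5, abs=1e-12)
            assert cumulative_prob(item, 2, 1.3) == pytest.approx(0.5, abs=1e-12)

    def test_logistic_values(self):
        item = ItemParameters("x", slope=2.0, thresholds=np.array([0.0, 1.0]))
        # frozen: 1/(1+exp(-2*(2-1)))
        assert cumulative_prob(item, 2, 2.0) == pytest.approx(0.8807970779778823, abs=1e-9)
        assert cumulative_prob(item, 1, 50.0) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_boundary(self, toy_item):
        with pytest.raises(IndexError):
            cumulative_prob(toy_item, 0, 0.0)
        with pytest.raises(IndexError):
            cumulative_prob(toy_item, 5, 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(item=item_strategy, t1=st.floats(-4, 4), dt=st.floats(0.01, 2.0))
    def test_strictly_increasing_in_theta(self, item, t1, dt):
        assert cumulative_prob(item, 1, t1 + dt) > cumulative_prob(item, 1, t1)


class TestCategoryProb:
    def test_frozen_toy_values(self, toy_item):
        # direct evaluation of logistic differences at theta = 0
        got = category_prob(toy_item, 0.0)
        expect = [0.11920292, 0.38079708, 0.38079708, 0.10121671, 0.01798621]
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_extreme_theta_limits(self, toy_item):
        lo = category_prob(toy_item, -40.0)
        hi = category_prob(toy_item, 40.0)
        np.testing.assert_allclose(lo, [1, 0, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(hi, [0, 0, 0, 0, 1], atol=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(item=item_strategy, theta=st.floats(-5, 5))
    def test_sums_to_one_and_nonnegative(self, item, theta):
        p = category_prob(item, theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= -1e-15)


class TestIccCurve:
    def test_matches_pointwise_and_rows_sum(self, toy_item, grid):
        curves = icc_curve(toy_item, grid)
        np.testing.assert_allclose(curves.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(curves[5], category_prob(toy_item, grid.points[5]))

    def test_middle_categories_single_peaked(self, toy_item):
        dense = ThetaGrid.normal(1201, -8, 8)
        curves = icc_curve(toy_item, dense)
        for j in range(1, toy_item.n_categories - 1):
            signs = np.sign(np.diff(curves[:, j]))
            changes = np.count_nonzero(np.diff(signs[signs != 0]))
            assert changes == 1, f"category {j} not unimodal"


def fisher_information_oracle(item, theta, h=1e-4):
    """Finite-difference Fisher information: E[-(d2/dtheta2) log P_x(theta)]."""
    p0 = category_prob(item, theta)
    lp = lambda t: np.log(np.clip(category_prob(item, t), 1e-300, None))
    d2 = (lp(theta + h) - 2 * lp(theta) + lp(theta - h)) / h**2
    return float(-(p0 * d2).sum())


class TestInformation:
    def test_matches_finite_difference_oracle(self, toy_item):
        rng = np.random.default_rng(5)
        items = [toy_item] + [
            random_item(rng.uniform(0.5, 4), rng.uniform(-2.5, 2.5, rng.integers(1, 6)),
                        item_id=f"r{k}")
            for k in range(20)
        ]
        for item in items:
            for theta in rng.uniform(-3, 3, 2):
                assert item_information(item, theta) == pytest.approx(
                    fisher_information_oracle(item, theta), abs=1e-6, rel=1e-5)

    def test_nonnegative_everywhere(self, toy_item):
        assert np.all(item_information(toy_item, np.linspace(-6, 6, 200)) >= 0)

    def test_doubling_slope_raises_peak(self, toy_item):
        theta = np.linspace(-6, 6, 601)
        doubled = ItemParameters("d", slope=2 * toy_item.slope,
                                 thresholds=toy_item.thresholds)
        assert item_information(doubled, theta).max() > item_information(toy_item, theta).max()

    def test_test_information_additive(self, toy_bank5):
        theta = np.linspace(-3, 3, 13)
        a = ItemBank(items=toy_bank5.items[:2])
        b = ItemBank(items=toy_bank5.items[2:])
        total, se = tif(toy_bank5, theta)
        np.testing.assert_allclose(
            total, np.asarray(tif(a, theta)[0]) + tif(b, theta)[0],
            rtol=1e-12)
        np.testing.assert_allclose(se, 1 / np.sqrt(total))

    def test_single_item_bank_equals_item(self, toy_item):
        bank = ItemBank(items=[toy_item])
        assert tif(bank, 0.3)[0] == pytest.approx(item_information(toy_item, 0.3))

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            tif(ItemBank(items=[]), 0.0)

    def test_short_form_information_meets_reliability_target(self, sf2_bank):
        # the precision-oriented 10-item form reaches information 10
        # (reliability ~0.90) half an SD below the mean
        info, _ = tif(sf2_bank, -0.5)
        assert info >= 10.0


class TestReliability:
    def test_ten_maps_to_090(self):
        assert reliability_from_information(10.0) == pytest.approx(0.90)

    def test_simple_values_and_limit(self):
        assert reliability_from_information(4.0) == pytest.approx(0.75)
        assert reliability_from_information(1e12) == pytest.approx(1.0, abs=1e-9)
        assert reliability_from_information(0.5) == 0.0  # floored

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            reliability_from_information(0.0)


class TestExpectedTotalScore:
    def test_limits(self, toy_bank5):
        m, C = 5, 5
        assert expected_total_score(toy_bank5, -40.0) == pytest.approx(0.0, abs=1e-9)
        assert expected_total_score(toy_bank5, 40.0) == pytest.approx(m * (C - 1), abs=1e-9)

    def test_monotone_on_dense_grid(self, toy_bank5):
        tcc = expected_total_score(toy_bank5, np.linspace(-8, 8, 2001))
        assert np.all(np.diff(tcc) >= -1e-9)


class TestScoreRespondents:
    def test_all_missing_gets_prior(self, toy_bank5, grid):
        vals = np.full((2, 5), MISSING)
        vals[1] = 3
        resp = ResponseMatrix(values=vals, item_ids=toy_bank5.item_ids)
        scores = score_respondents(toy_bank5, resp, grid)
        assert scores.iloc[0]["theta"] == 0.0
        assert scores.iloc[0]["se"] == 1.0
        assert bool(scores.iloc[0]["all_missing"])
        assert not bool(scores.iloc[1]["all_missing"])

    def test_likelihood_ordering(self, toy_bank5, grid):
        vals = np.array([[4] * 5, [0] * 5])
        resp = ResponseMatrix(values=vals, item_ids=toy_bank5.item_ids)
        scores = score_respondents(toy_bank5, resp, grid)
        assert scores.iloc[0]["theta"] > scores.iloc[1]["theta"]

    def test_matches_dense_trapezoid_oracle(self, toy_bank5):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 5, size=(6, 5))
        resp = ResponseMatrix(values=vals, item_ids=toy_bank5.item_ids)
        grid = ThetaGrid.normal(49, -6, 6)
        got = score_respondents(toy_bank5, resp, grid)

        theta = np.linspace(-6, 6, 10001)
        from scipy.stats import norm
        prior = norm.pdf(theta)
        for r in range(6):
            like = np.ones_like(theta)
            for c, item in enumerate(toy_bank5):
                like *= category_prob(item, theta)[:, vals[r, c]]
            post = prior * like
            eap = np.trapezoid(theta * post, theta) / np.trapezoid(post, theta)
            assert got.iloc[r]["theta"] == pytest.approx(eap, abs=1e-4)


class TestThetaGrid:
    def test_weights_normalized_and_increasing(self, grid):
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(grid.points) > 0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ThetaGrid(points=np.array([0.0, 0.0]), weights=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            ThetaGrid(points=np.array([0.0, 1.0]), weights=np.array([0.4, 0.4]))
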