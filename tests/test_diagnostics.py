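"""Item fit, local dependence, model fit, reliability and multiplicity."""

import itertools

import numpy as np
import pytest

from gradedform.calibrate import fit_grm
from gradedform.data import ResponseMatrix
from gradedform.diagnostics import (bh_adjust, cronbach_alpha, item_fit_sx2,
                                    local_dependence, marginal_reliability,
                                    model_fit)
from gradedform.grm import ItemBank, ItemParameters
from gradedform.simulate import (inject_local_dependence, inject_misfit,
                                 sample_theta, simulate_responses)


def bh_oracle(pvalues, level):
    """Brute-force step-up: largest k with p_(k) <= k*level/m rejects 1..k."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * level / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    # adjusted values: min over j >= rank of m*p_(j)/j, monotone-enforced
    adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, reject


class TestBhAdjust:
    def test_trivial_cases(self):
        adj, rej = bh_adjust([1.0, 1.0, 1.0], 0.05)
        assert not rej.any()
        adj, rej = bh_adjust([0.03], 0.05)
        assert adj[0] == pytest.approx(0.03)
        adj, rej = bh_adjust([], 0.05)
        assert adj.size == 0 and rej.size == 0

    def test_known_vector_matches_oracle(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.5]
        adj, rej = bh_adjust(p, 0.05)
        o_adj, o_rej = bh_oracle(p, 0.05)
        np.testing.assert_allclose(adj, o_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, o_rej)

    def test_all_orderings_of_random_vectors_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            base = rng.uniform(0, 1, 5)
            for perm in itertools.permutations(range(5)):
                p = base[list(perm)]
                adj, rej = bh_adjust(p, 0.05)
                o_adj, o_rej = bh_oracle(p, 0.05)
                np.testing.assert_allclose(adj, o_adj, atol=1e-12)
                np.testing.assert_array_equal(rej, o_rej)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2], 0.05)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.tile(np.array([0, 1, 2, 3, 4, 2, 1, 3]), 3)[:, None]
        resp = ResponseMatrix(values=np.hstack([col, col]), n_categories=5)
        assert cronbach_alpha(resp) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        resp = ResponseMatrix(values=rng.integers(0, 5, (10_000, 2)), n_categories=5)
        assert abs(cronbach_alpha(resp)) < 0.05

    def test_bank_simulation_exceeds_090(self, fixture):
        theta = sample_theta(2000, seed=6)
        resp = simulate_responses(fixture.bank, theta, missing_rate=0.055, seed=7)
        assert cronbach_alpha(resp) >= 0.90

    def test_zero_variance_is_nan(self):
        resp = ResponseMatrix(values=np.ones((10, 3), dtype=int), n_categories=5)
        assert np.isnan(cronbach_alpha(resp))


class TestItemFit:
    def test_records_well_formed_and_mostly_unflagged(self, wellfit):
        _, resp, res = wellfit
        records = item_fit_sx2(res, resp)
        assert len(records) == 10
        for r in records:
            assert r.df >= 1
            assert 0.0 <= r.p <= 1.0
            assert 0.0 <= r.p_adjusted <= 1.0
            assert r.flagged == (r.p_adjusted < 0.01)
        assert sum(r.flagged for r in records) <= 1

    def test_flags_item_with_scrambled_categories(self, sf1_bank):
        # category scrambling breaks the ordered-threshold structure outright;
        # the summed-score fit statistic should catch it decisively
        tgt = sf1_bank.item_ids[1]
        hits = 0
        for seed in (31, 32, 33):
            theta = sample_theta(2000, seed=seed)
            inj = inject_misfit(sf1_bank, tgt, "category_scramble")
            resp = simulate_responses(sf1_bank, theta, seed=seed + 50, injections=[inj])
            res = fit_grm(resp)
            rec = {r.item_id: r for r in item_fit_sx2(res, resp)}[tgt]
            hits += rec.p < 0.01
        assert hits >= 2

    def test_second_dimension_attenuates_slope(self, sf1_bank):
        # an item loading 0.5 on the trait calibrates to roughly half its
        # nominal slope; the margins themselves stay close to a (weaker) GRM,
        # so slope attenuation is the reliable symptom of this mechanism
        tgt = sf1_bank.item_ids[4]
        theta = sample_theta(2000, seed=34)
        inj = inject_misfit(sf1_bank, tgt, "second_dimension")
        resp = simulate_responses(sf1_bank, theta, seed=35, injections=[inj])
        res = fit_grm(resp)
        assert res.bank[tgt].slope < 0.6 * sf1_bank[tgt].slope

    def test_too_few_respondents_rejected(self, wellfit):
        bank, resp, res = wellfit
        tiny = resp.subset_respondents(np.arange(resp.n_respondents) < 30)
        with pytest.raises(ValueError):
            item_fit_sx2(res, tiny)


class TestLocalDependence:
    def test_symmetric_nan_diagonal(self, wellfit):
        _, resp, res = wellfit
        mat = local_dependence(res, resp).values.to_numpy()
        assert np.all(np.isnan(np.diag(mat)))
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(mat[off], mat.T[off])
        assert np.all(np.isfinite(mat[off]))

    def test_null_mean_near_zero_and_no_flags(self, wellfit):
        _, resp, res = wellfit
        mat = local_dependence(res, resp)
        vals = mat.values.to_numpy()
        mean = np.nanmean(vals)
        assert -0.5 <= mean <= 0.5
        assert not mat.flagged_pairs()

    def test_injected_pair_flagged(self, sf1_bank):
        pair = (sf1_bank.item_ids[2], sf1_bank.item_ids[7])
        hits = 0
        for seed in (41, 42, 43):
            theta = sample_theta(2000, seed=seed)
            inj = inject_local_dependence(sf1_bank, pair, strength=0.7)
            resp = simulate_responses(sf1_bank, theta, seed=seed + 50, injections=[inj])
            res = fit_grm(resp)
            mat = local_dependence(res, resp)
            hits += mat.values.loc[pair[0], pair[1]] >= 10.0
        assert hits >= 3


class TestModelFit:
    def test_information_criteria_identities(self, wellfit):
        _, resp, res = wellfit
        stats = model_fit(res, resp, compute_m2=False)
        assert stats.aic - stats.minus2ll == pytest.approx(2 * stats.n_params, abs=1e-9)
        assert stats.bic - stats.minus2ll == pytest.approx(
            stats.n_params * np.log(stats.n), abs=1e-9)

    def test_m2_rmsea_small_under_well_specified_model(self, wellfit):
        _, resp, res = wellfit
        stats = model_fit(res, resp)
        assert np.isfinite(stats.m2)
        assert stats.m2_df == 760 - 50
        assert stats.rmsea <= 0.05

    def test_m2_skipped_when_margins_exceed_limit(self, fixture):
        # 25 items -> 4900 first/second-order margins, past the default cap
        bank = fixture.bank.subset(fixture.bank.item_ids[:25])
        theta = sample_theta(800, seed=51)
        resp = simulate_responses(bank, theta, seed=52)
        res = fit_grm(resp)
        with pytest.warns(UserWarning, match="M2 skipped"):
            stats = model_fit(res, resp)
        assert np.isnan(stats.m2) and np.isnan(stats.rmsea)


class TestMarginalReliability:
    def test_in_unit_interval_and_high_for_good_bank(self, wellfit):
        _, resp, res = wellfit
        mr = marginal_reliability(res, resp)
        assert 0.0 <= mr <= 1.0
        assert mr > 0.85

    def test_near_zero_for_flat_items(self, grid):
        bank = ItemBank(items=[
            ItemParameters(f"flat{k}", slope=1e-3,
                           thresholds=np.array([-1.0, 0.0, 1.0, 2.0]))
            for k in range(5)
        ])
        rng = np.random.default_rng(61)
        resp = ResponseMatrix(values=rng.integers(0, 5, (300, 5)),
                              item_ids=bank.item_ids)
        from gradedform.calibrate import CalibrationResult, CalibrationConfig
        res = CalibrationResult(bank=bank, loglik=0.0, n_effective=300, converged=True,
                                n_cycles=1, grid=grid, config=CalibrationConfig())
        assert marginal_reliability(res, resp) < 0.05

    def test_increases_with_more_items(self, wellfit, fixture):
        bank, resp, res = wellfit
        sub = resp.subset_items(resp.item_ids[:4])
        res_sub = fit_grm(sub)
        assert marginal_reliability(res_sub, sub) < marginal_reliability(res, resp)
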