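"""Flag-based exclusion, discrimination ranking, content coverage and
deterministic short-form assembly."""

import numpy as np
import pytest

from gradedform.shortform import (ContentMap, ShortForm, build_form, compare_forms,
                                  dsm_coverage, exclude_flagged,
                                  rank_by_discrimination)
from gradedform.simulate import sample_theta, simulate_responses


class TestExcludeFlagged:
    def test_no_flags_everything_eligible(self, fixture):
        eligible, ledger = exclude_flagged(fixture.bank)
        assert eligible == fixture.bank.item_ids
        assert set(ledger.records.status) == {"eligible"}

    def test_ledger_partitions_bank(self, fixture):
        eligible, ledger = exclude_flagged(
            fixture.bank, misfit=fixture.misfit_items,
            ld_sets=[set(s) for s in fixture.ld_sets], dif=fixture.dif_items)
        recs = ledger.records
        assert len(recs) == 51
        assert set(recs.loc[recs.status == "eligible", "item_id"]) == set(eligible)
        # every item appears exactly once
        assert recs.item_id.is_unique

    def test_matches_set_arithmetic_oracle(self, fixture):
        """Eligible set equals the brute-force union computation on the
        published flag lists, with the best-slope unflagged item kept per
        locally dependent set."""
        eligible, _ = exclude_flagged(
            fixture.bank, misfit=fixture.misfit_items,
            ld_sets=[set(s) for s in fixture.ld_sets], dif=fixture.dif_items)

        excluded = set(fixture.misfit_items) | set(fixture.dif_items)
        for s in fixture.ld_sets:
            keepable = [i for i in s if i not in excluded]
            keeper = max(keepable, key=lambda i: (fixture.bank[i].slope, i)) if keepable else None
            excluded |= {i for i in s if i != keeper}
        oracle = [i for i in fixture.bank.item_ids if i not in excluded]
        assert eligible == oracle

    def test_crying_items_carry_both_reasons(self, fixture):
        # the crying pair is locally dependent AND shows gender DIF; neither
        # survives, and the ledger records both grounds
        _, ledger = exclude_flagged(
            fixture.bank, misfit=fixture.misfit_items,
            ld_sets=[set(s) for s in fixture.ld_sets], dif=fixture.dif_items)
        for item in ("I had crying spells", "I felt like crying"):
            reasons = ledger.reasons_for(item)
            assert "dif" in reasons
            assert "local_dependence" in reasons

    def test_override_restores_flagged_item(self, fixture):
        eligible, ledger = exclude_flagged(
            fixture.bank, misfit=fixture.misfit_items,
            overrides={"I felt sad": "integral to the construct"})
        assert "I felt sad" in eligible
        row = ledger.records.set_index("item_id").loc["I felt sad"]
        assert row.status == "retained_by_override"

    def test_override_of_unflagged_item_warns(self, fixture):
        with pytest.warns(UserWarning, match="no-op"):
            exclude_flagged(fixture.bank, overrides={"I felt hopeless": "x"})

    def test_unknown_flag_rejected(self, fixture):
        with pytest.raises(KeyError):
            exclude_flagged(fixture.bank, misfit={"not an item"})


class TestRankByDiscrimination:
    def test_fixture_rank_one_is_hopeless(self, fixture):
        assert rank_by_discrimination(fixture.bank)[0] == "I felt hopeless"

    def test_ties_broken_by_id_and_input_order_irrelevant(self, fixture):
        from conftest import make_bank
        bank = make_bank([2.0, 2.0, 2.0], [[-1, 0, 1]] * 3, prefix="z")
        assert rank_by_discrimination(bank) == ["z1", "z2", "z3"]
        rev = fixture.bank.subset(list(reversed(fixture.bank.item_ids)))
        assert rank_by_discrimination(rev) == rank_by_discrimination(fixture.bank)


class TestDsmCoverage:
    def test_published_forms_cover_nine_and_five(self, fixture):
        sf1 = ShortForm(name="sf1", item_ids=list(fixture.sf1_items))
        sf2 = ShortForm(name="sf2", item_ids=list(fixture.sf2_items))
        assert dsm_coverage(sf1, fixture.dsm_map)[0] == 9
        assert dsm_coverage(sf2, fixture.dsm_map)[0] == 5

    def test_empty_form_and_empty_map(self, fixture):
        assert dsm_coverage(ShortForm(name="e", item_ids=[]), fixture.dsm_map)[0] == 0
        with pytest.raises(ValueError):
            dsm_coverage(ShortForm(name="e", item_ids=[]),
                         ContentMap(criteria=[], mapping={}))

    def test_monotone_under_item_addition(self, fixture):
        rng = np.random.default_rng(1)
        ids = list(fixture.bank.item_ids)
        for _ in range(10):
            base = list(rng.choice(ids, size=6, replace=False))
            extra = rng.choice([i for i in ids if i not in base])
            c0 = dsm_coverage(ShortForm(name="a", item_ids=base), fixture.dsm_map)[0]
            c1 = dsm_coverage(ShortForm(name="b", item_ids=base + [extra]),
                              fixture.dsm_map)[0]
            assert c1 >= c0


class TestBuildForm:
    def _eligible(self, fixture):
        eligible, _ = exclude_flagged(
            fixture.bank, misfit=fixture.misfit_items,
            ld_sets=[set(s) for s in fixture.ld_sets], dif=fixture.dif_items)
        return eligible

    def test_full_size_returns_everything(self, fixture):
        eligible = self._eligible(fixture)
        form = build_form(eligible, fixture.dsm_map, fixture.bank,
                          strategy="content_first", size=len(eligible))
        assert sorted(form.item_ids) == sorted(eligible)

    def test_insomnia_never_covered(self, fixture):
        # the bank contains no sleep items, so that criterion stays uncovered
        eligible = self._eligible(fixture)
        for strategy in ("content_first", "precision_first"):
            form = build_form(eligible, fixture.dsm_map, fixture.bank,
                              strategy=strategy, size=10)
            assert form.coverage_detail["c4"] == []

    def test_content_first_covers_at_least_precision_first(self, fixture):
        rng = np.random.default_rng(2)
        eligible = self._eligible(fixture)
        for rep in range(20):
            crits = [(f"k{j}", f"crit {j}") for j in range(8)]
            mapping = {f"k{j}": frozenset(rng.choice(fixture.bank.item_ids,
                                                     size=rng.integers(1, 5),
                                                     replace=False))
                       for j in range(8)}
            cmap = ContentMap(criteria=crits, mapping=mapping)
            cf = build_form(eligible, cmap, fixture.bank, "content_first", 10)
            pf = build_form(eligible, cmap, fixture.bank, "precision_first", 10)
            assert pf.coverage_count <= cf.coverage_count

    def test_deterministic(self, fixture):
        eligible = self._eligible(fixture)
        a = build_form(eligible, fixture.dsm_map, fixture.bank, "precision_first", 10)
        b = build_form(eligible, fixture.dsm_map, fixture.bank, "precision_first", 10)
        assert a.item_ids == b.item_ids

    def test_oversized_request_warns_and_shrinks(self, fixture):
        eligible = self._eligible(fixture)[:4]
        with pytest.warns(UserWarning):
            form = build_form(eligible, fixture.dsm_map, fixture.bank,
                              "content_first", size=10)
        assert len(form.item_ids) == 4


class TestCompareForms:
    def test_self_comparison_identical_rows(self, fixture, sf1_bank):
        theta = sample_theta(700, seed=3)
        resp = simulate_responses(sf1_bank, theta, seed=4)
        f1 = ShortForm(name="a", item_ids=list(fixture.sf1_items))
        f2 = ShortForm(name="b", item_ids=list(fixture.sf1_items))
        table = compare_forms([f1, f2], resp)
        assert table.loc[1, "delta_minus2ll"] == pytest.approx(0.0, abs=1e-6)
        for col in ("alpha", "minus2ll", "aic", "bic", "rmsea"):
            assert table.loc[0, col] == pytest.approx(table.loc[1, col], abs=1e-6)

    def test_non_nested_delta_is_nan(self, fixture, sf1_bank):
        theta = sample_theta(700, seed=5)
        resp = simulate_responses(sf1_bank, theta, seed=6)
        f1 = ShortForm(name="a", item_ids=list(fixture.sf1_items)[:6])
        f2 = ShortForm(name="b", item_ids=list(fixture.sf1_items)[4:])
        table = compare_forms([f1, f2], resp)
        assert np.isnan(table.loc[1, "delta_minus2ll"])
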