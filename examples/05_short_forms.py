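"""Short-form construction: exclusions, content coverage, precision.

Applies the published flag sets (misfit, local dependence, gender DIF) to
the 51-item bank, builds a content-first and a precision-first 10-item
form, and compares their DSM-5 coverage and test information with the two
published forms.
"""

from gradedform.grm import test_information
from gradedform.shortform import (ShortForm, build_form, dsm_coverage,
                                  exclude_flagged, rank_by_discrimination)
from gradedform.simulate import promis_bank_fixture

fx = promis_bank_fixture()

eligible, ledger = exclude_flagged(
    fx.bank, misfit=fx.misfit_items,
    ld_sets=[set(s) for s in fx.ld_sets], dif=fx.dif_items)
counts = ledger.records.status.value_counts()
print(f"eligible after exclusions: {len(eligible)} of 51 "
      f"({counts.get('excluded', 0)} excluded)")
print(f"most discriminating item: {rank_by_discrimination(fx.bank)[0]!r}")
print()

cf = build_form(eligible, fx.dsm_map, fx.bank, strategy="content_first", size=10)
pf = build_form(eligible, fx.dsm_map, fx.bank, strategy="precision_first", size=10)
sf1 = ShortForm(name="published content form", item_ids=list(fx.sf1_items))
sf2 = ShortForm(name="published precision form", item_ids=list(fx.sf2_items))

for form in (cf, pf, sf1, sf2):
    cov, _ = dsm_coverage(form, fx.dsm_map)
    info, _ = test_information(fx.bank.subset(form.item_ids), -0.5)
    print(f"{form.name:28s} coverage {cov:2d}/11   information at theta=-0.5: {info:5.1f}")
print()
print("-> prioritizing content covers more diagnostic criteria; prioritizing")
print("   precision buys information (information 10 ~ reliability 0.90).")
print("   The published forms land at 9/11 and 5/11 coverage respectively.")
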