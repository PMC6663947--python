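"""Content-constrained short-form construction.

Combines diagnostic flags (misfit, local dependence, DIF), discrimination
ranking and a content-criterion map (e.g. the DSM-5 symptom checklist) to
build and compare fixed short forms from a calibrated bank.  The two
strategies are deterministic codifications of the usual expert trade-off:
``content_first`` walks the criterion list picking the most discriminating
eligible item per uncovered criterion, ``precision_first`` takes the
top-slope items with a small near-tie nudge toward uncovered content.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import ItemBank, ThetaGrid, test_information

log = logging.getLogger(__name__)

__all__ = [
    "ContentMap",
    "ShortForm",
    "ExclusionLedger",
    "exclude_flagged",
    "rank_by_discrimination",
    "dsm_coverage",
    "build_form",
    "compare_forms",
]


@dataclass(frozen=True)
class ContentMap:
    """Ordered content criteria and the items that satisfy each.

    ``criteria`` is an ordered list of (criterion_id, label); ``mapping``
    maps criterion_id -> frozenset of item ids.  A criterion may map to no
    items (content the bank simply cannot cover).
    """

    criteria: list
    mapping: dict

    def __post_init__(self):
        ids = [c for c, _ in self.criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")
        unknown = set(self.mapping) - set(ids)
        if unknown:
            raise ValueError(f"mapping refers to unknown criteria: {sorted(unknown)}")

    @property
    def criterion_ids(self) -> list:
        return [c for c, _ in self.criteria]

    def items_for(self, criterion_id) -> frozenset:
        return self.mapping.get(criterion_id, frozenset())

    def validate_against(self, bank: ItemBank) -> None:
        known = set(bank.item_ids)
        for cid, items in self.mapping.items():
            stray = set(items) - known
            if stray:
                raise ValueError(f"criterion {cid!r} maps unknown items: {sorted(stray)}")

    def restrict_to(self, bank: ItemBank) -> "ContentMap":
        """Drop mapped items absent from ``bank`` (criteria stay, possibly empty)."""
        known = set(bank.item_ids)
        return ContentMap(criteria=list(self.criteria),
                          mapping={cid: frozenset(items & known)
                                   for cid, items in self.mapping.items()})

    @classmethod
    def from_json_records(cls, records) -> "ContentMap":
        return cls(criteria=[(r["criterion_id"], r.get("label", r["criterion_id"]))
                             for r in records],
                   mapping={r["criterion_id"]: frozenset(r["item_ids"]) for r in records})

    def to_json_records(self) -> list:
        return [{"criterion_id": cid, "label": lbl,
                 "item_ids": sorted(self.mapping.get(cid, frozenset()))}
                for cid, lbl in self.criteria]


@dataclass
class ShortForm:
    """A fixed item subset with its content coverage and precision summaries."""

    name: str
    item_ids: list
    coverage_count: int = 0
    coverage_detail: dict = field(default_factory=dict)
    tif_curve: np.ndarray | None = None
    fit: "object" = None            # ModelFitStats, filled by compare_forms
    rationale: dict = field(default_factory=dict)   # item_id -> note

    def __post_init__(self):
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("short form contains duplicate items")


@dataclass
class ExclusionLedger:
    """Accounting of every bank item: eligible, excluded (with reasons), or
    retained by override."""

    records: pd.DataFrame   # item_id, status, reasons

    def reasons_for(self, item_id) -> list:
        row = self.records.loc[self.records.item_id == item_id]
        return list(row.iloc[0].reasons) if len(row) else []


def exclude_flagged(bank: ItemBank, misfit: set | None = None,
                    ld_sets: list | None = None, dif: set | None = None,
                    overrides: dict | None = None) -> tuple[list, ExclusionLedger]:
    """Remove flagged items from short-form consideration.

    From each locally dependent set at most one designated item is retained
    — the one with the best discrimination among set members that carry no
    other flag.  ``overrides`` (item_id -> reason) force-retains items that
    would otherwise be excluded, mirroring expert-consensus decisions; an
    override of an unflagged item is a warned no-op.

    Returns the eligible item ids (in bank order) and a ledger accounting
    for every bank item exactly once.
    """
    misfit = set(misfit or ())
    dif = set(dif or ())
    ld_sets = [set(s) for s in (ld_sets or [])]
    overrides = dict(overrides or {})
    known = set(bank.item_ids)
    for name, s in [("misfit", misfit), ("dif", dif)] + [("ld", s) for s in ld_sets]:
        stray = s - known
        if stray:
            raise KeyError(f"{name} flags reference unknown items: {sorted(stray)}")

    reasons: dict[str, list] = {i: [] for i in bank.item_ids}
    for i in misfit:
        reasons[i].append("misfit")
    for i in dif:
        reasons[i].append("dif")
    for s in ld_sets:
        # designated keeper: best slope among members free of other flags
        candidates = [i for i in s if i not in misfit and i not in dif]
        keeper = max(candidates, key=lambda i: (bank[i].slope, i)) if candidates else None
        for i in s:
            if i != keeper:
                reasons[i].append("local_dependence")
            elif keeper is not None:
                log.info("LD set %s: retaining %r (best discrimination)", sorted(s), keeper)

    status, eligible = {}, []
    for i in bank.item_ids:
        if not reasons[i]:
            status[i] = "eligible"
            eligible.append(i)
        elif i in overrides:
            status[i] = "retained_by_override"
            reasons[i].append(f"override: {overrides[i]}")
            eligible.append(i)
        else:
            status[i] = "excluded"
    for i, why in overrides.items():
        if i not in known:
            raise KeyError(f"override of unknown item {i!r}")
        if status[i] == "eligible":
            warnings.warn(f"override of unflagged item {i!r} is a no-op", stacklevel=2)

    ledger = ExclusionLedger(records=pd.DataFrame(
        {"item_id": bank.item_ids,
         "status": [status[i] for i in bank.item_ids],
         "reasons": [tuple(reasons[i]) for i in bank.item_ids]}))
    return eligible, ledger


def rank_by_discrimination(bank: ItemBank) -> list:
    """Item ids in descending slope order; ties broken by ascending id."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    return [i for i, _ in sorted(((it.item_id, it.slope) for it in bank),
                                 key=lambda t: (-t[1], t[0]))]


def dsm_coverage(form: ShortForm, content_map: ContentMap) -> tuple[int, dict]:
    """Number of content criteria satisfied by at least one form item.

    Returns (count, per-criterion detail mapping criterion_id to the form
    items covering it).
    """
    if not content_map.criteria:
        raise ValueError("empty content map")
    items = set(form.item_ids)
    detail = {cid: sorted(items & content_map.items_for(cid))
              for cid in content_map.criterion_ids}
    return sum(1 for v in detail.values() if v), detail


def build_form(eligible: list, content_map: ContentMap, bank: ItemBank,
               strategy: str = "content_first", size: int = 10,
               name: str | None = None, near_tie: float = 0.05) -> ShortForm:
    """Deterministically assemble a short form from the eligible items.

    content_first: for each uncovered criterion in map order, take the
    highest-slope eligible item mapped to it; fill remaining slots by
    slope rank.  precision_first: take top-slope items, breaking slope
    near-ties (within ``near_tie``) toward items covering an uncovered
    criterion.
    """
    if strategy not in ("content_first", "precision_first"):
        raise ValueError(f"unknown strategy {strategy!r}")
    eligible = list(eligible)
    if size > len(eligible):
        warnings.warn(f"only {len(eligible)} eligible items for requested size {size}",
                      stacklevel=2)
        size = len(eligible)
    by_rank = [i for i in rank_by_discrimination(bank.subset(eligible))]
    chosen: list = []
    rationale: dict = {}
    covered: set = set()

    def cover(item_id):
        newly = {cid for cid in content_map.criterion_ids
                 if item_id in content_map.items_for(cid)}
        covered.update(newly)
        return newly

    if strategy == "content_first":
        for cid, label in content_map.criteria:
            if len(chosen) >= size or cid in covered:
                continue
            pool = [i for i in by_rank if i not in chosen
                    and i in content_map.items_for(cid)]
            if pool:
                chosen.append(pool[0])
                cover(pool[0])
                rationale[pool[0]] = f"covers criterion {cid} ({label})"
        for i in by_rank:
            if len(chosen) >= size:
                break
            if i not in chosen:
                chosen.append(i)
                cover(i)
                rationale.setdefault(i, "filled by discrimination rank")
    else:
        remaining = list(by_rank)
        while len(chosen) < size and remaining:
            head = remaining[0]
            band = [i for i in remaining if bank[i].slope >= bank[head].slope - near_tie]
            pick = next((i for i in band
                         if any(cid not in covered and i in content_map.items_for(cid)
                                for cid in content_map.criterion_ids)), head)
            chosen.append(pick)
            newly = cover(pick)
            rationale[pick] = ("near-tie broken toward content "
                               f"({', '.join(sorted(newly))})" if pick != head
                               else "top discrimination")
            remaining.remove(pick)

    form = ShortForm(name=name or strategy, item_ids=chosen, rationale=rationale)
    form.coverage_count, form.coverage_detail = dsm_coverage(form, content_map)
    return form


def compare_forms(forms: list, responses, grid: ThetaGrid | None = None,
                  config=None) -> pd.DataFrame:
    """Model-fit comparison table across forms (each refit on its own columns).

    Per form: Cronbach's alpha, -2LL, AIC, BIC, RMSEA, M2 (+df, p) and the
    test information curve stored on the form.  The delta(-2LL) column is
    filled between successive rows only when the later form's items nest
    inside the earlier's (otherwise NA).
    """
    from .calibrate import CalibrationConfig, fit_grm
    from .diagnostics import cronbach_alpha, model_fit

    config = config or CalibrationConfig()
    grid = grid or config.make_grid()
    rows = []
    prev_items: set | None = None
    prev_m2ll = None
    for form in forms:
        sub = responses.subset_items(form.item_ids)
        res = fit_grm(sub, config)
        stats = model_fit(res, sub)
        form.fit = stats
        info, _ = test_information(res.bank, grid.points)
        form.tif_curve = np.asarray(info)
        items = set(form.item_ids)
        if prev_items is not None and (items <= prev_items or prev_items <= items):
            delta = prev_m2ll - stats.minus2ll
        else:
            delta = np.nan
        rows.append({
            "form": form.name, "n_items": len(form.item_ids),
            "alpha": cronbach_alpha(sub), "minus2ll": stats.minus2ll,
            "delta_minus2ll": delta if prev_items is not None else np.nan,
            "aic": stats.aic, "bic": stats.bic, "rmsea": stats.rmsea,
            "m2": stats.m2, "m2_df": stats.m2_df, "m2_p": stats.m2_p,
        })
        prev_items, prev_m2ll = items, stats.minus2ll
    return pd.DataFrame(rows)
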