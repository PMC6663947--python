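"""Synthetic response generation and the packaged published-calibration fixture.

Generates polytomous response matrices with exactly the structure the
analysis pipeline assumes — graded-response-model responses under a
standard-normal latent trait — plus controlled violations of that
structure: uniform/non-uniform DIF, locally dependent item pairs
(testlet-style shared nuisance factor), misfitting items, and MCAR
missingness.  The default emulation profile mirrors the published study's
sample: n = 825 respondents, a 49/51 two-group split, and ~5.5 %
item-level missingness.

The packaged fixture carries the published 51-item depression bank
calibration (slopes, thresholds, item-fit and local-dependence flags,
gender-DIF flags), the DSM-5 content map, and the two 10-item short
forms, transcribed once from the source tables and frozen under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .data import MISSING, ResponseMatrix
from .grm import ItemBank, ItemParameters, category_prob

__all__ = [
    "Fixture",
    "SimulationConfig",
    "LdInjection",
    "MisfitInjection",
    "sample_theta",
    "simulate_responses",
    "inject_dif",
    "inject_local_dependence",
    "inject_misfit",
    "promis_bank_fixture",
    "simulate_study",
]


def _num(s: str) -> float:
    """Parse a printed number, normalizing the Unicode minus sign."""
    return float(str(s).replace("−", "-"))


@dataclass(frozen=True)
class Fixture:
    """Published 51-item calibration plus flag sets, content map and forms."""

    bank: ItemBank
    misfit_items: frozenset
    ld_sets: tuple            # connected components of the LD partner graph
    ld_partners: dict         # item_id -> list of partner item_ids, as printed
    dif_items: frozenset
    ld_retained: frozenset    # best item kept from each LD set
    misfit_overrides: frozenset
    dsm_map: "object"         # shortform.ContentMap
    sf1_items: tuple
    sf2_items: tuple
    numbers: dict             # item_id -> printed row number


def promis_bank_fixture() -> Fixture:
    """Load the packaged published calibration of the 51 depression items."""
    from .shortform import ContentMap

    raw = json.loads(
        resources.files("gradedform.assets").joinpath("promis_depression.json").read_text()
    )
    items, metadata, numbers = [], {}, {}
    by_number = {}
    for rec in raw["items"]:
        stem = rec["stem"]
        items.append(ItemParameters(
            item_id=stem,
            slope=_num(rec["a"]),
            thresholds=np.array([_num(b) for b in rec["b"]]),
        ))
        metadata[stem] = {
            "stem": stem,
            "scale": rec["scale"],
            "sx2": _num(rec["sx2"]),
            "sx2_df": rec["sx2_df"],
            "misfit": rec["misfit"],
            "ld_partners": rec["ld_partners"],
            "dif_chi2": _num(rec["dif_chi2"]) if rec["dif_chi2"] else None,
            "dif_df": rec["dif_df"],
        }
        numbers[stem] = rec["number"]
        by_number[rec["number"]] = stem

    bank = ItemBank(items=items, metadata=metadata)

    # connected components of the printed partner lists
    ld_ids = [s for s in bank.item_ids if metadata[s]["ld_partners"]]
    comp: dict[str, set] = {}
    for s in ld_ids:
        group = {s} | {by_number[p] for p in metadata[s]["ld_partners"]}
        merged = set(group)
        for g in list(group):
            if g in comp:
                merged |= comp[g]
        for g in merged:
            comp[g] = merged
    seen, ld_sets = set(), []
    for s in ld_ids:
        if s not in seen:
            ld_sets.append(frozenset(comp[s]))
            seen |= comp[s]

    dsm = ContentMap(
        criteria=[(c["id"], c["label"]) for c in raw["dsm_map"]],
        mapping={c["id"]: frozenset(by_number[n] for n in c["items"]) for c in raw["dsm_map"]},
    )
    return Fixture(
        bank=bank,
        misfit_items=frozenset(s for s in bank.item_ids if metadata[s]["misfit"]),
        ld_sets=tuple(ld_sets),
        ld_partners={s: [by_number[p] for p in metadata[s]["ld_partners"]] for s in ld_ids},
        dif_items=frozenset(by_number[n] for n in raw["dif_items"]),
        ld_retained=frozenset(by_number[n] for n in raw["ld_retained"]),
        misfit_overrides=frozenset(by_number[n] for n in raw["misfit_overrides"]),
        dsm_map=dsm,
        sf1_items=tuple(by_number[n] for n in raw["short_form_1"]),
        sf2_items=tuple(by_number[n] for n in raw["short_form_2"]),
        numbers=numbers,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sample_theta(n: int, mean: float = 0.0, sd: float = 1.0, seed: int | None = None) -> np.ndarray:
    """Draw n latent-trait values from N(mean, sd); reproducible by seed."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)


@dataclass(frozen=True)
class LdInjection:
    """Shared-nuisance-factor (testlet) local dependence for one item pair.

    The pair's responses are generated from theta' = (theta + strength*u) /
    sqrt(1 + strength^2) with u ~ N(0,1) shared within respondent, so the
    marginal trait variance stays 1 while the pair gains covariance beyond
    the trait.  strength = 0 recovers independence.
    """

    item_pair: tuple
    strength: float

    def __post_init__(self):
        if not 0 <= self.strength < 1:
            raise ValueError("strength must be in [0, 1)")
        if self.item_pair[0] == self.item_pair[1]:
            raise ValueError("pair must be two distinct items")


@dataclass(frozen=True)
class MisfitInjection:
    """Deliberate model violation for one item.

    ``second_dimension``: the item loads 0.5 on theta and 0.866 on an
    independent nuisance trait (unit total variance), so the unidimensional
    model misfits it.  ``category_scramble``: the generating probabilities
    of the two middle categories (1 and 2) are swapped, breaking the
    monotone ordering of category severities.
    """

    item_id: str
    mechanism: str = "second_dimension"

    def __post_init__(self):
        if self.mechanism not in ("second_dimension", "category_scramble"):
            raise ValueError(f"unknown misfit mechanism {self.mechanism!r}")


def inject_local_dependence(bank: ItemBank, item_pair, strength: float,
                            seed: int | None = None) -> LdInjection:
    """Build a generator hook making one item pair locally dependent."""
    for i in item_pair:
        bank[i]  # raises KeyError if absent
    return LdInjection(item_pair=tuple(item_pair), strength=float(strength))


def inject_misfit(bank: ItemBank, item_id: str, mechanism: str = "second_dimension") -> MisfitInjection:
    """Build a generator hook making one item misfit the model."""
    bank[item_id]
    return MisfitInjection(item_id=item_id, mechanism=mechanism)


def inject_dif(bank: ItemBank, item_id: str, b_shift: float = 0.0, a_ratio: float = 1.0) -> ItemBank:
    """Focal-group bank with one item's thresholds shifted and/or slope scaled.

    b_shift != 0 with a_ratio = 1 produces uniform DIF (negative shift makes
    the item easier to endorse for the focal group at every level); a_ratio
    != 1 produces non-uniform DIF.
    """
    if a_ratio <= 0:
        raise ValueError("a_ratio must be positive")
    items = []
    for it in bank:
        if it.item_id == item_id:
            items.append(ItemParameters(
                item_id=it.item_id,
                slope=it.slope * a_ratio,
                thresholds=it.thresholds + b_shift,
            ))
        else:
            items.append(it)
    if item_id not in bank.item_ids:
        raise KeyError(item_id)
    return ItemBank(items=items, metadata=dict(bank.metadata))


def _draw_categories(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Invert the category CDF: probs is n x C, u is n uniforms."""
    cdf = np.cumsum(probs, axis=1)
    return (u[:, None] > cdf[:, :-1]).sum(axis=1)


def simulate_responses(bank: ItemBank, theta: np.ndarray, missing_rate: float = 0.0,
                       seed: int | None = None, injections: list | None = None) -> ResponseMatrix:
    """Draw GRM responses for every respondent/item, with optional violations.

    Each item's column uses an independent uniform stream keyed by column
    order, so injections alter only the targeted items' columns under a
    shared seed (injection locality).  Missingness is MCAR at
    ``missing_rate``.
    """
    if not 0 <= missing_rate <= 0.5:
        raise ValueError("missing_rate must be in [0, 0.5]")
    theta = np.asarray(theta, dtype=float)
    n, m = theta.size, len(bank)
    C = bank.common_categories()
    rng = np.random.default_rng(seed)
    u = rng.random((n, m))                       # per-cell category draws
    u_miss = rng.random((n, m))                  # per-cell missingness draws
    shared_nuisance = rng.normal(size=n)         # one stream for LD hooks
    extra_dim = rng.normal(size=n)               # one stream for misfit hooks

    ld_theta: dict[str, np.ndarray] = {}
    misfit_by_item: dict[str, MisfitInjection] = {}
    for inj in injections or []:
        if isinstance(inj, LdInjection):
            t = (theta + inj.strength * shared_nuisance) / np.sqrt(1 + inj.strength**2)
            for item_id in inj.item_pair:
                ld_theta[item_id] = t
        elif isinstance(inj, MisfitInjection):
            misfit_by_item[inj.item_id] = inj
        else:
            raise TypeError(f"unknown injection {inj!r}")

    values = np.empty((n, m), dtype=np.int64)
    for col, item in enumerate(bank):
        t = ld_theta.get(item.item_id, theta)
        mis = misfit_by_item.get(item.item_id)
        if mis is not None and mis.mechanism == "second_dimension":
            t = 0.5 * theta + 0.866 * extra_dim
        probs = category_prob(item, t)
        if mis is not None and mis.mechanism == "category_scramble":
            probs = probs.copy()
            probs[:, [1, 2]] = probs[:, [2, 1]]
        values[:, col] = _draw_categories(probs, u[:, col])

    if missing_rate > 0:
        values[u_miss < missing_rate] = MISSING
    return ResponseMatrix(values=values, item_ids=list(bank.item_ids), n_categories=C)


@dataclass
class SimulationConfig:
    """Study-emulation settings: sample size, trait distribution, missingness,
    group split and structural violations.

    Defaults mirror the published study's descriptives: 825 respondents,
    ~5.5 % missingness, and a 49/51 reference/focal split.
    """

    bank: ItemBank = None
    n: int = 825
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    missing_rate: float = 0.055
    group_fraction: float = 0.51          # focal share
    seed: int = 0
    focal_theta_shift: float = 0.0        # focal-group latent mean offset
    dif: list = field(default_factory=list)         # (item_id, b_shift, a_ratio)
    injections: list = field(default_factory=list)  # Ld/Misfit injections

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")


def simulate_study(config: SimulationConfig) -> tuple[ResponseMatrix, np.ndarray, np.ndarray]:
    """Simulate a two-group study: responses, group labels, true thetas.

    Group labels are an object array of "reference"/"focal".  DIF specs in
    ``config.dif`` apply :func:`inject_dif` to the focal group's generating
    bank.  The same uniform streams drive both groups' draws, so a
    zero-magnitude DIF spec reproduces the no-DIF data exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    theta = sample_theta(n, config.theta_mean, config.theta_sd,
                         seed=int(rng.integers(2**31)))
    focal = rng.random(n) < config.group_fraction
    theta = theta + np.where(focal, config.focal_theta_shift, 0.0)
    groups = np.where(focal, "focal", "reference").astype(object)

    focal_bank = config.bank
    for item_id, b_shift, a_ratio in config.dif:
        focal_bank = inject_dif(focal_bank, item_id, b_shift=b_shift, a_ratio=a_ratio)

    seed_resp = int(rng.integers(2**31))
    ref = simulate_responses(config.bank, theta, config.missing_rate,
                             seed=seed_resp, injections=config.injections)
    if focal_bank is config.bank:
        resp = ref
    else:
        foc = simulate_responses(focal_bank, theta, config.missing_rate,
                                 seed=seed_resp, injections=config.injections)
        values = np.where(focal[:, None], foc.values, ref.values)
        resp = ResponseMatrix(values=values, item_ids=list(config.bank.item_ids),
                              n_categories=config.bank.common_categories())
    return resp, groups, theta
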