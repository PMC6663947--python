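"""Pure functions of Samejima's graded response model (GRM).

The GRM describes the probability of an ordered polytomous item response
as a difference of adjacent cumulative logistic "trace lines",

    P*(x >= j | theta) = 1 / (1 + exp(-a (theta - b_j))),       j = 1..C-1
    P(x = j | theta)   = P*(x >= j) - P*(x >= j+1),

with the conventions P*(x >= 0) = 1 and P*(x >= C) = 0.  ``a`` is the item
slope (discrimination) and ``b_1 < ... < b_{C-1}`` the category thresholds
(severities) on the latent-trait metric, which is standardized to mean 0,
SD 1.  Everything in this module is a deterministic function of item
parameters and theta; estimation lives in :mod:`gradedform.calibrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "PROB_CLIP",
    "ItemParameters",
    "ItemBank",
    "ThetaGrid",
    "cumulative_prob",
    "category_prob",
    "icc_curve",
    "item_information",
    "test_information",
    "reliability_from_information",
    "expected_total_score",
    "score_respondents",
]

# Probabilities are clipped to this interior before logs/divisions.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class ItemParameters:
    """Slope and ordered thresholds of a single GRM item.

    Parameters
    ----------
    item_id
        Unique identifier (typically the item stem).
    slope
        Discrimination parameter ``a``; must be positive.
    thresholds
        Severity parameters ``b_1 .. b_{C-1}``, strictly increasing, in
        units of latent-trait standard deviations.
    """

    item_id: str
    slope: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", thr)
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"{self.item_id!r}: slope must be positive, got {self.slope}")
        if thr.ndim != 1 or thr.size < 1:
            raise ValueError(f"{self.item_id!r}: need at least one threshold")
        if not np.all(np.isfinite(thr)):
            raise ValueError(f"{self.item_id!r}: thresholds must be finite")
        if np.any(np.diff(thr) <= 0):
            raise ValueError(f"{self.item_id!r}: thresholds must be strictly increasing: {thr}")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


@dataclass
class ItemBank:
    """Ordered collection of jointly calibrated items plus per-item metadata.

    ``metadata`` maps item_id to a free-form dict (stem, subdomain,
    response-scale labels).  All items in a bank used for calibration must
    share one category count C; mixed banks are rejected there.
    """

    items: list[ItemParameters]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def slopes(self) -> np.ndarray:
        return np.array([it.slope for it in self.items])

    def common_categories(self) -> int:
        cs = {it.n_categories for it in self.items}
        if len(cs) != 1:
            raise ValueError(f"bank mixes category counts: {sorted(cs)}")
        return cs.pop()

    def subset(self, item_ids) -> "ItemBank":
        keep = list(item_ids)
        missing = set(keep) - set(self.item_ids)
        if missing:
            raise KeyError(f"items not in bank: {sorted(missing)}")
        return ItemBank(
            items=[self[i] for i in keep],
            metadata={i: self.metadata[i] for i in keep if i in self.metadata},
        )


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature grid over the latent trait: strictly increasing points
    with positive weights summing to 1."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)
        if pts.ndim != 1 or pts.shape != wts.shape:
            raise ValueError("points and weights must be 1-D and aligned")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(wts <= 0):
            raise ValueError("weights must be positive")
        if abs(wts.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1, got {wts.sum()!r}")

    def __len__(self) -> int:
        return self.points.size

    @classmethod
    def normal(cls, n_points: int = 49, lo: float = -6.0, hi: float = 6.0,
               mean: float = 0.0, sd: float = 1.0) -> "ThetaGrid":
        """Equally spaced grid with renormalized N(mean, sd) weights.

        The 49-point [-6, 6] default is a common choice for polytomous
        marginal maximum likelihood.
        """
        pts = np.linspace(lo, hi, n_points)
        wts = norm.pdf(pts, loc=mean, scale=sd)
        return cls(points=pts, weights=wts / wts.sum())

    def reweight(self, mean: float, sd: float) -> "ThetaGrid":
        """Same points, weights renormalized to N(mean, sd)."""
        wts = norm.pdf(self.points, loc=mean, scale=sd)
        return ThetaGrid(points=self.points, weights=wts / wts.sum())


# ---------------------------------------------------------------------------
# trace lines and derived curves
# ---------------------------------------------------------------------------

def _cum_all(item: ItemParameters, theta) -> np.ndarray:
    """Cumulative trace lines P*(x >= j) for j = 0..C at each theta.

    Returns an array of shape ``theta.shape + (C+1,)`` with the boundary
    conventions P*_0 = 1 and P*_C = 0.
    """
    theta = np.asarray(theta, dtype=float)
    z = item.slope * (theta[..., None] - item.thresholds)
    inner = 1.0 / (1.0 + np.exp(-z))
    out = np.empty(theta.shape + (item.n_categories + 1,))
    out[..., 0] = 1.0
    out[..., 1:-1] = inner
    out[..., -1] = 0.0
    return out


def cumulative_prob(item: ItemParameters, j: int, theta) -> np.ndarray | float:
    """Probability of responding in category ``j`` or higher at ``theta``.

    ``j`` indexes boundaries 1..C-1.  At ``theta == b_j`` the value is
    exactly 0.5 for any slope.
    """
    if not 1 <= j <= item.n_categories - 1:
        raise IndexError(f"boundary index j={j} out of range 1..{item.n_categories - 1}")
    theta = np.asarray(theta, dtype=float)
    z = item.slope * (theta - item.thresholds[j - 1])
    val = 1.0 / (1.0 + np.exp(-z))
    return float(val) if val.ndim == 0 else val


def category_prob(item: ItemParameters, theta) -> np.ndarray:
    """Category response probabilities (length C, summing to 1) at theta."""
    cum = _cum_all(item, theta)
    return cum[..., :-1] - cum[..., 1:]


def icc_curve(item: ItemParameters, grid: ThetaGrid) -> np.ndarray:
    """Item characteristic curves: |grid| x C matrix of category probabilities."""
    return category_prob(item, grid.points)


def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Samejima's Fisher information of one GRM item at theta.

    I(theta) = sum_j (P*'_j - P*'_{j+1})^2 / P_j  with  P*'_j = a P*_j (1 - P*_j)
    and the fixed boundaries P*_0 = 1, P*_C = 0 (whose derivatives vanish).
    """
    cum = _cum_all(item, theta)
    dcum = item.slope * cum * (1.0 - cum)  # zero at both boundaries
    probs = np.clip(cum[..., :-1] - cum[..., 1:], PROB_CLIP, None)
    num = dcum[..., :-1] - dcum[..., 1:]
    info = np.sum(num * num / probs, axis=-1)
    return float(info) if info.ndim == 0 else info


def test_information(bank: ItemBank, theta) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Test information (sum of item informations) and SE(theta) = info**-0.5."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    info = sum(item_information(it, theta) for it in bank)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(info)
    return info, se


def reliability_from_information(information: float) -> float:
    """IRT reliability 1 - 1/I, floored at 0.  I = 10 corresponds to 0.90."""
    if information <= 0:
        raise ValueError("information must be positive")
    return max(0.0, 1.0 - 1.0 / information)


def expected_total_score(bank: ItemBank, theta) -> np.ndarray | float:
    """Test characteristic curve: expected summed score at theta.

    Monotone nondecreasing in theta, from 0 (all lowest categories) to
    m*(C-1).
    """
    if len(bank) == 0:
        raise ValueError("empty bank")
    total = 0.0
    for it in bank:
        probs = category_prob(it, theta)
        total = total + probs @ np.arange(it.n_categories)
    return float(total) if np.ndim(total) == 0 else total


def score_respondents(bank: ItemBank, responses, grid: ThetaGrid):
    """Expected-a-posteriori trait scores under the grid's population prior.

    Missing responses are skipped in the likelihood.  Respondents with no
    observed responses get the prior mean 0 with SE 1 and are flagged.

    Returns a pandas DataFrame indexed by respondent id with columns
    ``theta``, ``se``, ``all_missing``.
    """
    import pandas as pd

    from .data import ResponseMatrix  # local import avoids a cycle

    if not isinstance(responses, ResponseMatrix):
        raise TypeError("responses must be a ResponseMatrix")
    if responses.n_categories != bank.common_categories():
        raise ValueError("bank and responses disagree on category count")

    logpost = np.log(grid.weights)[None, :].repeat(responses.n_respondents, axis=0)
    for col, item_id in enumerate(responses.item_ids):
        item = bank[item_id]
        logp = np.log(np.clip(icc_curve(item, grid), PROB_CLIP, None))  # T x C
        obs = ~responses.missing_mask[:, col]
        logpost[obs] += logp[:, responses.values[obs, col]].T

    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    eap = post @ grid.points
    var = post @ (grid.points**2) - eap**2
    se = np.sqrt(np.maximum(var, 0.0))

    all_missing = responses.missing_mask.all(axis=1)
    eap[all_missing] = 0.0
    se[all_missing] = 1.0
    return pd.DataFrame(
        {"theta": eap, "se": se, "all_missing": all_missing},
        index=pd.Index(responses.respondent_ids, name="respondent_id"),
    )
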