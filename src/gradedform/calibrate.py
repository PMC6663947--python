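"""Marginal-maximum-likelihood (EM) calibration of the graded response model.

The marginal likelihood of respondent ``p`` is

    L_p = sum_t w_t prod_i P(x_pi | theta_t),

with the latent-trait distribution handled by a fixed quadrature grid
(default: 49 equally spaced points on [-6, 6] with renormalized standard
normal weights, fixing the metric to theta ~ N(0,1)).  Missing responses
contribute nothing to the product.  EM alternates posterior weights on the
grid (E-step) with independent per-item maximizations of the expected
complete-data log-likelihood (M-step, quasi-Newton with thresholds
reparameterized as log gaps to keep them ordered).  A partial M-step is
enough for the generalized-EM monotonicity guarantee.

Standard errors use the outer-product-of-gradients (empirical
cross-product) approximation to the observed information of the marginal
likelihood, which also supplies the per-item covariance blocks that the
Wald DIF tests consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import MISSING, ResponseMatrix
from .grm import PROB_CLIP, ItemBank, ItemParameters, ThetaGrid

log = logging.getLogger(__name__)

__all__ = [
    "CategoryUnobserved",
    "CalibrationConfig",
    "CalibrationResult",
    "fit_grm",
    "standard_errors",
    "loglikelihood",
    "estimate_population",
]


class CategoryUnobserved(ValueError):
    """An item has a response category with zero observations."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Estimation settings.

    ``prior`` switches on MAP estimation: a dict with optional keys
    ``slope_lognormal`` = (mu, sigma) on log a and ``threshold_normal`` =
    (mu, sigma) on each b.  Off (plain ML) by default.
    """

    n_quadrature: int = 49
    grid_lo: float = -6.0
    grid_hi: float = 6.0
    prior_mean: float = 0.0        # population distribution fixing the metric
    prior_sd: float = 1.0
    tol: float = 1e-4              # max abs parameter change
    max_cycles: int = 500
    mstep_maxiter: int = 15
    on_unobserved: str = "error"   # or "collapse"
    prior: dict | None = None      # MAP priors; None = plain ML

    def make_grid(self) -> ThetaGrid:
        return ThetaGrid.normal(self.n_quadrature, self.grid_lo, self.grid_hi,
                                mean=self.prior_mean, sd=self.prior_sd)


@dataclass
class CalibrationResult:
    """Fitted bank with fit metadata and (once computed) standard errors."""

    bank: ItemBank
    loglik: float
    n_effective: int
    converged: bool
    n_cycles: int
    grid: ThetaGrid
    config: CalibrationConfig
    loglik_path: list = field(default_factory=list)
    se: pd.DataFrame | None = None          # item_id x (a, b1..)
    covariance: np.ndarray | None = None    # full OPG covariance
    param_names: list = field(default_factory=list)

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik

    @property
    def n_params(self) -> int:
        return sum(it.n_categories for it in self.bank)

    def item_cov_block(self, item_id: str) -> np.ndarray:
        """Covariance block (a, b1..b_{C-1}) for one item."""
        if self.covariance is None:
            raise ValueError("run standard_errors first")
        idx = [k for k, (i, _) in enumerate(self.param_names) if i == item_id]
        if not idx:
            raise KeyError(item_id)
        return self.covariance[np.ix_(idx, idx)]

    def parameter_table(self) -> pd.DataFrame:
        """Tidy estimates: one row per item, columns a, b1.., se_a, se_b1.. ."""
        C = max(it.n_categories for it in self.bank)
        rows = []
        for it in self.bank:
            row = {"item_id": it.item_id, "a": it.slope}
            for j, b in enumerate(it.thresholds, start=1):
                row[f"b{j}"] = b
            if self.se is not None:
                for col in self.se.columns:
                    row[f"se_{col}"] = self.se.loc[it.item_id, col]
            rows.append(row)
        cols = ["item_id", "a"] + [f"b{j}" for j in range(1, C)]
        if self.se is not None:
            cols += [f"se_{c}" for c in self.se.columns]
        return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# probability tables and their parameter derivatives
# ---------------------------------------------------------------------------

def _prob_table(item: ItemParameters, points: np.ndarray) -> np.ndarray:
    """T x C category probabilities, clipped into the open interval."""
    z = item.slope * (points[:, None] - item.thresholds[None, :])
    cum = np.empty((points.size, item.n_categories + 1))
    cum[:, 0] = 1.0
    cum[:, 1:-1] = 1.0 / (1.0 + np.exp(-z))
    cum[:, -1] = 0.0
    return np.clip(cum[:, :-1] - cum[:, 1:], PROB_CLIP, 1.0)


def _dlogprob_table(item: ItemParameters, points: np.ndarray) -> np.ndarray:
    """T x C x (1 + C-1) array of d log P_j / d(a, b_1..b_{C-1})."""
    T, C = points.size, item.n_categories
    a, b = item.slope, item.thresholds
    z = a * (points[:, None] - b[None, :])
    cum = 1.0 / (1.0 + np.exp(-z))                 # T x (C-1), interior boundaries
    q = cum * (1.0 - cum)
    probs = _prob_table(item, points)

    dP = np.zeros((T, C, C))                        # last axis: a, b_1..b_{C-1}
    for j in range(C):
        if j >= 1:                                  # lower boundary j
            dP[:, j, 0] += (points - b[j - 1]) * q[:, j - 1]
            dP[:, j, j] += -a * q[:, j - 1]
        if j + 1 <= C - 1:                          # upper boundary j+1
            dP[:, j, 0] -= (points - b[j]) * q[:, j]
            dP[:, j, j + 1] += a * q[:, j]
    return dP / probs[:, :, None]


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def _estep(bank: ItemBank, responses: ResponseMatrix, grid: ThetaGrid):
    """Posterior grid weights per respondent and the marginal log-likelihood.

    Returns (post n x T, loglik, logp_tables list of T x C arrays).
    """
    n, T = responses.n_respondents, len(grid)
    logp_tables = [np.log(_prob_table(it, grid.points)) for it in bank]
    logL = np.zeros((n, T))
    vals = responses.values
    for col in range(responses.n_items):
        x = vals[:, col]
        obs = x != MISSING
        if obs.any():
            logL[obs] += logp_tables[col][:, x[obs]].T
    logjoint = logL + np.log(grid.weights)[None, :]
    case = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - case[:, None])
    return post, float(case.sum()), logp_tables


def loglikelihood(bank: ItemBank, responses: ResponseMatrix, grid: ThetaGrid) -> float:
    """Marginal log-likelihood of a bank on a response matrix.

    Deterministic given inputs; an empty response set (or an all-missing
    respondent) contributes exactly zero.
    """
    if responses.n_respondents == 0:
        return 0.0
    _, ll, _ = _estep(bank, responses, grid)
    return ll


# ---------------------------------------------------------------------------
# M-step: one item, expected counts r (T x C)
# ---------------------------------------------------------------------------

def _pack(item: ItemParameters) -> np.ndarray:
    gaps = np.diff(item.thresholds)
    return np.concatenate([[np.log(item.slope), item.thresholds[0]], np.log(gaps)])


def _unpack(z: np.ndarray, item_id: str) -> ItemParameters:
    a = float(np.exp(z[0]))
    thr = z[1] + np.concatenate([[0.0], np.cumsum(np.exp(z[2:]))])
    return ItemParameters(item_id=item_id, slope=a, thresholds=thr)


def _mstep_objective(z, theta, r, prior):
    """Negative expected complete-data log-likelihood and gradient in z."""
    a = np.exp(z[0])
    gaps = np.exp(z[2:])
    b = z[1] + np.concatenate([[0.0], np.cumsum(gaps)])
    zz = a * (theta[:, None] - b[None, :])
    cum = 1.0 / (1.0 + np.exp(-zz))
    q = cum * (1.0 - cum)
    full = np.concatenate([np.ones((theta.size, 1)), cum, np.zeros((theta.size, 1))], axis=1)
    probs = np.clip(full[:, :-1] - full[:, 1:], PROB_CLIP, 1.0)

    f = -float(np.sum(r * np.log(probs)))

    R = r / probs                                   # T x C
    D = R[:, 1:] - R[:, :-1]                        # boundary k=1..C-1: R_k - R_{k-1}
    grad_a = -float(np.sum((theta[:, None] - b[None, :]) * q * D))
    grad_b = a * np.sum(q * D, axis=0)              # df/db_k = -dL/db_k = a * sum q D
    # chain rule to z
    g = np.empty_like(z)
    g[0] = grad_a * a
    g[1] = grad_b.sum()
    csum = np.cumsum(grad_b[::-1])[::-1]            # sum_{k>=j} grad_b[k]
    g[2:] = csum[1:] * gaps

    if prior:
        if "slope_lognormal" in prior:
            mu, sig = prior["slope_lognormal"]
            f += 0.5 * ((z[0] - mu) / sig) ** 2
            g[0] += (z[0] - mu) / sig**2
        if "threshold_normal" in prior:
            mu, sig = prior["threshold_normal"]
            f += 0.5 * float(np.sum(((b - mu) / sig) ** 2))
            db = (b - mu) / sig**2
            g[1] += db.sum()
            g[2:] += np.cumsum(db[::-1])[::-1][1:] * gaps
    return f, g


def _start_values(responses: ResponseMatrix, col: int, C: int, item_id: str) -> ItemParameters:
    x = responses.values[:, col]
    x = x[x != MISSING]
    p = np.clip([(x >= j).mean() for j in range(1, C)], 0.005, 0.995)
    a0 = 1.5
    b = -np.log(p / (1 - p)) / a0
    b = np.maximum.accumulate(b + 1e-6 * np.arange(C - 1))
    b += 0.05 * np.arange(C - 1) * (np.diff(np.concatenate([[b[0] - 1], b])) < 1e-4)
    for k in range(1, C - 1):                      # enforce strict order
        if b[k] <= b[k - 1]:
            b[k] = b[k - 1] + 0.05
    return ItemParameters(item_id=item_id, slope=a0, thresholds=b)


# ---------------------------------------------------------------------------
# the EM driver
# ---------------------------------------------------------------------------

def _validate_categories(responses: ResponseMatrix, config: CalibrationConfig):
    """Check every item shows every category; collapse or raise otherwise.

    Returns (responses, per-item category count list).  With
    ``on_unobserved="collapse"`` unobserved codes are merged out by
    renumbering each column's observed codes contiguously.
    """
    C = responses.n_categories
    vals = responses.values.copy()
    cats = []
    collapsed = False
    for col, item_id in enumerate(responses.item_ids):
        obs_cats = responses.observed_categories(col)
        if obs_cats.size < 2:
            raise CategoryUnobserved(
                f"item {item_id!r} has fewer than 2 observed categories")
        if obs_cats.size == C:
            cats.append(C)
            continue
        if config.on_unobserved == "error":
            missing_cats = sorted(set(range(C)) - set(obs_cats.tolist()))
            raise CategoryUnobserved(
                f"item {item_id!r}: categories {missing_cats} unobserved "
                f"(set on_unobserved='collapse' to merge)")
        recode = {c: k for k, c in enumerate(obs_cats.tolist())}
        x = vals[:, col]
        vals[:, col] = np.array([recode.get(v, MISSING) for v in x])
        cats.append(obs_cats.size)
        collapsed = True
        log.warning("item %r: collapsed to %d categories", item_id, obs_cats.size)
    if collapsed:
        responses = ResponseMatrix(values=vals, respondent_ids=list(responses.respondent_ids),
                                   item_ids=list(responses.item_ids),
                                   n_categories=C)
    return responses, cats


def fit_grm(responses: ResponseMatrix, config: CalibrationConfig | None = None,
            start: ItemBank | None = None) -> CalibrationResult:
    """Fit GRM item parameters by MML-EM.

    The latent metric is identified by the fixed population distribution in
    ``config`` (default N(0,1)).  Stops when the largest absolute parameter
    change falls below ``config.tol`` or at ``config.max_cycles`` (the
    result is then flagged unconverged and a warning logged).
    """
    config = config or CalibrationConfig()
    if responses.n_respondents < 1:
        raise ValueError("need at least one respondent")
    responses, cats = _validate_categories(responses, config)
    grid = config.make_grid()
    theta = grid.points
    m = responses.n_items

    if start is not None:
        items = [start[i] for i in responses.item_ids]
    else:
        items = [_start_values(responses, col, cats[col], responses.item_ids[col])
                 for col in range(m)]
    bank = ItemBank(items=items)

    obs_masks = [responses.values[:, col] != MISSING for col in range(m)]
    codes = [responses.values[:, col] for col in range(m)]

    loglik_path: list[float] = []
    converged = False
    n_cycles = 0
    for cycle in range(1, config.max_cycles + 1):
        n_cycles = cycle
        post, ll, _ = _estep(bank, responses, grid)
        loglik_path.append(ll)

        new_items = []
        max_change = 0.0
        for col, item in enumerate(bank):
            Ci = cats[col]
            obs = obs_masks[col]
            x = codes[col][obs]
            p_obs = post[obs]
            r = np.empty((len(grid), Ci))
            for j in range(Ci):
                r[:, j] = p_obs[x == j].sum(axis=0)
            z0 = _pack(item)
            res = minimize(_mstep_objective, z0, args=(theta, r, config.prior),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": config.mstep_maxiter})
            new_item = _unpack(res.x, item.item_id)
            max_change = max(
                max_change,
                abs(new_item.slope - item.slope),
                float(np.max(np.abs(new_item.thresholds - item.thresholds))),
            )
            new_items.append(new_item)
        bank = ItemBank(items=new_items)
        if max_change < config.tol:
            converged = True
            break

    final_ll = loglikelihood(bank, responses, grid)
    loglik_path.append(final_ll)
    if not converged:
        warnings.warn(f"EM did not converge in {config.max_cycles} cycles", stacklevel=2)

    bank = ItemBank(items=bank.items, metadata=dict(start.metadata) if start else {})
    return CalibrationResult(
        bank=bank,
        loglik=final_ll,
        n_effective=int((~responses.missing_mask.all(axis=1)).sum()),
        converged=converged,
        n_cycles=n_cycles,
        grid=grid,
        config=config,
        loglik_path=loglik_path,
    )


# ---------------------------------------------------------------------------
# standard errors (OPG)
# ---------------------------------------------------------------------------

def standard_errors(result: CalibrationResult, responses: ResponseMatrix) -> pd.DataFrame:
    """Per-parameter SEs from the outer-product-of-gradients approximation.

    The score of respondent p w.r.t. an item's parameters is the posterior
    expectation over the grid of the complete-data score; the empirical
    cross-product of these scores approximates the observed information.
    Caches the full covariance on ``result`` for downstream Wald tests.
    """
    bank, grid = result.bank, result.grid
    post, _, _ = _estep(bank, responses, grid)
    n = responses.n_respondents

    blocks, names = [], []
    for col, item in enumerate(bank):
        dlp = _dlogprob_table(item, grid.points)    # T x C x P_i
        x = responses.values[:, col]
        obs = x != MISSING
        Gi = np.zeros((n, item.n_categories))
        if obs.any():
            sel = dlp[:, x[obs], :]                 # T x n_obs x P_i
            Gi[obs] = np.einsum("nt,tnp->np", post[obs], sel)
        blocks.append(Gi)
        names += [(item.item_id, "a")] + [
            (item.item_id, f"b{j}") for j in range(1, item.n_categories)
        ]
    G = np.concatenate(blocks, axis=1)
    info = G.T @ G
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        norms = np.array([np.linalg.norm(b, axis=0).min() for b in blocks])
        worst = bank.item_ids[int(norms.argmin())]
        raise np.linalg.LinAlgError(
            f"information matrix singular (weakest item: {worst!r})") from None

    se = np.sqrt(np.diag(cov))
    C = max(it.n_categories for it in bank)
    table = pd.DataFrame(index=pd.Index(bank.item_ids, name="item_id"),
                         columns=["a"] + [f"b{j}" for j in range(1, C)], dtype=float)
    for (item_id, pname), s in zip(names, se):
        table.loc[item_id, pname] = s
    result.se = table
    result.covariance = cov
    result.param_names = names
    return table


# ---------------------------------------------------------------------------
# population-distribution estimation (used by DIF linking)
# ---------------------------------------------------------------------------

def estimate_population(bank: ItemBank, responses: ResponseMatrix, grid: ThetaGrid,
                        item_ids: list | None = None) -> tuple[float, float]:
    """ML estimate of a group's latent mean and SD with item parameters fixed.

    Maximizes the marginal likelihood over (mean, log sd), reweighting the
    quadrature grid; only the anchor items in ``item_ids`` (default: all)
    enter the likelihood.
    """
    if item_ids is not None:
        responses = responses.subset_items(list(item_ids))
        bank = bank.subset(list(item_ids))
    logp_tables = [np.log(_prob_table(it, grid.points)) for it in bank]
    n = responses.n_respondents
    logL = np.zeros((n, len(grid)))
    for col in range(responses.n_items):
        x = responses.values[:, col]
        obs = x != MISSING
        if obs.any():
            logL[obs] += logp_tables[col][:, x[obs]].T

    def nll(z):
        mean, sd = z[0], np.exp(z[1])
        logw = -0.5 * ((grid.points - mean) / sd) ** 2
        logw -= logsumexp(logw)
        return -float(logsumexp(logL + logw[None, :], axis=1).sum())

    res = minimize(nll, np.array([0.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400})
    return float(res.x[0]), float(np.exp(res.x[1]))
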