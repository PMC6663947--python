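"""Two-group differential item functioning via Wald tests with anchor
purification.

The flow follows the standard fixed-anchor IRT-DIF recipe: anchor item
parameters come from a pooled calibration; then, for each candidate item
and each group, the candidate's parameters are re-estimated together with
that group's latent mean and SD while every other anchor item stays fixed
at its pooled values.  The omnibus Wald chi-square on the stacked
parameter difference (df = C: slope plus C-1 thresholds) uses
outer-product-of-gradients covariance blocks from the joint
(item, mean, SD) estimation, so the uncertainty of the group metric
propagates into the test — without this the test is badly conservative.

Items with omnibus p below the level get constrained follow-up tests — a
slope difference (df 1) and a joint threshold difference (df C-1) — which
classify the DIF as non-uniform (slope differs) or uniform (only
thresholds differ).  No anchors are pre-selected: the first pass anchors
on all items (leave-one-out for the candidate itself), then iteratively
re-anchors on the non-flagged set until the flagged set stabilizes
(max 10 iterations; an oscillating set keeps the union, with a warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .calibrate import (CalibrationConfig, _dlogprob_table, _pack, _prob_table,
                        _unpack, estimate_population, fit_grm)
from .data import MISSING, ResponseMatrix
from .grm import ItemBank, ItemParameters, ThetaGrid, icc_curve, _cum_all

log = logging.getLogger(__name__)

__all__ = [
    "AnchorSetEmpty",
    "DifConfig",
    "ItemDifTest",
    "DifResult",
    "dif_scan",
    "classify_dif",
    "group_icc_overlay",
]


class AnchorSetEmpty(RuntimeError):
    """Every item was flagged for DIF, leaving nothing to anchor on."""


@dataclass(frozen=True)
class DifConfig:
    level: float = 0.01                 # flag level for omnibus and follow-ups
    max_iterations: int = 10
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)


@dataclass(frozen=True)
class ItemDifTest:
    item_id: str
    chi2: float
    df: int
    p: float
    a_chi2: float = np.nan
    a_df: int = 1
    a_p: float = np.nan
    b_chi2: float = np.nan
    b_df: int = 0
    b_p: float = np.nan
    flagged: bool = False
    dif_type: str = "none"              # none | uniform | nonuniform


@dataclass
class DifResult:
    tests: list                         # ItemDifTest per tested item
    anchors: list                       # final anchor item ids
    excluded: list                      # items excluded (unobserved category in a group)
    group_summary: dict                 # {"reference": (mean, sd), "focal": (mean, sd)}
    iteration_log: list                 # flagged set per iteration
    reference_bank: ItemBank = None
    focal_bank: ItemBank = None

    @property
    def flagged_items(self) -> list:
        return [t.item_id for t in self.tests if t.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "item_id": t.item_id, "chi2": t.chi2, "df": t.df, "p": t.p,
            "a_chi2": t.a_chi2, "a_p": t.a_p, "b_chi2": t.b_chi2, "b_p": t.b_p,
            "flagged": t.flagged, "dif_type": t.dif_type,
        } for t in self.tests])


def classify_dif(a_test: tuple, b_test: tuple, level: float = 0.01) -> str:
    """Classify DIF from constrained tests (chi2, df, p) pairs.

    A significant slope test means non-uniform DIF regardless of the
    threshold test; a significant threshold test alone means uniform DIF.
    """
    _, _, a_p = a_test
    _, _, b_p = b_test
    if np.isfinite(a_p) and a_p < level:
        return "nonuniform"
    if np.isfinite(b_p) and b_p < level:
        return "uniform"
    return "none"


def _wald(diff: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    df = diff.size
    try:
        stat = float(diff @ np.linalg.solve(cov, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(cov) @ diff)
    stat = max(stat, 0.0)
    return stat, df, float(chi2_dist.sf(stat, df))


# ---------------------------------------------------------------------------
# joint (candidate item, group mean, group sd) estimation with fixed anchors
# ---------------------------------------------------------------------------

def _joint_nll(z, theta, logL_anchor, codes, obs, C, npz):
    """Negative log-likelihood and gradient for one candidate item in one
    group: parameters z = (log a, b1, log gaps..., mu, log sd); all other
    items enter through the fixed anchor likelihood table."""
    zi, mu, logsd = z[:C], z[C], z[C + 1]
    sd = np.exp(logsd)
    item = _unpack(zi, "cand")
    logw = -0.5 * ((theta - mu) / sd) ** 2
    logw = logw - _lse(logw)
    wbar = np.exp(logw)

    logp = np.log(_prob_table(item, theta))             # T x C
    A = logL_anchor + logw[None, :]
    A = A.copy()
    A[obs] += logp[:, codes[obs]].T
    rowmax = A.max(axis=1, keepdims=True)
    expA = np.exp(A - rowmax)
    denom = expA.sum(axis=1)
    ll = float(np.sum(np.log(denom) + rowmax[:, 0]))
    post = expA / denom[:, None]                        # n x T

    # gradient wrt natural item params, via posterior-weighted scores
    dlp = _dlogprob_table(item, theta)                  # T x C x C
    g_item_nat = np.einsum("nt,tnp->p", post[obs], dlp[:, codes[obs], :])
    # chain rule natural (a, b) -> z (log a, b1, log gaps)
    a = item.slope
    gaps = np.exp(zi[2:])
    g_z = np.empty(C)
    g_z[0] = g_item_nat[0] * a
    gb = g_item_nat[1:]
    g_z[1] = gb.sum()
    g_z[2:] = np.cumsum(gb[::-1])[::-1][1:] * gaps

    u = (theta - mu) / sd**2
    u = u - wbar @ u
    v = ((theta - mu) / sd) ** 2
    v = v - wbar @ v
    g_mu = float((post @ u).sum())
    g_logsd = float((post @ v).sum())

    grad = -np.concatenate([g_z, [g_mu, g_logsd]])
    return -ll, grad


def _lse(x):
    m = x.max()
    return m + np.log(np.exp(x - m).sum())


def _fit_item_in_group(item0: ItemParameters, mu0: float, sd0: float,
                       theta: np.ndarray, logL_anchor: np.ndarray,
                       codes: np.ndarray, maxiter: int = 80):
    """Jointly estimate one item's parameters with the group's latent mean
    and SD (anchors fixed), and return the OPG covariance block of the
    item parameters with metric uncertainty propagated.

    Returns (ItemParameters, mu, sd, cov_item CxC)."""
    C = item0.n_categories
    obs = codes != MISSING
    z0 = np.concatenate([_pack(item0), [mu0, np.log(sd0)]])
    res = minimize(_joint_nll, z0,
                   args=(theta, logL_anchor, codes, obs, C, None),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
    z = res.x
    item = _unpack(z[:C], item0.item_id)
    mu, sd = float(z[C]), float(np.exp(z[C + 1]))

    # per-respondent scores in natural parameters (a, b1.., mu, log sd)
    logw = -0.5 * ((theta - mu) / sd) ** 2
    logw = logw - _lse(logw)
    wbar = np.exp(logw)
    logp = np.log(_prob_table(item, theta))
    A = logL_anchor + logw[None, :]
    A = A.copy()
    A[obs] += logp[:, codes[obs]].T
    rowmax = A.max(axis=1, keepdims=True)
    expA = np.exp(A - rowmax)
    post = expA / expA.sum(axis=1, keepdims=True)

    n = codes.size
    G = np.zeros((n, C + 2))
    dlp = _dlogprob_table(item, theta)
    G[obs, :C] = np.einsum("nt,tnp->np", post[obs], dlp[:, codes[obs], :])
    u = (theta - mu) / sd**2
    u = u - wbar @ u
    v = ((theta - mu) / sd) ** 2
    v = v - wbar @ v
    G[:, C] = post @ u
    G[:, C + 1] = post @ v

    info = G.T @ G
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return item, mu, sd, cov[:C, :C]


def dif_scan(responses: ResponseMatrix, groups, config: DifConfig | None = None) -> DifResult:
    """Omnibus + constrained Wald DIF tests with iterative anchor purification.

    ``groups`` is a per-respondent array of "reference"/"focal" labels
    (anything else, including None/NaN, drops the respondent from the DIF
    analysis only).
    """
    config = config or DifConfig()
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != responses.n_respondents:
        raise ValueError("group labels must align with respondents")
    keep = (groups == "reference") | (groups == "focal")
    if (~keep).any():
        log.info("DIF: dropping %d respondents without a group label", int((~keep).sum()))
    resp = responses.subset_respondents(keep)
    glab = groups[keep]
    ref_mask = glab == "reference"
    foc_mask = glab == "focal"
    if ref_mask.sum() < 2 or foc_mask.sum() < 2:
        raise ValueError("need at least 2 respondents per group")
    group_resp = {"reference": resp.subset_respondents(ref_mask),
                  "focal": resp.subset_respondents(foc_mask)}

    # items must show every category in both groups to be testable
    C = resp.n_categories
    testable, excluded = [], []
    for col, item_id in enumerate(resp.item_ids):
        ok = all(r.observed_categories(col).size == C for r in group_resp.values())
        (testable if ok else excluded).append(item_id)
    if excluded:
        warnings.warn(f"items excluded from DIF (unobserved category in a group): "
                      f"{excluded}", stacklevel=2)
        resp = resp.subset_items(testable)
        group_resp = {g: r.subset_items(testable) for g, r in group_resp.items()}

    cal_cfg = config.calibration
    pooled = fit_grm(resp, cal_cfg)
    grid = pooled.grid
    theta = grid.points
    ids = resp.item_ids
    m = len(ids)

    # fixed per-group anchor machinery at pooled parameter values
    logp_tables = {i: np.log(_prob_table(pooled.bank[i], theta)) for i in ids}
    group_logL = {}          # per group: per item contribution tables (n x T)
    for g, r in group_resp.items():
        contribs = np.zeros((m, r.n_respondents, len(grid)))
        for col, item_id in enumerate(ids):
            x = r.values[:, col]
            obs = x != MISSING
            if obs.any():
                contribs[col][obs] = logp_tables[item_id][:, x[obs]].T
        group_logL[g] = contribs

    anchors = list(ids)                 # no pre-selected anchors: start with all
    iteration_log = []
    tests: list[ItemDifTest] = []
    group_summary = {}
    group_banks = {}
    prev_flagged: set | None = None

    for iteration in range(1, config.max_iterations + 1):
        anchor_cols = [ids.index(i) for i in anchors]
        fits = {}                       # (group, item) -> (item, mu, sd, cov)
        for g, r in group_resp.items():
            mu0, sd0 = estimate_population(pooled.bank, r, grid, item_ids=anchors)
            group_summary[g] = (mu0, sd0)
            contribs = group_logL[g]
            anchor_sum = contribs[anchor_cols].sum(axis=0)
            for col, item_id in enumerate(ids):
                logL_anchor = anchor_sum - contribs[col] if col in anchor_cols \
                    else anchor_sum
                fits[(g, item_id)] = _fit_item_in_group(
                    pooled.bank[item_id], mu0, sd0, theta, logL_anchor,
                    r.values[:, col])

        tests = []
        for item_id in ids:
            ir, mu_r, sd_r, cov_r = fits[("reference", item_id)]
            if_, mu_f, sd_f, cov_f = fits[("focal", item_id)]
            d = np.concatenate([[if_.slope - ir.slope], if_.thresholds - ir.thresholds])
            cov = cov_r + cov_f
            chi2, df, p = _wald(d, cov)
            rec = ItemDifTest(item_id=item_id, chi2=chi2, df=df, p=p)
            if p < config.level:
                a_stat = _wald(d[:1], cov[:1, :1])
                b_stat = _wald(d[1:], cov[1:, 1:])
                rec = replace(rec,
                              a_chi2=a_stat[0], a_df=a_stat[1], a_p=a_stat[2],
                              b_chi2=b_stat[0], b_df=b_stat[1], b_p=b_stat[2],
                              flagged=True,
                              dif_type=classify_dif(a_stat, b_stat, config.level))
                if rec.dif_type == "none":
                    # omnibus significant but neither constrained test is:
                    # keep the flag, attribute to the stronger component
                    rec = replace(rec, dif_type="uniform" if b_stat[2] <= a_stat[2]
                                  else "nonuniform")
            tests.append(rec)

        group_banks = {
            g: ItemBank(items=[fits[(g, i)][0] for i in ids])
            for g in group_resp
        }
        flagged = {t.item_id for t in tests if t.flagged}
        iteration_log.append({"iteration": iteration, "anchors": list(anchors),
                              "flagged": sorted(flagged),
                              "group_summary": dict(group_summary)})
        if not (set(ids) - flagged):
            raise AnchorSetEmpty("all items flagged for DIF; no anchors remain")
        if set(ids) - flagged == set(anchors):
            break   # anchors unchanged: the next pass would be identical
        if prev_flagged is not None and flagged == prev_flagged:
            break
        if any(flagged == set(rec["flagged"]) for rec in iteration_log[:-2]):
            union = flagged | (prev_flagged or set())
            warnings.warn("DIF purification oscillated; keeping the union of "
                          "flagged sets", stacklevel=2)
            tests = [replace(t, flagged=True) if t.item_id in union else t
                     for t in tests]
            break
        prev_flagged = flagged
        anchors = [i for i in ids if i not in flagged]
    else:
        warnings.warn("DIF purification hit the iteration cap", stacklevel=2)

    final_anchors = [i for i in ids
                     if i not in {t.item_id for t in tests if t.flagged}]
    return DifResult(tests=tests, anchors=final_anchors, excluded=excluded,
                     group_summary=group_summary, iteration_log=iteration_log,
                     reference_bank=group_banks["reference"],
                     focal_bank=group_banks["focal"])


def group_icc_overlay(reference: ItemParameters, focal: ItemParameters,
                      grid: ThetaGrid) -> dict:
    """Paired category and cumulative curves for graphical DIF magnitude.

    Returns the grid, each group's category curves (|grid| x C) and
    cumulative curves (|grid| x (C-1)), plus the mean area between the two
    expected-score curves as a scalar magnitude summary.
    """
    if reference.n_categories != focal.n_categories:
        raise ValueError("groups disagree on category count")
    ref_icc = icc_curve(reference, grid)
    foc_icc = icc_curve(focal, grid)
    ref_cum = _cum_all(reference, grid.points)[:, 1:-1]
    foc_cum = _cum_all(focal, grid.points)[:, 1:-1]
    cats = np.arange(reference.n_categories)
    ref_escore = ref_icc @ cats
    foc_escore = foc_icc @ cats
    area = float(np.trapezoid(np.abs(foc_escore - ref_escore), grid.points)
                 / (grid.points[-1] - grid.points[0]))
    return {
        "theta": grid.points,
        "reference_icc": ref_icc, "focal_icc": foc_icc,
        "reference_cumulative": ref_cum, "focal_cumulative": foc_cum,
        "reference_expected_score": ref_escore, "focal_expected_score": foc_escore,
        "area_between_curves": area,
    }
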