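"""Item fit, local dependence, scale-level model fit and reliability.

Item fit uses the summed-score (Orlando-Thissen style) S-X2: respondents
are grouped by their rest score (summed score excluding the item under
test), model-expected category proportions per rest-score group come from
the recursive summed-score distribution over the quadrature grid, sparse
groups are collapsed, and a Pearson X2 compares observed to expected
cells.  p-values are Benjamini-Hochberg adjusted across items.

Local dependence is the standardized bivariate X2: observed vs
model-expected C x C tables per item pair, with (X2 - df)/sqrt(2 df)
reported; values of 10 or more flag a pair, 5-10 is a reported-but-not-
flagged borderline band.

Scale-level fit combines -2LL, AIC/BIC, the limited-information M2
statistic on univariate + bivariate category margins with its RMSEA,
Cronbach's alpha and IRT marginal reliability.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .calibrate import CalibrationResult, _estep, _prob_table, _dlogprob_table
from .data import MISSING, ResponseMatrix
from .grm import score_respondents

log = logging.getLogger(__name__)

__all__ = [
    "ItemFitRecord",
    "LdMatrix",
    "ModelFitStats",
    "item_fit_sx2",
    "local_dependence",
    "model_fit",
    "cronbach_alpha",
    "marginal_reliability",
    "bh_adjust",
]

LD_FLAG_THRESHOLD = 10.0
LD_BORDERLINE = 5.0
DEFAULT_ALPHA_LEVEL = 0.01


@dataclass(frozen=True)
class ItemFitRecord:
    item_id: str
    sx2: float
    df: int
    p: float
    p_adjusted: float = np.nan
    flagged: bool = False


@dataclass
class LdMatrix:
    """Symmetric matrix of standardized local-dependence statistics."""

    values: pd.DataFrame             # m x m, NaN diagonal
    flag_threshold: float = LD_FLAG_THRESHOLD
    borderline: tuple = (LD_BORDERLINE, LD_FLAG_THRESHOLD)

    def flagged_pairs(self) -> list:
        out = []
        ids = list(self.values.index)
        for i, j in itertools.combinations(range(len(ids)), 2):
            if self.values.iat[i, j] >= self.flag_threshold:
                out.append((ids[i], ids[j]))
        return out

    def borderline_pairs(self) -> list:
        lo, hi = self.borderline
        out = []
        ids = list(self.values.index)
        for i, j in itertools.combinations(range(len(ids)), 2):
            if lo <= self.values.iat[i, j] < hi:
                out.append((ids[i], ids[j]))
        return out


@dataclass(frozen=True)
class ModelFitStats:
    minus2ll: float
    n_params: int
    n: int
    aic: float
    bic: float
    m2: float
    m2_df: int
    m2_p: float
    rmsea: float
    cronbach_alpha: float
    marginal_reliability: float


def bh_adjust(pvalues, level: float = DEFAULT_ALPHA_LEVEL):
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    Thin wrapper over statsmodels' ``multipletests(method="fdr_bh")``;
    rejection means adjusted p < level.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return adj, adj < level


# ---------------------------------------------------------------------------
# S-X2 item fit
# ---------------------------------------------------------------------------

def _score_distributions(prob_tables: list, skip: int | None = None) -> np.ndarray:
    """Recursive summed-score distribution over the grid.

    prob_tables: per item T x C probability tables.  Returns T x (S+1)
    where S is the max summed score over the included items.
    """
    T = prob_tables[0].shape[0]
    f = np.ones((T, 1))
    for col, P in enumerate(prob_tables):
        if col == skip:
            continue
        C = P.shape[1]
        new = np.zeros((T, f.shape[1] + C - 1))
        for j in range(C):
            new[:, j:j + f.shape[1]] += f * P[:, [j]]
        f = new
    return f


def _collapse_rows(obs: np.ndarray, exp: np.ndarray, min_expected: float):
    """Merge adjacent rest-score rows (from the extremes inward) until every
    row's expected cell minimum is >= min_expected.  Returns lists of row
    index groups."""
    rows = [[k] for k in range(obs.shape[0])]

    def row_ok(group):
        return exp[group].sum(axis=0).min() >= min_expected

    changed = True
    while changed and len(rows) > 1:
        changed = False
        # sweep from the low end, then the high end
        for idx in list(range(len(rows) - 1)) + list(range(len(rows) - 1, 0, -1)):
            if len(rows) <= 1:
                break
            if idx >= len(rows):
                continue
            if not row_ok(rows[idx]):
                if idx < len(rows) - 1:
                    rows[idx] = rows[idx] + rows.pop(idx + 1)
                else:
                    rows[idx - 1] = rows[idx - 1] + rows.pop(idx)
                changed = True
                break
    return rows


def item_fit_sx2(result: CalibrationResult, responses: ResponseMatrix,
                 alpha_level: float = DEFAULT_ALPHA_LEVEL,
                 min_expected: float = 1.0) -> list[ItemFitRecord]:
    """Summed-score S-X2 item-fit statistics with BH adjustment across items.

    Requires complete response vectors (rest scores are undefined
    otherwise); respondents with any missing response are dropped with a
    log notice.
    """
    complete = ~responses.missing_mask.any(axis=1)
    if not complete.all():
        log.info("S-X2: dropping %d incomplete respondents", int((~complete).sum()))
    resp = responses.subset_respondents(complete)
    if resp.n_respondents < 50:
        raise ValueError(
            f"only {resp.n_respondents} complete respondents; too few for "
            "summed-score item-fit groups (lower min_expected or use more data)")

    bank, grid = result.bank, result.grid
    prob_tables = [_prob_table(it, grid.points) for it in bank]
    w = grid.weights
    m = resp.n_items
    total = resp.values.sum(axis=1)

    records = []
    for col, item in enumerate(bank):
        C = item.n_categories
        rest = total - resp.values[:, col]
        S_rest = rest.max()
        frest = _score_distributions(prob_tables, skip=col)      # T x (S-1)*?..
        n_scores = frest.shape[1]
        # expected joint mass over (rest score k, category j)
        joint = np.einsum("t,tk,tj->kj", w, frest, prob_tables[col])
        obs = np.zeros((n_scores, C))
        for k, j in zip(rest, resp.values[:, col]):
            obs[k, j] += 1
        exp = joint / joint.sum() * resp.n_respondents

        groups = _collapse_rows(obs, exp, min_expected)
        sx2 = 0.0
        n_cells = 0
        for g in groups:
            o = obs[g].sum(axis=0)
            e = exp[g].sum(axis=0)
            # merge sparse category cells within the row, adjacent first
            cells_o, cells_e = [], []
            co, ce = 0.0, 0.0
            for j in range(C):
                co += o[j]
                ce += e[j]
                if ce >= min_expected:
                    cells_o.append(co)
                    cells_e.append(ce)
                    co, ce = 0.0, 0.0
            if ce > 0 or co > 0:
                if cells_e:
                    cells_o[-1] += co
                    cells_e[-1] += ce
                else:
                    cells_o.append(co)
                    cells_e.append(ce)
            for o_c, e_c in zip(cells_o, cells_e):
                if e_c > 0:
                    sx2 += (o_c - e_c) ** 2 / e_c
                    n_cells += 1
        df = n_cells - C - len(groups)   # item params = C (slope + C-1 thresholds)
        df = max(df, 1)
        p = float(chi2_dist.sf(sx2, df))
        records.append(ItemFitRecord(item_id=item.item_id, sx2=float(sx2), df=int(df), p=p))

    adj, reject = bh_adjust([r.p for r in records], level=alpha_level)
    return [ItemFitRecord(r.item_id, r.sx2, r.df, r.p, float(a), bool(rej))
            for r, a, rej in zip(records, adj, reject)]


# ---------------------------------------------------------------------------
# local dependence
# ---------------------------------------------------------------------------

def local_dependence(result: CalibrationResult, responses: ResponseMatrix,
                     min_expected: float = 1.0) -> LdMatrix:
    """Standardized bivariate X2 local-dependence statistics for all pairs.

    Expected pair tables integrate the product of the two items' category
    probabilities over the posterior-weighted trait distribution of the
    respondents observed on both items.  Cells with expected count below
    ``min_expected`` are merged with adjacent cells (rows, then columns).
    """
    bank, grid = result.bank, result.grid
    m = responses.n_items
    if m < 2:
        raise ValueError("need at least two items")
    post, _, _ = _estep(bank, responses, grid)
    prob_tables = [_prob_table(it, grid.points) for it in bank]
    ids = responses.item_ids
    vals = responses.values

    out = np.full((m, m), np.nan)
    for i, k in itertools.combinations(range(m), 2):
        both = (vals[:, i] != MISSING) & (vals[:, k] != MISSING)
        n_pair = int(both.sum())
        if n_pair == 0:
            log.warning("LD: no joint observations for pair (%s, %s)", ids[i], ids[k])
            continue
        mass = post[both].sum(axis=0)                    # posterior mass per node
        exp = np.einsum("t,tj,tl->jl", mass, prob_tables[i], prob_tables[k])
        exp *= n_pair / exp.sum()
        Ci, Ck = prob_tables[i].shape[1], prob_tables[k].shape[1]
        obs = np.zeros((Ci, Ck))
        np.add.at(obs, (vals[both, i], vals[both, k]), 1.0)

        obs_c, exp_c = _collapse_table(obs, exp, min_expected)
        x2 = float(np.sum((obs_c - exp_c) ** 2 / np.maximum(exp_c, 1e-300)))
        df = (obs_c.shape[0] - 1) * (obs_c.shape[1] - 1)
        df = max(df, 1)
        out[i, k] = out[k, i] = (x2 - df) / np.sqrt(2.0 * df)

    return LdMatrix(values=pd.DataFrame(out, index=ids, columns=ids))


def _collapse_table(obs: np.ndarray, exp: np.ndarray, min_expected: float):
    """Merge adjacent rows/columns of a 2-way table until all expected
    cells reach min_expected (or only a 2x2 remains)."""
    obs, exp = obs.copy(), exp.copy()
    while exp.min() < min_expected and min(exp.shape) > 2:
        r, c = np.unravel_index(np.argmin(exp), exp.shape)
        if exp.shape[0] >= exp.shape[1]:
            j = r - 1 if r == exp.shape[0] - 1 else r + 1
            obs[min(r, j)] += obs[max(r, j)]
            exp[min(r, j)] += exp[max(r, j)]
            obs = np.delete(obs, max(r, j), axis=0)
            exp = np.delete(exp, max(r, j), axis=0)
        else:
            j = c - 1 if c == exp.shape[1] - 1 else c + 1
            obs[:, min(c, j)] += obs[:, max(c, j)]
            exp[:, min(c, j)] += exp[:, max(c, j)]
            obs = np.delete(obs, max(c, j), axis=1)
            exp = np.delete(exp, max(c, j), axis=1)
    return obs, exp


# ---------------------------------------------------------------------------
# classical and IRT reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(responses: ResponseMatrix) -> float:
    """Cronbach's alpha from the pairwise-available covariance matrix.

    alpha = m/(m-1) * (1 - sum item variances / total variance), with the
    total-score variance assembled from pairwise-complete covariances so
    incomplete data need not be discarded.
    """
    if responses.n_items < 2:
        raise ValueError("need at least two items")
    frame = responses.to_frame()
    cov = frame.cov().to_numpy()                 # pairwise-complete by default
    m = responses.n_items
    total_var = float(cov.sum())
    if not np.isfinite(total_var) or total_var <= 0:
        return float("nan")
    return m / (m - 1) * (1.0 - float(np.trace(cov)) / total_var)


def marginal_reliability(result: CalibrationResult, responses: ResponseMatrix) -> float:
    """1 - mean EAP posterior variance across respondents (N(0,1) population)."""
    scores = score_respondents(result.bank, responses, result.grid)
    return float(1.0 - np.mean(scores["se"] ** 2))


# ---------------------------------------------------------------------------
# limited-information model fit (M2) and summary stats
# ---------------------------------------------------------------------------

def _m2_statistic(result: CalibrationResult, responses: ResponseMatrix,
                  max_margins: int = 2500):
    """M2 on first- and second-order category margins (categories 1..C-1).

    Returns (m2, df, p).  Uses complete cases (the sample margin vector
    needs one common n).  NaN when the margin system is too large or
    under-identified.
    """
    complete = ~responses.missing_mask.any(axis=1)
    resp = responses.subset_respondents(complete)
    n = resp.n_respondents
    bank, grid = result.bank, result.grid
    m = resp.n_items
    C = bank.common_categories()
    n_params = sum(it.n_categories for it in bank)

    n_margins = m * (C - 1) + m * (m - 1) // 2 * (C - 1) ** 2
    if n_margins <= n_params:
        warnings.warn("M2 undefined: margins do not exceed parameter count", stacklevel=2)
        return np.nan, 0, np.nan
    if n_margins > max_margins:
        warnings.warn(f"M2 skipped: {n_margins} margins exceeds limit {max_margins}",
                      stacklevel=2)
        return np.nan, 0, np.nan
    if n < 50:
        warnings.warn("M2 skipped: fewer than 50 complete cases", stacklevel=2)
        return np.nan, 0, np.nan

    w = grid.weights
    P = [_prob_table(it, grid.points) for it in bank]        # T x C each
    dP = [_dlogprob_table(it, grid.points) * _prob_table(it, grid.points)[:, :, None]
          for it in bank]                                    # dP/dparam, T x C x C

    # margin bookkeeping: univariate then bivariate, categories 1..C-1
    margins = []                                             # ({item: cat}, profile T,)
    for i in range(m):
        for j in range(1, C):
            margins.append(({i: j}, P[i][:, j]))
    for i, k in itertools.combinations(range(m), 2):
        for j in range(1, C):
            for l in range(1, C):
                margins.append(({i: j, k: l}, P[i][:, j] * P[k][:, l]))
    A = np.stack([prof for _, prof in margins])              # M x T
    pmod = A @ w

    # observed margins
    pobs = np.empty_like(pmod)
    vals = resp.values
    idx = 0
    for i in range(m):
        for j in range(1, C):
            pobs[idx] = np.mean(vals[:, i] == j)
            idx += 1
    for i, k in itertools.combinations(range(m), 2):
        for j in range(1, C):
            for l in range(1, C):
                pobs[idx] = np.mean((vals[:, i] == j) & (vals[:, k] == l))
                idx += 1

    # Gamma = E[z z'] - p p'; start with the conditional-independence product
    # (exact for margin pairs with disjoint item sets) and patch overlaps.
    E = (A * w) @ A.T
    by_item: dict[int, list] = {}
    for a_idx, (assign, _) in enumerate(margins):
        for it in assign:
            by_item.setdefault(it, []).append(a_idx)
    seen = set()
    for item_list in by_item.values():
        for a_idx, b_idx in itertools.combinations(item_list, 2):
            if (a_idx, b_idx) in seen:
                continue
            seen.add((a_idx, b_idx))
            aa, bb = margins[a_idx][0], margins[b_idx][0]
            conflict = any(aa[i2] != bb[i2] for i2 in aa.keys() & bb.keys())
            if conflict:
                val = 0.0
            else:
                prof = np.ones(len(w))
                for i2, c2 in {**aa, **bb}.items():
                    prof = prof * P[i2][:, c2]
                val = float(prof @ w)
            E[a_idx, b_idx] = E[b_idx, a_idx] = val
    np.fill_diagonal(E, pmod)
    Gamma = E - np.outer(pmod, pmod)

    # Jacobian of model margins w.r.t. item parameters
    Delta = np.zeros((len(margins), n_params))
    offsets = np.cumsum([0] + [it.n_categories for it in bank])
    for a_idx, (assign, _) in enumerate(margins):
        items2 = list(assign.items())
        for pos, (i2, c2) in enumerate(items2):
            other = np.ones(len(w))
            for k2, c3 in items2:
                if k2 != i2:
                    other = other * P[k2][:, c3]
            block = np.einsum("t,tp->p", w * other, dP[i2][:, c2, :])
            Delta[a_idx, offsets[i2]:offsets[i2 + 1]] += block

    try:
        Gi = np.linalg.solve(Gamma, np.eye(Gamma.shape[0]))
    except np.linalg.LinAlgError:
        Gi = np.linalg.pinv(Gamma)
    GiD = Gi @ Delta
    middle = Delta.T @ GiD
    try:
        corr = GiD @ np.linalg.solve(middle, GiD.T)
    except np.linalg.LinAlgError:
        corr = GiD @ np.linalg.pinv(middle) @ GiD.T
    Cmat = Gi - corr
    e = pobs - pmod
    m2 = float(n * e @ Cmat @ e)
    df = len(margins) - n_params
    p = float(chi2_dist.sf(m2, df))
    return m2, df, p


def model_fit(result: CalibrationResult, responses: ResponseMatrix,
              compute_m2: bool = True) -> ModelFitStats:
    """Scale-level fit summary: -2LL, AIC, BIC, M2 (+RMSEA), alpha and
    marginal reliability.

    AIC = -2LL + 2k and BIC = -2LL + k ln(n) hold exactly by construction;
    RMSEA = sqrt(max(0, (M2 - df) / (df * n))) on the complete-case n used
    for M2.
    """
    minus2ll = result.minus2ll
    k = result.n_params
    n = result.n_effective
    if compute_m2:
        m2, m2_df, m2_p = _m2_statistic(result, responses)
    else:
        m2, m2_df, m2_p = np.nan, 0, np.nan
    if np.isfinite(m2) and m2_df > 0:
        n_complete = int((~responses.missing_mask.any(axis=1)).sum())
        rmsea = float(np.sqrt(max(0.0, (m2 - m2_df) / (m2_df * n_complete))))
    else:
        rmsea = np.nan
    return ModelFitStats(
        minus2ll=minus2ll,
        n_params=k,
        n=n,
        aic=minus2ll + 2 * k,
        bic=minus2ll + k * np.log(n),
        m2=m2,
        m2_df=int(m2_df),
        m2_p=m2_p,
        rmsea=rmsea,
        cronbach_alpha=cronbach_alpha(responses) if responses.n_items >= 2 else np.nan,
        marginal_reliability=marginal_reliability(result, responses),
    )
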