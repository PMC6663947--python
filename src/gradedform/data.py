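"""Respondent-by-item response container.

Responses are integer category codes 0..C-1 stored in an int array with a
sentinel for missing cells; the convention throughout the package is that a
missing response simply contributes nothing to any likelihood ("use all
available information" — no listwise deletion, no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["MISSING", "ResponseMatrix"]


@dataclass
class ResponseMatrix:
    """n x m matrix of polytomous category codes with a missing mask.

    Parameters
    ----------
    values
        Integer array, entries in ``0..C-1`` or ``MISSING`` (-1).
    respondent_ids, item_ids
        Row / column labels; must match the array shape.
    n_categories
        The common category count C (>= 2).
    """

    values: np.ndarray
    respondent_ids: list = field(default_factory=list)
    item_ids: list = field(default_factory=list)
    n_categories: int = 5

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.issubdtype(vals.dtype, np.integer):
            if np.any(~np.isnan(vals.astype(float)) & (vals != np.floor(vals))):
                raise ValueError("non-integer response codes")
            vals = np.where(np.isnan(vals.astype(float)), MISSING, vals).astype(np.int64)
        self.values = vals.astype(np.int64)
        n, m = vals.shape
        if m < 1:
            raise ValueError("need at least one item")
        # n == 0 is tolerated (useful for degenerate likelihood queries);
        # calibration itself requires n >= 1.
        if not self.respondent_ids:
            self.respondent_ids = list(range(n))
        if not self.item_ids:
            self.item_ids = [f"item{j + 1}" for j in range(m)]
        if len(self.respondent_ids) != n or len(self.item_ids) != m:
            raise ValueError("id lengths must match the value matrix")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        obs = self.values[self.values != MISSING]
        if obs.size and (obs.min() < 0 or obs.max() > self.n_categories - 1):
            raise ValueError(
                f"response codes outside 0..{self.n_categories - 1}: "
                f"range [{obs.min()}, {obs.max()}]"
            )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    @property
    def missing_rate(self) -> float:
        return float(self.missing_mask.mean())

    def column(self, item_id) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def subset_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            values=self.values[:, idx].copy(),
            respondent_ids=list(self.respondent_ids),
            item_ids=list(item_ids),
            n_categories=self.n_categories,
        )

    def subset_respondents(self, row_mask) -> "ResponseMatrix":
        row_mask = np.asarray(row_mask)
        ids = [r for r, keep in zip(self.respondent_ids, row_mask) if keep]
        return ResponseMatrix(
            values=self.values[row_mask].copy(),
            respondent_ids=ids,
            item_ids=list(self.item_ids),
            n_categories=self.n_categories,
        )

    def observed_categories(self, col: int) -> np.ndarray:
        """Sorted distinct observed codes in one column."""
        v = self.values[:, col]
        return np.unique(v[v != MISSING])

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with NaN for missing cells."""
        vals = self.values.astype(float)
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(
            vals,
            index=pd.Index(self.respondent_ids, name="respondent_id"),
            columns=self.item_ids,
        )
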