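"""Readers/writers for the wide-CSV response dialect, response times, item
parameter tables and content maps, plus the response-time cleaning rule.

The response dialect: first column = respondent id, remaining columns =
item ids, cells = integer category codes or blank (missing).  A dialect
``origin`` remaps 1-based files to the package's 0-based codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, ResponseMatrix
from .shortform import ContentMap

__all__ = [
    "RtMatrix",
    "read_responses",
    "write_responses",
    "read_response_times",
    "rt_filter",
    "read_content_map",
    "write_content_map",
    "write_parameter_table",
]


@dataclass
class RtMatrix:
    """Per-response response times in seconds (NaN = missing)."""

    values: np.ndarray
    respondent_ids: list
    item_ids: list

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.isfinite(vals).any() and np.nanmin(vals) < 0:
            raise ValueError("response times must be nonnegative")
        self.values = vals


def read_responses(path, origin: int = 0, n_categories: int | None = None) -> ResponseMatrix:
    """Read a wide-CSV response matrix.

    Blanks become missing; codes are shifted to 0-based via ``origin``.
    C is inferred from the data unless given (and validated either way).
    """
    frame = pd.read_csv(path, index_col=0)
    vals = np.full(frame.shape, MISSING, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        series = frame[col]
        obs = series.notna()
        raw = series[obs]
        as_float = pd.to_numeric(raw, errors="coerce")
        if as_float.isna().any():
            bad = raw[as_float.isna()].index[0]
            raise ValueError(f"non-integer cell at row {bad!r}, column {col!r}")
        if (as_float != np.floor(as_float)).any():
            bad = raw[(as_float != np.floor(as_float))].index[0]
            raise ValueError(f"non-integer cell at row {bad!r}, column {col!r}")
        vals[obs.to_numpy(), j] = as_float.astype(int) - origin
    obs_vals = vals[vals != MISSING]
    if obs_vals.size == 0:
        raise ValueError("file contains no observed responses")
    inferred = int(obs_vals.max()) + 1
    C = n_categories or inferred
    if obs_vals.min() < 0 or inferred > C:
        raise ValueError(
            f"codes outside 0..{C - 1} after origin shift "
            f"(observed range {obs_vals.min()}..{obs_vals.max()})")
    return ResponseMatrix(values=vals, respondent_ids=list(frame.index),
                          item_ids=list(frame.columns), n_categories=C)


def write_responses(responses: ResponseMatrix, path, origin: int = 0) -> None:
    frame = responses.to_frame()
    if origin:
        frame = frame + origin
    # integer-formatted cells, blanks for missing
    frame.to_csv(path, float_format="%.0f")


def read_response_times(path) -> RtMatrix:
    frame = pd.read_csv(path, index_col=0)
    return RtMatrix(values=frame.to_numpy(dtype=float),
                    respondent_ids=list(frame.index), item_ids=list(frame.columns))


def rt_filter(responses: ResponseMatrix, rt: RtMatrix,
              mean_cutoff: float = 1.0, run_cutoff: int = 10):
    """Drop careless responders by the response-time rule.

    A respondent is removed when their mean response time is below
    ``mean_cutoff`` seconds OR they have ``run_cutoff`` or more consecutive
    items answered faster than ``mean_cutoff`` seconds.  Returns the
    filtered matrix and a removal ledger (respondent_id, reason); the
    ledger plus the retained rows partition the input exactly.
    """
    if rt.values.shape != responses.values.shape:
        raise ValueError("response-time matrix does not match responses")
    vals = rt.values
    with np.errstate(invalid="ignore"):
        mean_rt = np.nanmean(vals, axis=1)
    fast = np.nan_to_num(vals, nan=np.inf) < mean_cutoff

    def longest_run(row) -> int:
        best = cur = 0
        for f in row:
            cur = cur + 1 if f else 0
            best = max(best, cur)
        return best

    runs = np.array([longest_run(r) for r in fast])
    drop_mean = mean_rt < mean_cutoff
    drop_run = runs >= run_cutoff
    drop = drop_mean | drop_run
    ledger = pd.DataFrame({
        "respondent_id": [r for r, d in zip(responses.respondent_ids, drop) if d],
        "reason": ["mean_rt" if dm else "fast_run"
                   for dm, d in zip(drop_mean, drop) if d],
    })
    return responses.subset_respondents(~drop), ledger


def read_content_map(path) -> ContentMap:
    with open(path) as fh:
        return ContentMap.from_json_records(json.load(fh))


def write_content_map(content_map: ContentMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(content_map.to_json_records(), fh, indent=1)


def write_parameter_table(result, path) -> None:
    """CSV with columns item_id, a, b1.., se_a, se_b1.. ."""
    result.parameter_table().to_csv(path, index=False, float_format="%.6g")
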