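"""Entropy-method objective weighting of indicators.

Values are first min-max standardized with orientation applied (so larger
is always better and every column lands in [0, 1]); working on raw values
would be invalid whenever an indicator (e.g. net income) takes negative
values.  Each standardized column is then treated as a distribution over
treatments: its Shannon entropy e_j (normalized by ln m) measures how
uninformative the indicator is, the divergence d_j = 1 − e_j measures
dispersion, and weights are the normalized divergences.  Constant columns
carry no information and receive weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ahp import WeightVector
from .exceptions import DataError
from .trial_data import TrialTable

__all__ = ["StandardizedTable", "minmax_standardize", "entropy_weighting"]


@dataclass
class StandardizedTable:
    """Treatment × indicator matrix mapped to [0, 1] with orientation
    applied (1 = column best, 0 = column worst); constant columns are
    flagged, not divided."""

    values: pd.DataFrame
    constant_columns: tuple[str, ...]


def minmax_standardize(table: TrialTable) -> StandardizedTable:
    """Orientation-aware min-max standardization.

    Positive indicators map as (x − min)/(max − min); negative ones as
    (max − x)/(max − min).  Requires at least two treatments.
    """
    if len(table.treatments) < 2:
        raise DataError("standardization requires >= 2 treatments")
    out = {}
    constant = []
    for ind in table.indicators:
        col = table.column(ind).to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            constant.append(ind)
            out[ind] = np.zeros_like(col)
            continue
        if table.orientation(ind) == "positive":
            out[ind] = (col - lo) / (hi - lo)
        else:
            out[ind] = (hi - col) / (hi - lo)
    values = pd.DataFrame(out, index=table.values.index)[table.indicators]
    return StandardizedTable(values=values, constant_columns=tuple(constant))


def entropy_weighting(std: StandardizedTable) -> tuple[WeightVector, pd.DataFrame]:
    """Entropy weights plus a per-indicator diagnostics frame.

    For each non-constant column: P_ij = G_ij / Σ_i G_ij,
    e_j = −(1/ln m) Σ_i P_ij ln P_ij (with 0·ln 0 := 0), d_j = 1 − e_j,
    and weights are d_j normalized to sum 1.  Constant columns get
    d_j = 0 directly.  Diagnostics columns: e, d, weight.
    """
    m = len(std.values.index)
    if m < 2:
        raise DataError("entropy weighting requires >= 2 treatments")
    cols = list(std.values.columns)
    e = pd.Series(index=cols, dtype=float)
    d = pd.Series(index=cols, dtype=float)
    for ind in cols:
        if ind in std.constant_columns:
            e[ind] = 1.0  # uninformative by definition
            d[ind] = 0.0
            continue
        g = std.values[ind].to_numpy(dtype=float)
        total = g.sum()
        if total <= 0:  # cannot happen after min-max, defensive
            e[ind] = 1.0
            d[ind] = 0.0
            continue
        p = g / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        e[ind] = -terms.sum() / np.log(m)
        d[ind] = 1.0 - e[ind]
    if d.sum() <= 0:
        raise DataError(
            "all indicator columns are constant; entropy weights undefined"
        )
    weights = WeightVector.from_values(cols, d.to_numpy())
    diagnostics = pd.DataFrame({"e": e, "d": d, "weight": weights.as_series()})
    return weights, diagnostics
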