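"""Fuzzy comprehensive evaluation over five ordered grades.

Each indicator value is mapped to membership degrees over the grades
Excellent, Good, Average, Poor, Very Poor via piecewise-linear functions
parameterized by thresholds C1..C5 (trapezoidal saturation at the extremes,
triangular in the interior).  For positive indicators thresholds decrease
(C1 best); for negative indicators they increase.  The membership rows
form the matrix R; the weighted-average operator B = W·R (clamped at 1
entry-wise) gives grade memberships, the maximum membership names the
grade, and the semantic scale 5..1 turns B into a scalar score.

Membership rows always sum to 1: between two adjacent thresholds exactly
the two adjacent grades share membership linearly, and beyond C1/C5 a
single grade saturates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import WeightVector
from .exceptions import SchemeError, StructureError
from .trial_data import TrialTable

__all__ = [
    "GRADE_LABELS",
    "GRADE_VALUES",
    "GradeScheme",
    "MembershipMatrix",
    "EvaluationResult",
    "membership",
    "build_R",
    "evaluate",
    "default_grade_scheme",
]

GRADE_LABELS = ("Excellent", "Good", "Average", "Poor", "Very Poor")
GRADE_VALUES = np.array([5.0, 4.0, 3.0, 2.0, 1.0])


@dataclass(frozen=True)
class GradeScheme:
    """Five grade thresholds for one indicator.

    thresholds = (C1, ..., C5), strictly decreasing for positive
    indicators and strictly increasing for negative ones.
    """

    indicator_id: str
    orientation: str
    thresholds: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.orientation not in ("positive", "negative"):
            raise SchemeError(
                f"scheme {self.indicator_id!r}: orientation must be "
                "'positive' or 'negative'"
            )
        t = self.thresholds
        if len(t) != 5:
            raise SchemeError(f"scheme {self.indicator_id!r}: need exactly 5 thresholds")
        diffs = np.diff(t)
        if self.orientation == "positive" and not np.all(diffs < 0):
            raise SchemeError(
                f"scheme {self.indicator_id!r}: thresholds must be strictly "
                f"decreasing for a positive indicator, got {t}"
            )
        if self.orientation == "negative" and not np.all(diffs > 0):
            raise SchemeError(
                f"scheme {self.indicator_id!r}: thresholds must be strictly "
                f"increasing for a negative indicator, got {t}"
            )


@dataclass(frozen=True)
class MembershipMatrix:
    indicator_ids: tuple[str, ...]
    values: np.ndarray  # n indicators x 5 grades

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.indicator_ids), columns=list(GRADE_LABELS)
        )


@dataclass(frozen=True)
class EvaluationResult:
    B: np.ndarray  # grade-membership 5-vector
    grade: str
    score: float  # in [1, 5]
    tie: bool  # max membership shared by several grades
    clamped: bool  # the min{1, .} cap was active (only possible if Σw > 1)


def membership(x: float, scheme: GradeScheme) -> np.ndarray:
    """Membership 5-vector of a value under one grade scheme.

    A value exactly at an interior threshold C_e belongs fully to grade e;
    between adjacent thresholds the two neighboring grades share membership
    linearly; beyond C1 (resp. C5) the extreme grade saturates.
    """
    c = np.asarray(scheme.thresholds, dtype=float)
    if scheme.orientation == "negative":
        # mirror onto the decreasing-threshold case
        c = -c
        x = -x
    out = np.zeros(5)
    if x >= c[0]:
        out[0] = 1.0
        return out
    if x <= c[4]:
        out[4] = 1.0
        return out
    for k in range(4):  # segment between grade k and k+1 thresholds
        if c[k + 1] < x < c[k]:
            t = (x - c[k + 1]) / (c[k] - c[k + 1])
            out[k] = t
            out[k + 1] = 1.0 - t
            return out
        if x == c[k + 1]:
            out[k + 1] = 1.0
            return out
    raise AssertionError("unreachable: thresholds are strictly monotone")


def build_R(
    values: Mapping[str, float], schemes: Mapping[str, GradeScheme]
) -> MembershipMatrix:
    """Stack per-indicator membership rows into the fuzzy evaluation
    matrix R (row order follows ``values``)."""
    rows = []
    ids = []
    for ind, x in values.items():
        if ind not in schemes:
            raise StructureError(f"no grade scheme for indicator {ind!r}")
        rows.append(membership(float(x), schemes[ind]))
        ids.append(ind)
    return MembershipMatrix(tuple(ids), np.vstack(rows))


def evaluate(weights: WeightVector, r: MembershipMatrix) -> EvaluationResult:
    """Weighted-average aggregation, max-membership grading and 5..1
    scoring.

    Grade ties resolve toward the better grade (lower index) and are
    recorded.  With weights summing to 1 the entry-wise min{1, ·} clamp is
    provably inactive.
    """
    if weights.labels != r.indicator_ids:
        raise StructureError(
            "weight labels and membership-matrix rows differ: "
            f"{weights.labels} vs {r.indicator_ids}"
        )
    raw = weights.weights @ r.values
    b = np.minimum(1.0, raw)
    clamped = bool(np.any(raw > 1.0))
    best = float(b.max())
    winners = np.flatnonzero(b >= best - 1e-12)
    grade_idx = int(winners[0])
    score = float(b @ GRADE_VALUES)
    return EvaluationResult(
        B=b,
        grade=GRADE_LABELS[grade_idx],
        score=score,
        tie=len(winners) > 1,
        clamped=clamped,
    )


def default_grade_scheme(
    table: TrialTable,
    quantile_levels: Sequence[float] = (0.9, 0.7, 0.5, 0.3, 0.1),
) -> dict[str, GradeScheme]:
    """Data-driven fallback thresholds at observed-value quantiles.

    The original grade boundaries of the source trial are not public, so
    this scheme anchors the five grades to the empirical distribution of
    each indicator: C1..C5 sit at the (0.9, 0.7, 0.5, 0.3, 0.1) quantiles,
    ordered by orientation.  Ties are broken by a tiny monotone jitter
    (with a warning).  Evaluations under this scheme are method
    demonstrations, not reproductions of the original grading.
    """
    if len(quantile_levels) != 5:
        raise SchemeError("need exactly 5 quantile levels")
    schemes: dict[str, GradeScheme] = {}
    for ind in table.indicators:
        col = table.column(ind).to_numpy(dtype=float)
        if len(np.unique(col)) < 2:
            raise SchemeError(
                f"indicator {ind!r} is constant; supply explicit grade thresholds"
            )
        q = np.quantile(col, quantile_levels)  # best-to-worst quantiles
        orientation = table.orientation(ind)
        if orientation == "negative":
            # smaller is better: best grade threshold at the low quantile
            q = np.quantile(col, [1 - l for l in quantile_levels])
        q = _enforce_strict(q, decreasing=(orientation == "positive"), label=ind)
        schemes[ind] = GradeScheme(ind, orientation, tuple(q))
    return schemes


def _enforce_strict(q: np.ndarray, decreasing: bool, label: str) -> np.ndarray:
    """Nudge tied quantile thresholds apart so the scheme is strictly
    monotone."""
    q = q.astype(float).copy()
    sign = -1.0 if decreasing else 1.0
    eps = max(1e-9, 1e-6 * (abs(q).max() or 1.0))
    adjusted = False
    for k in range(1, 5):
        if sign * (q[k] - q[k - 1]) <= 0:
            q[k] = q[k - 1] + sign * eps
            adjusted = True
    if adjusted:
        warnings.warn(
            f"grade thresholds for {label!r} had ties; applied epsilon jitter",
            stacklevel=2,
        )
    return q
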