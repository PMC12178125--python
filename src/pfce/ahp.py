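"""Analytic Hierarchy Process: subjective indicator weighting.

A reciprocal pairwise-comparison (judgment) matrix on the Saaty 1–9 scale
is reduced to a weight vector by the geometric-mean (root) method:
M_i = (∏_j b_ij)^(1/n), w_i = M_i / Σ M_i.  Consistency is checked via
λmax = mean_i (B w)_i / w_i, CI = (λmax − n)/(n − 1), CR = CI/RI with the
tabulated random index RI; CR < 0.1 passes.  Criterion and within-criterion
weights compose multiplicatively into leaf weights.

The expert matrices of the source trial are unavailable; the package ships
an illustrative default hierarchy (see :func:`default_hierarchy`) clearly
labeled as such.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, StructureError

__all__ = [
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyReport",
    "RI_TABLE",
    "validate_judgment",
    "ahp_weights",
    "lambda_max",
    "consistency",
    "hierarchy_weights",
    "aggregate_expert_matrices",
    "DEFAULT_HIERARCHY",
    "default_hierarchy",
]

#: Random consistency index by matrix order (orders 1–10).
RI_TABLE = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.9, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_SAATY_SET = {float(k) for k in range(1, 10)} | {1.0 / k for k in range(2, 10)}


@dataclass(frozen=True)
class JudgmentMatrix:
    labels: tuple[str, ...]
    entries: np.ndarray  # n x n, positive reciprocal

    @classmethod
    def from_rows(cls, labels: Sequence[str], rows: Sequence[Sequence[float]]) -> "JudgmentMatrix":
        return cls(tuple(labels), np.asarray(rows, dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "JudgmentMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise StructureError(
                f"judgment matrix in {path!r} must have identical row and column labels"
            )
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    @property
    def order(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WeightVector:
    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.labels):
            raise StructureError("labels and weights length mismatch")
        if np.any(w < 0):
            raise DataError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise DataError(f"weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_values(cls, labels: Sequence[str], values: Sequence[float]) -> "WeightVector":
        """Build from nonnegative values, normalizing to sum 1."""
        v = np.asarray(values, dtype=float)
        if np.any(v < 0):
            raise DataError("weight values must be nonnegative")
        s = v.sum()
        if s <= 0:
            raise DataError("weight values sum to zero")
        return cls(tuple(labels), v / s)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels))

    def restrict(self, labels: Sequence[str]) -> "WeightVector":
        """Renormalize over a label subset (e.g. when some indicators are
        unavailable in the data)."""
        idx = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in idx]
        if missing:
            raise StructureError(f"labels not in weight vector: {missing}")
        sub = np.array([self.weights[idx[l]] for l in labels])
        if sub.sum() <= 0:
            raise DataError("restricted weights sum to zero")
        return WeightVector(tuple(labels), sub / sub.sum())


@dataclass(frozen=True)
class ConsistencyReport:
    label: str
    order: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passes: bool


def validate_judgment(matrix: JudgmentMatrix, rel_tol: float = 1e-9) -> JudgmentMatrix:
    """Check positivity, unit diagonal and reciprocity; warn (not error) on
    entries outside the Saaty {1..9, 1/2..1/9} scale."""
    a = matrix.entries
    n = matrix.order
    if a.shape != (n, n):
        raise StructureError(
            f"judgment matrix must be {n}x{n} to match its labels, got {a.shape}"
        )
    if n < 1:
        raise StructureError("judgment matrix must have order >= 1")
    off_scale = []
    for i in range(n):
        if abs(a[i, i] - 1.0) > rel_tol:
            raise DataError(
                f"diagonal entry ({matrix.labels[i]}, {matrix.labels[i]}) must be 1, got {a[i, i]}"
            )
        for j in range(n):
            if a[i, j] <= 0:
                raise DataError(
                    f"entry ({matrix.labels[i]}, {matrix.labels[j]}) must be positive, got {a[i, j]}"
                )
            if j > i:
                if abs(a[j, i] * a[i, j] - 1.0) > rel_tol * max(1.0, a[i, j] * a[j, i]):
                    raise DataError(
                        f"entries ({matrix.labels[i]}, {matrix.labels[j]})={a[i, j]} and "
                        f"({matrix.labels[j]}, {matrix.labels[i]})={a[j, i]} are not reciprocal"
                    )
                if not any(math.isclose(a[i, j], s, rel_tol=1e-6) for s in _SAATY_SET):
                    off_scale.append((matrix.labels[i], matrix.labels[j], a[i, j]))
    if off_scale:
        warnings.warn(
            f"judgment entries outside the 1-9 scale: {off_scale}", stacklevel=2
        )
    return matrix


def ahp_weights(matrix: JudgmentMatrix) -> WeightVector:
    """Geometric-mean (root) method weights."""
    validate_judgment(matrix)
    # n-th root of row products, computed in log space for stability
    m = np.exp(np.log(matrix.entries).mean(axis=1))
    return WeightVector(matrix.labels, m / m.sum())


def lambda_max(matrix: JudgmentMatrix, weights: WeightVector) -> float:
    """λmax = mean over rows of (B w)_i / w_i."""
    if matrix.labels != weights.labels:
        raise StructureError("matrix and weight labels differ")
    w = weights.weights
    if np.any(w == 0):
        raise DataError("lambda_max undefined with zero weights")
    lam = (matrix.entries @ w) / w
    return float(lam.mean())


def consistency(matrix: JudgmentMatrix, label: str = "") -> ConsistencyReport:
    """CI/CR consistency check against the tabulated random index.

    Orders 1–2 are always consistent (RI = 0): CR is defined as 0.
    """
    n = matrix.order
    if n > max(RI_TABLE):
        raise StructureError(
            f"consistency check supports order <= {max(RI_TABLE)}, got {n}"
        )
    w = ahp_weights(matrix)
    lam = lambda_max(matrix, w) if n >= 1 else 1.0
    ci = 0.0 if n < 2 else (lam - n) / (n - 1)
    ri = RI_TABLE[n]
    cr = 0.0 if ri == 0.0 else ci / ri
    return ConsistencyReport(
        label=label or "+".join(matrix.labels),
        order=n,
        lambda_max=lam,
        ci=ci,
        ri=ri,
        cr=cr,
        passes=cr < 0.1,
    )


def hierarchy_weights(
    criteria: WeightVector, sub_weights: Mapping[str, WeightVector]
) -> WeightVector:
    """Compose criterion weights with within-criterion weights into leaf
    weights (criterion weight × within-criterion weight), flattened in
    criteria order."""
    orphan_subs = [c for c in sub_weights if c not in criteria.labels]
    if orphan_subs:
        raise StructureError(f"sub-weights for unknown criteria: {orphan_subs}")
    missing = [c for c in criteria.labels if c not in sub_weights]
    if missing:
        raise StructureError(f"criteria without sub-weights: {missing}")
    labels: list[str] = []
    values: list[float] = []
    for c, cw in zip(criteria.labels, criteria.weights):
        sub = sub_weights[c]
        dup = [l for l in sub.labels if l in labels]
        if dup:
            raise StructureError(f"leaf indicators appear under two criteria: {dup}")
        labels.extend(sub.labels)
        values.extend(cw * sub.weights)
    return WeightVector.from_values(labels, values)


def aggregate_expert_matrices(matrices: Sequence[JudgmentMatrix]) -> JudgmentMatrix:
    """Merge several experts' judgments by element-wise geometric mean (the
    standard aggregation that preserves reciprocity).  Optional extension;
    the source trial does not state its merging rule."""
    if not matrices:
        raise StructureError("no matrices to aggregate")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise StructureError("expert matrices must share labels")
    stack = np.stack([m.entries for m in matrices])
    agg = np.exp(np.log(stack).mean(axis=0))
    return JudgmentMatrix(labels, agg)


# ---------------------------------------------------------------------------
# Illustrative default hierarchy.  The original expert matrices are not
# public; these defaults are internally consistent (CR < 0.1) examples that
# weight economic benefit highest, then water/fertilizer efficiency, then
# quality, then environmental benefit.
# ---------------------------------------------------------------------------

DEFAULT_HIERARCHY: dict[str, list[str]] = {
    "Z1": ["Z11", "Z12"],  # economic benefit: yield, net income
    "Z2": ["Z21", "Z22", "Z23"],  # quality: starch, vitamin C, reducing sugar
    "Z3": ["Z31", "Z32"],  # water & fertilizer use efficiency: WUE, PFP
    "Z4": ["Z41", "Z42", "Z43"],  # environmental benefit: soil residues
}


def default_hierarchy(
    equal_criteria: bool = False,
) -> tuple[JudgmentMatrix, dict[str, JudgmentMatrix]]:
    """Default (illustrative, non-elicited) judgment matrices for the
    four-criterion, ten-indicator hierarchy.

    ``equal_criteria=True`` replaces the criteria matrix with all-ones
    (equal criterion weights), useful for neutral synthetic experiments.
    """
    if equal_criteria:
        criteria = JudgmentMatrix.from_rows(
            list(DEFAULT_HIERARCHY), np.ones((4, 4)).tolist()
        )
    else:
        criteria = JudgmentMatrix.from_rows(
            list(DEFAULT_HIERARCHY),
            [
                [1, 3, 2, 4],
                [1 / 3, 1, 1 / 2, 2],
                [1 / 2, 2, 1, 3],
                [1 / 4, 1 / 2, 1 / 3, 1],
            ],
        )
    subs = {
        "Z1": JudgmentMatrix.from_rows(["Z11", "Z12"], [[1, 1 / 2], [2, 1]]),
        "Z2": JudgmentMatrix.from_rows(
            ["Z21", "Z22", "Z23"], [[1, 2, 2], [1 / 2, 1, 1], [1 / 2, 1, 1]]
        ),
        "Z3": JudgmentMatrix.from_rows(["Z31", "Z32"], [[1, 1], [1, 1]]),
        "Z4": JudgmentMatrix.from_rows(
            ["Z41", "Z42", "Z43"], [[1, 1, 1], [1, 1, 1], [1, 1, 1]]
        ),
    }
    return criteria, subs
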