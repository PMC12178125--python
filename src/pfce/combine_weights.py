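"""Least-squares fusion of subjective (AHP) and objective (entropy) weights.

The combined vector is W = α1·W1 + α2·W2 with α1 + α2 = 1.  α solves the
deviation-minimizing 2×2 Gram system

    [[W1ᵀW1, W1ᵀW2], [W2ᵀW1, W2ᵀW2]] · α = [W1ᵀW1, W2ᵀW2],

normalized to sum 1.  The system is singular when W1 = W2, and the raw
solution can leave [0, 1]; both cases are handled by an explicit policy
(default: fall back to α = (0.5, 0.5), recorded in the result).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ahp import WeightVector
from .exceptions import StructureError

__all__ = ["CombinationResult", "combine"]

NegativeAlphaPolicy = Literal["fallback_equal", "absolute_normalize"]


@dataclass(frozen=True)
class CombinationResult:
    alpha: tuple[float, float]
    combined: WeightVector
    method_note: str  # "raw" | "normalized" | "fallback"


def combine(
    w1: WeightVector,
    w2: WeightVector,
    negative_alpha_policy: NegativeAlphaPolicy = "fallback_equal",
) -> CombinationResult:
    """Combine two weight vectors over identical labels.

    method_note: "raw" if the Gram solution already summed to 1, and was
    nonnegative, "normalized" if it needed sum-normalization (or the
    absolute-value policy), "fallback" if equal coefficients were imposed.
    """
    if w1.labels != w2.labels:
        raise StructureError("weight vectors must share labels and order")
    v1, v2 = w1.weights, w2.weights
    gram = np.array([[v1 @ v1, v1 @ v2], [v2 @ v1, v2 @ v2]])
    rhs = np.array([v1 @ v1, v2 @ v2])

    note = "raw"
    alpha: np.ndarray
    # Singular Gram system iff W1 and W2 are collinear (equal, for two
    # probability vectors).
    if np.linalg.matrix_rank(gram, tol=1e-12) < 2:
        alpha = np.array([0.5, 0.5])
        note = "fallback"
    else:
        raw = np.linalg.solve(gram, rhs)
        s = raw.sum()
        if abs(s) < 1e-12:
            alpha = np.array([0.5, 0.5])
            note = "fallback"
        else:
            alpha = raw / s
            if abs(s - 1.0) > 1e-9:
                note = "normalized"
            if np.any(alpha < 0):
                if negative_alpha_policy == "absolute_normalize":
                    alpha = np.abs(alpha) / np.abs(alpha).sum()
                    note = "normalized"
                else:
                    alpha = np.array([0.5, 0.5])
                    note = "fallback"
    combined = WeightVector.from_values(w1.labels, alpha[0] * v1 + alpha[1] * v2)
    return CombinationResult(alpha=(float(alpha[0]), float(alpha[1])), combined=combined, method_note=note)
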