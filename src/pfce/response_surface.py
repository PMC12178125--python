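"""Quadratic response surface of comprehensive score on (temperature, rate).

The factorial design gives one comprehensive score per treatment; a full
quadratic f(T, C) = β0 + βT·T + βC·C + βTT·T² + βCC·C² + βTC·T·C is fitted
by ordinary least squares (internally on centered/scaled coordinates for
conditioning, with coefficients reported in raw units) and maximized over
the rectangle of factor levels.  The maximizer is found analytically
(interior stationary point when the Hessian is negative definite, else the
best of edge-restricted 1-D maxima and corners) and cross-checked against
a dense grid.  A recommendation band reports the bounding box of the
near-optimal region (predicted score within 1% of the maximum), matching
how scheme recommendations are stated as ranges in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import FitError

__all__ = ["SurfaceFit", "OptimumScheme", "fit_quadratic", "optimize", "recommendation_band"]

_TERMS = ("1", "T", "C", "T^2", "C^2", "T*C")


@dataclass(frozen=True)
class SurfaceFit:
    """Fitted quadratic surface in raw units.

    coefficients = (β0, βT, βC, βTT, βCC, βTC).
    """

    coefficients: tuple[float, float, float, float, float, float]
    r_squared: float
    n_points: int
    bounds: tuple[tuple[float, float], tuple[float, float]]  # (T range, C range)

    def predict(self, t: np.ndarray | float, c: np.ndarray | float) -> np.ndarray | float:
        b0, bt, bc, btt, bcc, btc = self.coefficients
        return b0 + bt * t + bc * c + btt * t**2 + bcc * c**2 + btc * t * c


@dataclass(frozen=True)
class OptimumScheme:
    temperature: float
    rate: float
    predicted_score: float
    at_boundary: tuple[bool, bool]  # (T at a bound, C at a bound)


def fit_quadratic(
    points: Sequence[tuple[float, float, float]],
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> SurfaceFit:
    """OLS fit of a full quadratic to (T, C, score) points.

    Requires >= 6 points and a full-rank design; constant scores leave R²
    undefined and raise.  Default bounds are the observed (T, C) ranges.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FitError("points must be (T, C, score) triples")
    n = pts.shape[0]
    if n < 6:
        raise FitError(f"a full quadratic needs >= 6 points, got {n}")
    t_raw, c_raw, y = pts[:, 0], pts[:, 1], pts[:, 2]

    # center/scale for conditioning; guard zero spread
    mt, mc = t_raw.mean(), c_raw.mean()
    st = t_raw.std() or 1.0
    sc = c_raw.std() or 1.0
    t = (t_raw - mt) / st
    c = (c_raw - mc) / sc
    x = np.column_stack([np.ones(n), t, c, t**2, c**2, t * c])

    rank = np.linalg.matrix_rank(x)
    if rank < 6:
        collinear = _collinear_terms(x)
        raise FitError(
            f"design matrix is rank-deficient (rank {rank} < 6); "
            f"collinear terms: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise FitError("scores are constant; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot

    a0, a1, a2, a3, a4, a5 = beta
    # back-transform scaled-coordinate coefficients to raw (T, C) units
    btt = a3 / st**2
    bcc = a4 / sc**2
    btc = a5 / (st * sc)
    bt = a1 / st - 2 * a3 * mt / st**2 - a5 * mc / (st * sc)
    bc = a2 / sc - 2 * a4 * mc / sc**2 - a5 * mt / (st * sc)
    b0 = (
        a0
        - a1 * mt / st
        - a2 * mc / sc
        + a3 * mt**2 / st**2
        + a4 * mc**2 / sc**2
        + a5 * mt * mc / (st * sc)
    )
    if bounds is None:
        bounds = ((float(t_raw.min()), float(t_raw.max())), (float(c_raw.min()), float(c_raw.max())))
    return SurfaceFit(
        coefficients=(float(b0), float(bt), float(bc), float(btt), float(bcc), float(btc)),
        r_squared=float(r2),
        n_points=n,
        bounds=bounds,
    )


def _collinear_terms(x: np.ndarray) -> list[str]:
    names = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ coef
        scale = np.linalg.norm(x[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-8:
            names.append(_TERMS[j])
    return names or ["<undetermined>"]


def optimize(fit: SurfaceFit, grid: int = 201) -> OptimumScheme:
    """Maximize the fitted surface over its rectangular bounds.

    Candidates: the interior stationary point (if the Hessian is negative
    definite and the point is in bounds), the four edge-restricted 1-D
    quadratic maxima, and the corners; the winner is verified against a
    dense grid evaluation (and replaced by the grid point if the analytic
    search somehow missed, which would indicate a degenerate surface).
    """
    (t_lo, t_hi), (c_lo, c_hi) = fit.bounds
    _, bt, bc, btt, bcc, btc = fit.coefficients
    candidates: list[tuple[float, float]] = [
        (t_lo, c_lo),
        (t_lo, c_hi),
        (t_hi, c_lo),
        (t_hi, c_hi),
    ]

    # interior stationary point: solve grad f = 0
    hessian = np.array([[2 * btt, btc], [btc, 2 * bcc]])
    eigvals = np.linalg.eigvalsh(hessian)
    if np.all(eigvals < 0):  # strictly concave -> unique stationary max
        try:
            t0, c0 = np.linalg.solve(hessian, [-bt, -bc])
        except np.linalg.LinAlgError:
            t0, c0 = np.nan, np.nan
        if t_lo <= t0 <= t_hi and c_lo <= c0 <= c_hi:
            candidates.append((float(t0), float(c0)))

    # edge restrictions: 1-D quadratics along each side
    for t_fixed in (t_lo, t_hi):
        c_star = _quad_1d_argmax(bcc, bc + btc * t_fixed, c_lo, c_hi)
        candidates.append((t_fixed, c_star))
    for c_fixed in (c_lo, c_hi):
        t_star = _quad_1d_argmax(btt, bt + btc * c_fixed, t_lo, t_hi)
        candidates.append((t_star, c_fixed))

    scores = [float(fit.predict(t, c)) for t, c in candidates]
    best_idx = int(np.argmax(scores))
    t_best, c_best = candidates[best_idx]
    best_score = scores[best_idx]

    # dense-grid verification
    tg = np.linspace(t_lo, t_hi, grid)
    cg = np.linspace(c_lo, c_hi, grid)
    tt, cc = np.meshgrid(tg, cg, indexing="ij")
    zz = fit.predict(tt, cc)
    gi = np.unravel_index(int(np.argmax(zz)), zz.shape)
    if float(zz[gi]) > best_score + 1e-9:
        t_best, c_best = float(tt[gi]), float(cc[gi])
        best_score = float(zz[gi])

    edge_tol_t = 1e-9 * max(1.0, abs(t_hi - t_lo))
    edge_tol_c = 1e-9 * max(1.0, abs(c_hi - c_lo))
    return OptimumScheme(
        temperature=float(t_best),
        rate=float(c_best),
        predicted_score=float(best_score),
        at_boundary=(
            min(abs(t_best - t_lo), abs(t_best - t_hi)) <= edge_tol_t,
            min(abs(c_best - c_lo), abs(c_best - c_hi)) <= edge_tol_c,
        ),
    )


def _quad_1d_argmax(a2: float, a1: float, lo: float, hi: float) -> float:
    """argmax of a2·x² + a1·x (+ const) on [lo, hi]."""
    candidates = [lo, hi]
    if a2 < 0:
        x0 = -a1 / (2 * a2)
        if lo <= x0 <= hi:
            candidates.append(x0)
    vals = [a2 * x**2 + a1 * x for x in candidates]
    return float(candidates[int(np.argmax(vals))])


def recommendation_band(
    fit: SurfaceFit, fraction: float = 0.01, grid: int = 201
) -> dict[str, tuple[float, float]]:
    """Bounding box of the near-optimal region.

    Returns the (T, C) ranges of grid points whose predicted score is
    within ``fraction`` of the maximum (relative for positive maxima,
    absolute-magnitude otherwise) — the scheme recommendation stated as a
    range rather than a point.
    """
    (t_lo, t_hi), (c_lo, c_hi) = fit.bounds
    tg = np.linspace(t_lo, t_hi, grid)
    cg = np.linspace(c_lo, c_hi, grid)
    tt, cc = np.meshgrid(tg, cg, indexing="ij")
    zz = np.asarray(fit.predict(tt, cc))
    zmax = zz.max()
    threshold = zmax - fraction * abs(zmax) if zmax != 0 else zmax - fraction
    mask = zz >= threshold
    return {
        "temperature": (float(tt[mask].min()), float(tt[mask].max())),
        "rate": (float(cc[mask].min()), float(cc[mask].max())),
    }
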