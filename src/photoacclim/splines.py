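"""Natural cubic regression spline basis with a curvature penalty.

The basis is parametrized by the function values at k knots (a "cardinal"
natural cubic spline), with the penalty matrix S such that beta' S beta
equals the integrated squared second derivative of the interpolating natural
spline.  Construction follows the standard banded formulation: with knot
gaps h_j, tridiagonal B ((k-2)x(k-2)) and banded D ((k-2)xk),

    B_ii = (h_i + h_{i+1})/3,  B_{i,i+1} = h_{i+1}/6
    D_{i,i} = 1/h_i,  D_{i,i+1} = -1/h_i - 1/h_{i+1},  D_{i,i+2} = 1/h_{i+1}

the knot second derivatives are delta = B^{-1} D beta (zero at the boundary
knots) and S = D' B^{-1} D.  The penalty null space is exactly the straight
lines, for any knot placement, so linear signals are never shrunk.
Evaluation outside the knot range extends linearly (natural boundary).
"""

from __future__ import annotations

import numpy as np

__all__ = ["cr_knots", "cr_design", "cr_penalty"]


def cr_knots(x, k: int) -> np.ndarray:
    """Knots at quantiles of the unique covariate values (at most k of them)."""
    uniq = np.unique(np.asarray(x, dtype=float))
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct covariate values for a spline")
    k = min(k, uniq.size)
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
    return np.unique(knots)


def _bands(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = knots.size
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    return B, D


def cr_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated-squared-second-derivative penalty matrix (k x k)."""
    B, D = _bands(knots)
    S = D.T @ np.linalg.solve(B, D)
    return (S + S.T) / 2.0


def cr_design(x, knots: np.ndarray) -> np.ndarray:
    """Design matrix mapping knot values beta to spline evaluations at x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = knots.size
    h = np.diff(knots)
    B, D = _bands(knots)
    # rows of F give knot second derivatives as linear maps of beta
    F = np.zeros((k, k))
    F[1:-1, :] = np.linalg.solve(B, D)
    X = np.zeros((x.size, k))

    inside = (x >= knots[0]) & (x <= knots[-1])
    xi = x[inside]
    j = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, k - 2)
    hj = h[j]
    xr = knots[j + 1] - xi
    xl = xi - knots[j]
    a_m, a_p = xr / hj, xl / hj
    c_m = (xr**3 / hj - hj * xr) / 6.0
    c_p = (xl**3 / hj - hj * xl) / 6.0
    rows = np.where(inside)[0]
    for r, jj, am, ap, cm, cp in zip(rows, j, a_m, a_p, c_m, c_p):
        X[r, jj] += am
        X[r, jj + 1] += ap
        X[r, :] += cm * F[jj] + cp * F[jj + 1]

    # natural linear extrapolation beyond the boundary knots
    left = x < knots[0]
    if np.any(left):
        d_row = np.zeros(k)
        d_row[0], d_row[1] = -1.0 / h[0], 1.0 / h[0]
        d_row -= (h[0] / 6.0) * F[1]
        base = np.zeros(k)
        base[0] = 1.0
        for r in np.where(left)[0]:
            X[r, :] = base + (x[r] - knots[0]) * d_row
    right = x > knots[-1]
    if np.any(right):
        d_row = np.zeros(k)
        d_row[-2], d_row[-1] = -1.0 / h[-1], 1.0 / h[-1]
        d_row += (h[-1] / 6.0) * F[-2]
        base = np.zeros(k)
        base[-1] = 1.0
        for r in np.where(right)[0]:
            X[r, :] = base + (x[r] - knots[-1]) * d_row
    return X
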