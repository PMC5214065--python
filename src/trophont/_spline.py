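"""Natural cubic regression spline in value-at-knot parameterization.

The spline is parameterized by its values ``delta`` at the knots; second
derivatives ``gamma`` at interior knots follow from the natural-spline
banded system ``B gamma = D delta``, and the curvature penalty is

    integral f''(x)^2 dx = delta' D' B^{-1} D delta.

This is the classical Green & Silverman construction underlying the 'cr'
basis of penalized-regression software.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve as lin_solve

from .exceptions import ValidationError


def choose_knots(x: np.ndarray, k: int) -> np.ndarray:
    """k knots at evenly spaced quantiles of the covariate."""
    if k < 3:
        raise ValidationError("need at least 3 knots for a cubic spline")
    knots = np.quantile(np.asarray(x, float), np.linspace(0.0, 1.0, k))
    if np.any(np.diff(knots) <= 0):
        raise ValidationError(
            "covariate quantiles are not distinct; covariate (nearly) constant"
        )
    return knots


def penalty_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (F_full, S): gamma = F_full @ delta (with zero end rows) and
    the curvature penalty S = D' B^{-1} D."""
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = lin_solve(B, D, assume_a="pos")
    F_full = np.zeros((k, k))
    F_full[1:-1] = F
    S = D.T @ F
    S = 0.5 * (S + S.T)  # symmetrize against round-off
    return F_full, S


def basis(x: np.ndarray, knots: np.ndarray, F_full: np.ndarray) -> np.ndarray:
    """Evaluate the k basis functions (columns) at points x.

    Points must lie within [knots[0], knots[-1]] up to a small tolerance.
    """
    x = np.asarray(x, dtype=float)
    k = len(knots)
    span = knots[-1] - knots[0]
    tol = 1e-8 * max(span, 1.0)
    if np.any(x < knots[0] - tol) or np.any(x > knots[-1] + tol):
        raise ValidationError("prediction points outside the fitted covariate range")
    xc = np.clip(x, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    h = np.diff(knots)[idx]
    t_minus = knots[idx + 1] - xc  # distance to right knot
    t_plus = xc - knots[idx]       # distance to left knot

    N = np.zeros((x.size, k))
    rows = np.arange(x.size)
    N[rows, idx] += t_minus / h
    N[rows, idx + 1] += t_plus / h
    w = -(t_minus * t_plus) / 6.0
    N += (w * (1.0 + t_minus / h))[:, None] * F_full[idx]
    N += (w * (1.0 + t_plus / h))[:, None] * F_full[idx + 1]
    return N
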