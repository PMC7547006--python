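"""Penalized-regression-spline bases.

Cubic B-spline bases on equally spaced knots, cyclic (periodic) bases for
day-of-year, and row-wise tensor products of marginal bases.  Wiggliness
penalties are the exact integrated squared second derivative of the
represented function, computed by Gauss-Legendre quadrature (exact for the
piecewise-polynomial integrand), so the penalty null space is exactly the
straight lines (constants, for the cyclic basis).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "cubic_knots",
    "cubic_design",
    "cubic_penalty",
    "cyclic_design",
    "cyclic_penalty",
    "row_kron",
    "sum_to_zero",
    "DOY_PERIOD",
    "doy_phase",
]

#: Day-of-year wraps so that doy 366 coincides with doy 1.
DOY_PERIOD = 365.0


def doy_phase(doy) -> np.ndarray:
    """Map day-of-year to the cyclic phase in [0, 365): (doy - 1) mod 365."""
    return np.mod(np.asarray(doy, dtype=float) - 1.0, DOY_PERIOD)


# ---------------------------------------------------------------------------
# cubic basis


def cubic_knots(lo: float, hi: float, k: int) -> np.ndarray:
    """Equally spaced cubic B-spline knot vector giving k basis functions on
    [lo, hi] (k - 3 interior intervals, 3 exterior knots each side)."""
    if k < 4:
        raise ValueError("cubic basis needs k >= 4")
    if not hi > lo:
        raise ValueError("need hi > lo for the basis range")
    h = (hi - lo) / (k - 3)
    return lo + h * np.arange(-3, k + 1)


def _bspline_eval(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    nb = len(knots) - 4
    if deriv == 0:
        return BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    spl = BSpline(knots, np.eye(nb), 3, extrapolate=False)
    return spl.derivative(deriv)(x)


def cubic_design(x, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = knots[3], knots[-4]
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("x outside the basis range; clamp before evaluating")
    return _bspline_eval(np.clip(x, lo, hi), knots, deriv)


def _quadrature(knots_inner: np.ndarray, npts: int = 4):
    """Gauss-Legendre nodes/weights on each inter-knot interval."""
    gx, gw = np.polynomial.legendre.leggauss(npts)
    a = knots_inner[:-1]
    b = knots_inner[1:]
    mid = (a + b) / 2
    half = (b - a) / 2
    pts = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    wts = (half[:, None] * gw[None, :]).ravel()
    return pts, wts


def cubic_penalty(knots: np.ndarray) -> np.ndarray:
    """S with quadratic form beta' S beta = integral of f''(x)^2 over the
    basis range (exact: the integrand is piecewise quadratic)."""
    pts, wts = _quadrature(knots[3:-3])
    D2 = _bspline_eval(pts, knots, deriv=2)
    return D2.T @ (wts[:, None] * D2)


# ---------------------------------------------------------------------------
# cyclic basis


def _cyclic_ext_knots(k: int, period: float) -> np.ndarray:
    h = period / k
    return h * np.arange(-3, k + 4)


def cyclic_design(phase, k: int, period: float = DOY_PERIOD, deriv: int = 0):
    """Periodic cubic B-spline design with k basis functions.

    Built by folding an extended basis: the value and the first two
    derivatives are continuous across the wrap point by construction.
    """
    if k < 4:
        raise ValueError("cyclic basis needs k >= 4")
    phase = np.mod(np.asarray(phase, dtype=float), period)
    t = _cyclic_ext_knots(k, period)
    B = _bspline_eval(phase, t, deriv)  # (n, k + 3)
    C = np.zeros((B.shape[0], k))
    for j in range(k + 3):
        C[:, j % k] += B[:, j]
    return C


def cyclic_penalty(k: int, period: float = DOY_PERIOD) -> np.ndarray:
    """Exact integrated squared second derivative over one period of the
    folded (periodic) basis."""
    h = period / k
    pts, wts = _quadrature(h * np.arange(0, k + 1))
    D2 = cyclic_design(pts, k, period, deriv=2)
    return D2.T @ (wts[:, None] * D2)


# ---------------------------------------------------------------------------
# tensors and constraints


def row_kron(*mats: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product of marginal designs."""
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, :, None] * m[:, None, :]).reshape(out.shape[0], -1)
    return out


def sum_to_zero(X: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the sum-to-zero constraint 1'Xb = 0.

    Returns Z with shape (k, k-1); the constrained design is X @ Z and a
    penalty S becomes Z' S Z.
    """
    c = X.mean(axis=0)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        return np.eye(X.shape[1])[:, 1:]
    # Householder reflection sending c to a multiple of e1; columns 2..k of
    # the reflector span the null space of c'.
    v = c / nc
    e1 = np.zeros_like(v)
    e1[0] = 1.0
    u = v - e1
    un = np.linalg.norm(u)
    if un < 1e-12:
        return np.eye(len(c))[:, 1:]
    u /= un
    Q = np.eye(len(c)) - 2.0 * np.outer(u, u)
    return Q[:, 1:]
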