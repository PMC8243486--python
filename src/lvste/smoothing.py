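"""Cubic smoothing splines on regular grids (Reinsch / de Boor algorithm).

``smooth1d`` minimizes  p * sum_i (y_i - f(x_i))^2 + (1 - p) * int f''(x)^2 dx
over natural cubic splines and returns the fitted values at the sites; the
2D version applies the 1D smoother along each grid axis in turn (tensor
product), matching the behaviour of gridded-data smoothing-spline toolboxes.

The balance of the two terms depends on the units of the sites.  Throughout
the displacement pipeline sites are expressed in meters, for which the
regularization coefficients p = 1 - 10^-6.5 (estimates) and p = 1 - 10^-9
(reference) correspond to centimeter- and millimeter-scale smoothing
respectively.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solveh_banded

ESTIMATE_P = 1.0 - 10.0 ** -6.5
REFERENCE_P = 1.0 - 10.0 ** -9.0


def smooth1d(y: np.ndarray, p: float, spacing: float, axis: int = 0) -> np.ndarray:
    """Smoothing-spline fit of uniformly sampled data along ``axis``.

    NaNs are not allowed; columns are smoothed independently.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    y = np.asarray(y, dtype=float)
    if p == 1.0:
        return y.copy()
    y = np.moveaxis(y, axis, 0)
    n = y.shape[0]
    if n < 3:
        return np.moveaxis(y.copy(), 0, axis)
    shape = y.shape
    flat = y.reshape(n, -1)
    h = float(spacing)
    # R (tridiagonal) and Q^T Q (pentadiagonal) for uniform spacing
    m = n - 2
    main_r = np.full(m, 4.0 * h / 3.0)
    off_r = np.full(m - 1, h / 3.0)
    q2 = 1.0 / h
    # Q^T Q rows: [1, -4, 6, -4, 1] / h^2 pattern
    main_q = np.full(m, 6.0 * q2 * q2)
    off1_q = np.full(m - 1, -4.0 * q2 * q2)
    off2_q = np.full(max(m - 2, 0), 1.0 * q2 * q2)
    lam = 6.0 * (1.0 - p)
    ab = np.zeros((3, m))
    ab[2, :] = lam * main_q + p * main_r
    ab[1, 1:] = lam * off1_q + p * off_r
    if m > 2:
        ab[0, 2:] = lam * off2_q
    # Q^T y  (second differences / h)
    qty = (flat[:-2] - 2.0 * flat[1:-1] + flat[2:]) / h
    u = solveh_banded(ab, qty, lower=False)
    # a = y - 6 (1 - p) Q u
    qu = np.zeros_like(flat)
    qu[:-2] += u / h
    qu[1:-1] += -2.0 * u / h
    qu[2:] += u / h
    out = flat - lam * qu
    return np.moveaxis(out.reshape(shape), 0, axis)


def smooth_grid(z: np.ndarray, p: float, spacing: float | tuple[float, float]
                ) -> np.ndarray:
    """Tensor-product smoothing of a 2D grid (rows then columns)."""
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    out = smooth1d(z, p, spacing[0], axis=0)
    return smooth1d(out, p, spacing[1], axis=1)
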