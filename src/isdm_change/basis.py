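"""Low-rank 2-D spline basis for the residual spatial field.

The latent intensity carries a smooth spatial term B @ g that absorbs
missing covariates and residual spatial autocorrelation. B is a
tensor-product B-spline basis over the projected cell coordinates with
knots on a square lattice; columns are centred so the field is
identifiable next to the intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def _design_1d(x: np.ndarray, m: int) -> np.ndarray:
    """Clamped B-spline design matrix with exactly m basis functions."""
    degree = min(3, m - 1)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, m - degree + 1)[1:-1]
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def spline_basis(centroids: np.ndarray, K: int) -> np.ndarray:
    """Tensor-product B-spline basis at cell centroids, centred columns.

    Marginal bases have ceil(sqrt(K)) functions per axis (cubic where
    possible); tensor columns are ordered low-order first (by the sum of
    marginal indices) and the first K are returned, so the matrix is
    exactly (n_cells, K). With K >= 16 the span contains every bilinear
    surface exactly.

    Parameters
    ----------
    centroids : (n, 2) projected coordinates in km.
    K : basis dimension, 4 <= K <= n.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if K < 4:
        raise ValueError("spline basis needs K >= 4")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of cells ({n})")
    m = int(np.ceil(np.sqrt(K)))
    Bx = _design_1d(centroids[:, 0], m)
    By = _design_1d(centroids[:, 1], m)
    order = sorted(((i + j, i, j) for i in range(m) for j in range(m)))
    cols = [Bx[:, i] * By[:, j] for (_, i, j) in order[:K]]
    B = np.column_stack(cols)
    return B - B.mean(axis=0)
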