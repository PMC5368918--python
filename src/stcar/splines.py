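"""Natural cubic spline bases for nonlinear covariate effects.

Deprivation covariates enter the disease model through a natural cubic
spline with a small number of degrees of freedom (default 3), allowing a
smooth nonlinear risk relationship while remaining linear beyond the
boundary knots (the "natural" constraint), which tames extrapolation.

The basis follows the classic construction used by R's ``splines::ns``:
with knots k_1 < ... < k_m (boundary knots included, m = df + 1, internal
knots at quantiles of the data), define

    d_j(x) = [ (x - k_j)_+^3 - (x - k_m)_+^3 ] / (k_m - k_j)

and take the df columns {x, d_1 - d_{m-1}, ..., d_{m-2} - d_{m-1}}.  Every
column has zero second derivative outside [k_1, k_m], and x itself is in
the span, so any linear function is reproduced exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_cubic_spline_basis"]


def _pos_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 3


def natural_cubic_spline_basis(
    x: np.ndarray,
    df: int = 3,
    knots: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a natural cubic spline basis with ``df`` columns.

    Parameters
    ----------
    x : array_like, shape (n,)
    df : int >= 1
        Number of basis columns (excluding any intercept).  df = 1 gives
        the linear basis [x].
    knots : optional, shape (df + 1,)
        Full strictly increasing knot sequence (boundary knots first and
        last).  By default the boundary knots are min(x), max(x) and the
        df - 1 internal knots sit at the corresponding quantiles of x.

    Returns
    -------
    basis : ndarray, shape (n, df)
    knots : ndarray, shape (df + 1,)
        The knot sequence used (pass back in to evaluate on new data).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        distinct = np.unique(x)
        if distinct.size < df + 1:
            raise ValueError(
                f"need at least df + 1 = {df + 1} distinct values, got {distinct.size}"
            )
        probs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(x, probs)
    knots = np.asarray(knots, dtype=float).reshape(-1)
    if knots.size != df + 1:
        raise ValueError(f"expected {df + 1} knots, got {knots.size}")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (ties in quantiles?)")

    cols = [x]
    if df >= 2:
        k_last = knots[-1]
        tail = _pos_cube(x - k_last)

        def d(j: int) -> np.ndarray:
            return (_pos_cube(x - knots[j]) - tail) / (k_last - knots[j])

        d_pen = d(df - 1)  # d_{m-1}
        for j in range(df - 1):
            cols.append(d(j) - d_pen)
    return np.column_stack(cols), knots
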