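"""Least-squares helpers shared by the scan and variance modules.

All model fits in this package reduce to ordinary least squares on small
dense design matrices (a few hundred rows, tens of columns).  The helpers
here centralise residual-sum-of-squares computation, nested F tests and
orthonormal-basis updates so every caller treats rank deficiency and
degenerate designs the same way.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Relative tolerance used when deciding that a column adds no information
# beyond the current model (rank / collinearity decisions).
RCOND = 1e-9


def ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Fit ``y ~ X`` by least squares.

    Returns ``(rss, rank, coef)`` where ``coef`` is the minimum-norm
    solution.  ``rss`` is computed from the residual vector directly so it
    is valid for rank-deficient designs too.
    """
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=RCOND)
    resid = y - X @ coef
    return float(resid @ resid), int(rank), coef


def f_test_nested(rss_red: float, rss_full: float, df_num: int,
                  df_resid: int) -> tuple[float, float]:
    """F test of a full model against a nested reduced model.

    Returns ``(F, p)``.  Degenerate cases (no residual degrees of freedom,
    or a numerically zero full-model RSS) yield ``p`` clipped into (0, 1].
    """
    if df_resid < 1 or df_num < 1:
        return np.nan, 1.0
    diff = max(rss_red - rss_full, 0.0)
    if rss_full <= 0.0:
        # Saturated full model: infinite F unless the reduction is also zero.
        if diff <= 0.0:
            return 0.0, 1.0
        return np.inf, np.nextafter(0.0, 1.0)
    fstat = (diff / df_num) / (rss_full / df_resid)
    p = float(stats.f.sf(fstat, df_num, df_resid))
    return float(fstat), max(p, np.nextafter(0.0, 1.0))


def orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of ``X`` (drops null columns)."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > RCOND * max(1.0, np.abs(r).max())
    return q[:, keep]


def residualize(Q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Residual of ``v`` (vector or matrix of columns) against basis ``Q``."""
    if Q.shape[1] == 0:
        return v.copy()
    return v - Q @ (Q.T @ v)


def family_design(families: np.ndarray) -> tuple[np.ndarray, list]:
    """Family incidence matrix X_f (one column per family, rows sum to 1).

    The family columns span the intercept, so models built on top of this
    design never add a separate constant column.
    """
    levels = list(dict.fromkeys(families))
    X = np.zeros((len(families), len(levels)))
    index = {f: j for j, f in enumerate(levels)}
    for i, f in enumerate(families):
        X[i, index[f]] = 1.0
    return X, levels
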