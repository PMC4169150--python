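"""Independent least-squares oracles used to validate the scan machinery.

Everything here goes through statsmodels' OLS (a code path the package
itself never uses), so agreement is a genuine dual-route check.
"""

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm


def family_dummies(families) -> np.ndarray:
    return pd.get_dummies(pd.Series(list(families)), dtype=float).to_numpy()


def f_test_marker(y, families, marker, cofactors=()) -> tuple[float, float]:
    """F test of one marker above family + cofactors via statsmodels."""
    B = family_dummies(families)
    X_red = np.column_stack([B, *cofactors]) if len(cofactors) else B
    X_full = np.column_stack([X_red, marker])
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    f, p, _ = fit_full.compare_f_test(fit_red)
    return float(f), float(p)


def f_test_interaction(y, families, x1, x2) -> tuple[float, float]:
    """Two-locus interaction F test via statsmodels."""
    B = family_dummies(families)
    X_red = np.column_stack([B, x1, x2])
    X_full = np.column_stack([X_red, x1 * x2])
    f, p, _ = sm.OLS(y, X_full).fit().compare_f_test(sm.OLS(y, X_red).fit())
    return float(f), float(p)


def sequential_r2(y, families, marker_cols) -> np.ndarray:
    """Nested-RSS sequential partial R2 relative to the family baseline."""
    B = family_dummies(families)
    rss_fam = float(sm.OLS(y, B).fit().ssr)
    shares = []
    X = B
    prev = rss_fam
    for col in marker_cols:
        X = np.column_stack([X, col])
        rss = float(sm.OLS(y, X).fit().ssr)
        shares.append((prev - rss) / rss_fam)
        prev = rss
    return np.array(shares)


def sbc(y, X, n_params) -> float:
    n = len(y)
    rss = float(sm.OLS(y, X).fit().ssr)
    return n * np.log(max(rss, 1e-12) / n) + n_params * np.log(n)


def best_subset_by_sbc(y, families, marker_cols) -> tuple:
    """Exhaustive best subset (by SBC) over all marker combinations."""
    B = family_dummies(families)
    F = B.shape[1]
    m = len(marker_cols)
    best = (sbc(y, B, F), ())
    for k in range(1, m + 1):
        for subset in itertools.combinations(range(m), k):
            X = np.column_stack([B] + [marker_cols[j] for j in subset])
            score = sbc(y, X, F + k)
            if score < best[0] - 1e-12:
                best = (score, subset)
    return best
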