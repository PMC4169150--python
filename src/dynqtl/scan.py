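"""Multi-family main-effect QTL scan.

The scan model is marker regression across families,

    Y = l mu + X_f M_f + X_q b_q + sum_{c != q} X_c b_c + eps

with Y the vector of line BLUEs, X_f the family incidence matrix (the
family effect absorbs differences in family means and spans the
intercept), X_q the 0/1 genotype vector of the tested marker and X_c the
selected cofactor markers.  The detection procedure has two steps:

1. stepwise multiple linear regression (forward-backward) selects the
   cofactor set by the Schwarz Bayesian Criterion
   ``SBC = n ln(RSS/n) + k ln(n)`` with the family effect always included;
2. each marker is tested by the F test of the full model (with the marker)
   against the reduced model (without it), and the Bonferroni-Holm
   step-down procedure flags significant markers at level alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import (family_design, f_test_nested, ols_rss, orth_basis,
                      residualize)
from .genotypes import GenotypeMatrix
from .gmap import GeneticMap
from .phenotype import BlueVector

_NORM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def holm_correct(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni-Holm step-down significance flags (original order).

    Sort p values ascending and reject while ``p_(i) <= alpha / (m - i + 1)``
    (1-based i); the procedure stops at the first failure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            flags[idx] = True
        else:
            break
    return flags


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------

def _align(y, genotypes: GenotypeMatrix):
    """Intersect phenotype and genotype lines (genotype order, finite y)."""
    if isinstance(y, BlueVector):
        values = y.values
    else:
        values = pd.Series(y)
    values = values.dropna()
    keep = genotypes.lines.isin(values.index)
    lines = genotypes.lines[keep]
    if len(lines) == 0:
        raise ValueError("no shared lines between phenotypes and genotypes")
    yv = values.loc[lines].to_numpy(dtype=float)
    rows = np.flatnonzero(keep)
    fam = genotypes.families.loc[lines].to_numpy()
    return yv, rows, lines, fam


# ---------------------------------------------------------------------------
# Cofactor selection
# ---------------------------------------------------------------------------

def select_cofactors(y, genotypes: GenotypeMatrix,
                     max_cofactors: int | None = None) -> list:
    """Forward-backward stepwise cofactor selection by SBC.

    The family effect is always in the model.  Candidate markers enter on a
    family-mean-imputed copy of the genotype matrix (selection is a
    screening step; all downstream inference is complete-case).  The search
    is deterministic: SBC ties are broken by the larger RSS reduction
    (equivalently the smaller p value) and then by map order.

    An empty set is a valid outcome (no marker improves the SBC).
    """
    yv, rows, lines, fam = _align(y, genotypes)
    n = len(yv)
    B, _ = family_design(fam)
    F = B.shape[1]
    if n <= F + 2:
        raise ValueError("too few lines for cofactor selection")
    X = genotypes.impute_family_mean()[rows]
    markers = genotypes.markers
    if max_cofactors is None:
        max_cofactors = max(1, n // 5)

    floor = 1e-12 * max(float(np.var(yv)) * n, 1.0)
    logn = np.log(n)

    def sbc(rss: float, k: int) -> float:
        return n * np.log(max(rss, floor) / n) + k * logn

    selected: list[int] = []

    def refit():
        cols = [B] + [X[:, [j]] for j in selected]
        Q = orth_basis(np.hstack(cols))
        r = residualize(Q, yv)
        return Q, r, float(r @ r)

    Q, r, rss = refit()
    current = sbc(rss, F)
    available = np.ones(X.shape[1], dtype=bool)
    # Monomorphic columns can never help.
    available &= X.std(axis=0) > 0

    changed = True
    while changed and len(selected) < max_cofactors:
        changed = False
        # Forward step.
        cand = np.flatnonzero(available)
        if cand.size:
            C = residualize(Q, X[:, cand])
            norms2 = np.einsum("ij,ij->j", C, C)
            valid = norms2 > _NORM_TOL * n
            num = (C.T @ r) ** 2
            drss = np.where(valid, num / np.maximum(norms2, _NORM_TOL), 0.0)
            rss_new = np.maximum(rss - drss, 0.0)
            k_new = F + len(selected) + 1
            scores = n * np.log(np.maximum(rss_new, floor) / n) + k_new * logn
            scores[~valid] = np.inf
            # Ties: larger RSS drop (smaller p), then map order.
            best = min(range(cand.size),
                       key=lambda i: (round(scores[i] / 1e-9),
                                      -drss[i], cand[i]))
            if scores[best] < current - 1e-9:
                j = int(cand[best])
                selected.append(j)
                available[j] = False
                Q, r, rss = refit()
                current = sbc(rss, F + len(selected))
                changed = True
        # Backward step(s).
        improved = True
        while improved and len(selected) > 1:
            improved = False
            drop_scores = []
            for pos, j in enumerate(selected):
                others = [B] + [X[:, [k]] for k in selected if k != j]
                rss_wo, _, _ = ols_rss(np.hstack(others), yv)
                drop_scores.append((sbc(rss_wo, F + len(selected) - 1), pos))
            best_score, best_pos = min(drop_scores)
            if best_score < current - 1e-9:
                selected.pop(best_pos)
                Q, r, rss = refit()
                current = sbc(rss, F + len(selected))
                improved = True
                changed = True
    return [markers[j] for j in selected]


# ---------------------------------------------------------------------------
# Marker scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResults:
    """Per-marker scan output plus metadata.

    ``table`` columns: marker, group, cm, n, effect (allele-substitution
    effect on the 0/1 coding, reference allele = allele coded 0), p_value,
    significant (Holm), skipped, duplicate_of.
    """

    table: pd.DataFrame
    cofactors: list
    alpha: float
    m_tested: int
    stage: str | None = None
    n_lines: int = 0
    cofactor_window: float = 0.0
    notes: dict = field(default_factory=dict)

    @property
    def significant_table(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def pvalues(self) -> pd.Series:
        return self.table.set_index("marker")["p_value"]

    def summary(self) -> str:
        sig = self.significant_table
        lines = [
            f"Multi-family QTL scan{' for ' + self.stage if self.stage else ''}",
            f"  lines: {self.n_lines}   markers tested: {self.m_tested}"
            f"   cofactors: {len(self.cofactors)}",
            f"  Holm-significant markers (alpha={self.alpha}): {len(sig)}",
        ]
        for _, row in sig.iterrows():
            lines.append(f"    {row['marker']:<12} {row['group']:<5} "
                         f"{row['cm']:7.1f} cM  effect={row['effect']:+.3f}  "
                         f"p={row['p_value']:.3g}")
        return "\n".join(lines)


def _column_key(col: np.ndarray) -> bytes:
    return np.ascontiguousarray(col).tobytes()


def scan_markers(y, genotypes: GenotypeMatrix, gmap: GeneticMap | None = None,
                 cofactors=(), alpha: float = 0.05,
                 cofactor_window: float = 10.0,
                 stage: str | None = None) -> ScanResults:
    """Per-marker F tests of the full vs the reduced multi-family model.

    For each polymorphic marker q the reduced model contains the family
    effect and the cofactors minus any cofactor that (a) is q itself,
    (b) has a genotype vector identical to q, or (c) lies within
    ``cofactor_window`` cM of q on the same linkage group.  Both models are
    fitted on the lines complete for q and the active cofactors
    (complete-case).  ``F = ((RSS_red - RSS_full)/1) / (RSS_full/(n - p))``
    with p the rank of the full design.

    Perfectly duplicated marker columns are collapsed: one representative
    is tested and the duplicates inherit its statistics (flagged through
    the ``duplicate_of`` column).
    """
    yv, rows, lines, fam = _align(y, genotypes)
    n = len(yv)
    B, _ = family_design(fam)
    markers = list(genotypes.markers)
    X = genotypes.calls[rows]
    constant_response = bool(np.ptp(yv) == 0.0)
    cofactors = [c for c in cofactors if c in genotypes._col]
    cof_cols = {c: X[:, genotypes.marker_index(c)] for c in cofactors}
    cof_keys = {c: _column_key(cof_cols[c]) for c in cofactors}

    # Collapse duplicate columns.
    rep_of: dict[bytes, str] = {}
    duplicate_of: dict[str, str] = {}
    for mk in markers:
        key = _column_key(X[:, genotypes.marker_index(mk)])
        if key in rep_of:
            duplicate_of[mk] = rep_of[key]
        else:
            rep_of[key] = mk

    reduced_cache: dict = {}
    rec: dict[str, dict] = {}
    n_skipped = 0

    def active_cofactors(mk: str, key: bytes) -> tuple:
        out = []
        for c in cofactors:
            if c == mk or cof_keys[c] == key:
                continue
            if (gmap is not None and cofactor_window > 0
                    and gmap.has_marker(c) and gmap.has_marker(mk)
                    and gmap.within_window(c, mk, cofactor_window)):
                continue
            out.append(c)
        return tuple(out)

    for mk in markers:
        if mk in duplicate_of:
            continue
        xq = X[:, genotypes.marker_index(mk)]
        key = _column_key(xq)
        active = active_cofactors(mk, key)
        mask = ~np.isnan(xq)
        for c in active:
            mask &= ~np.isnan(cof_cols[c])
        n_used = int(mask.sum())
        xm = xq[mask]
        if n_used < 3 or np.nanstd(xm) == 0:
            rec[mk] = dict(n=n_used, effect=np.nan, p_value=np.nan,
                           skipped=True)
            n_skipped += 1
            continue
        if constant_response:
            # A trait without variation carries no association signal.
            rec[mk] = dict(n=n_used, effect=0.0, p_value=1.0, skipped=False)
            continue
        ckey = (active, mask.tobytes())
        if ckey in reduced_cache:
            rss_red, rank_red = reduced_cache[ckey]
        else:
            X_red = np.column_stack([B[mask]]
                                    + [cof_cols[c][mask] for c in active])
            rss_red, rank_red, _ = ols_rss(X_red, yv[mask])
            reduced_cache[ckey] = (rss_red, rank_red)
        X_full = np.column_stack([B[mask]]
                                 + [cof_cols[c][mask] for c in active]
                                 + [xm])
        rss_full, rank_full, coef = ols_rss(X_full, yv[mask])
        df_resid = n_used - rank_full
        if df_resid < 1:
            warnings.warn(f"marker {mk}: no residual degrees of freedom, "
                          f"skipped")
            rec[mk] = dict(n=n_used, effect=np.nan, p_value=np.nan,
                           skipped=True)
            n_skipped += 1
            continue
        if rank_full == rank_red:
            # Marker absorbed by the family/cofactor space (e.g. perfectly
            # confounded with family): effect inestimable.
            rec[mk] = dict(n=n_used, effect=np.nan, p_value=1.0,
                           skipped=False)
            continue
        _, p = f_test_nested(rss_red, rss_full, 1, df_resid)
        rec[mk] = dict(n=n_used, effect=float(coef[-1]), p_value=p,
                       skipped=False)

    for mk, rep in duplicate_of.items():
        rec[mk] = dict(rec[rep])

    table = pd.DataFrame(
        [{"marker": mk, **rec[mk],
          "duplicate_of": duplicate_of.get(mk)} for mk in markers])
    if gmap is not None:
        table["group"] = [gmap.group(m) if gmap.has_marker(m) else None
                          for m in table["marker"]]
        table["cm"] = [gmap.position(m) if gmap.has_marker(m) else np.nan
                       for m in table["marker"]]
    else:
        table["group"] = None
        table["cm"] = np.nan

    tested = table["p_value"].notna()
    # Holm over the representative markers actually tested (duplicates do
    # not inflate m).
    rep_tested = tested & table["duplicate_of"].isna()
    flags = np.zeros(len(table), dtype=bool)
    if rep_tested.any():
        flags_rep = holm_correct(table.loc[rep_tested, "p_value"].to_numpy(),
                                 alpha)
        flags[np.flatnonzero(rep_tested.to_numpy())] = flags_rep
        # Duplicates inherit their representative's flag.
        rep_flag = dict(zip(table.loc[rep_tested, "marker"],
                            flags_rep))
        for i, mk in enumerate(table["marker"]):
            dup = table["duplicate_of"].iloc[i]
            if dup is not None and dup in rep_flag:
                flags[i] = rep_flag[dup]
    table["significant"] = flags
    table = table[["marker", "group", "cm", "n", "effect", "p_value",
                   "significant", "skipped", "duplicate_of"]]
    return ScanResults(table, list(cofactors), alpha,
                       int(rep_tested.sum()), stage, n, cofactor_window,
                       notes={"n_skipped": n_skipped,
                              "n_duplicates": len(duplicate_of)})


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class AssociationScan:
    """Multi-family association scan model.

    Parameters
    ----------
    y:
        :class:`BlueVector` or Series of line BLUEs for one stage.
    genotypes:
        :class:`GenotypeMatrix` (carries the family assignment).
    gmap:
        Genetic map; needed for the cofactor exclusion window and for map
        annotation of the results.
    alpha:
        Family-wise error level of the Holm correction.
    cofactor_window:
        Cofactors within this many cM of the tested marker (same linkage
        group) are excluded from that marker's fit; 0 reproduces the
        literal ``c != q`` rule.
    cofactors:
        Optional fixed cofactor set; if None, ``fit`` runs the stepwise
        SBC selection first.
    """

    def __init__(self, y, genotypes: GenotypeMatrix,
                 gmap: GeneticMap | None = None, alpha: float = 0.05,
                 cofactor_window: float = 10.0, cofactors=None):
        self.y = y
        self.genotypes = genotypes
        self.gmap = gmap
        self.alpha = alpha
        self.cofactor_window = cofactor_window
        self.cofactors = cofactors

    def fit(self, select: bool = True) -> ScanResults:
        cofs = self.cofactors
        if cofs is None:
            cofs = (select_cofactors(self.y, self.genotypes)
                    if select else [])
        stage = self.y.stage if isinstance(self.y, BlueVector) else None
        return scan_markers(self.y, self.genotypes, self.gmap, cofs,
                            self.alpha, self.cofactor_window, stage)
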