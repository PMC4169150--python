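"""Two-dimensional epistasis scan with the region-count Bonferroni threshold.

Each unordered marker pair (q, q') is tested by the F test of

    Y = X_f M_f + X_q b_q + X_q' b_q' + X_qq' b_qq' + eps

against the same model without the interaction term, where X_qq' is the
elementwise product of the two 0/1 genotype vectors.  The genome-wide
significance threshold divides alpha by the number of possible pairwise
interactions between chromosome regions, assuming two separate regions per
linkage group: ``alpha / C(2L, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import family_design, f_test_nested, ols_rss, orth_basis, \
    residualize
from .genotypes import GenotypeMatrix
from .gmap import GeneticMap
from .phenotype import BlueVector
from .scan import _align

_NORM_TOL = 1e-9


def epistasis_threshold(n_linkage_groups: int, alpha: float = 0.05) -> float:
    """Region-pair Bonferroni threshold ``alpha / C(2L, 2)``.

    With L = 22 linkage groups and alpha = 0.05 this gives
    0.05 / 946 = 5.3e-5 (two significant digits).
    """
    if n_linkage_groups < 1:
        raise ValueError("need at least one linkage group")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / comb(2 * n_linkage_groups, 2)


@dataclass
class EpistasisResults:
    """Significant marker pairs and scan metadata."""

    table: pd.DataFrame
    threshold: float
    n_linkage_groups: int | None
    alpha: float
    n_pairs_tested: int
    n_pairs_skipped: int
    stage: str | None = None
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Epistasis scan{' for ' + self.stage if self.stage else ''}",
            f"  pairs tested: {self.n_pairs_tested}   "
            f"skipped (inestimable): {self.n_pairs_skipped}",
            f"  threshold: p < {self.threshold:.3g}"
            + (f"  (L = {self.n_linkage_groups}, alpha = {self.alpha})"
               if self.n_linkage_groups else ""),
            f"  significant pairs: {len(self.table)}",
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"    {row['marker_a']} x {row['marker_b']}  "
                f"b_qq'={row['effect']:+.3f}  p={row['p_value']:.3g}")
        return "\n".join(lines)


def _thin_markers(genotypes: GenotypeMatrix, gmap: GeneticMap | None,
                  thin_cm: float) -> list:
    markers = list(genotypes.markers)
    if thin_cm <= 0 or gmap is None:
        return markers
    kept = []
    last: dict = {}
    for mk in markers:
        if not gmap.has_marker(mk):
            kept.append(mk)
            continue
        g, pos = gmap.group(mk), gmap.position(mk)
        if g not in last or pos - last[g] >= thin_cm:
            kept.append(mk)
            last[g] = pos
    return kept


def scan_pairs(y, genotypes: GenotypeMatrix, threshold: float,
               gmap: GeneticMap | None = None, thin_cm: float = 0.0,
               stage: str | None = None, alpha: float = 0.05,
               n_linkage_groups: int | None = None,
               keep_all: bool = False) -> EpistasisResults:
    """Full two-dimensional scan for interaction QTL.

    Pairs whose interaction column is constant or collinear with the main
    effects, or for which fewer than all four two-locus genotype classes
    are observed, are inestimable and skipped (counted).  Complete-case
    lines per pair.  ``keep_all`` retains every estimable pair in the
    table (used for small-scale validation); by default only pairs with
    ``p < threshold`` are kept.
    """
    yv, rows, lines, fam = _align(y, genotypes)
    B, _ = family_design(fam)
    markers = _thin_markers(genotypes, gmap, thin_cm)
    idx = [genotypes.marker_index(m) for m in markers]
    X = genotypes.calls[rows][:, idx]
    m = len(markers)
    if m < 2:
        raise ValueError("need at least two polymorphic markers")
    n = len(yv)
    has_missing = bool(np.isnan(X).any())

    hits = []
    tested = 0
    skipped = 0

    def record(ia, ib, p, fstat, n_used, coef_full):
        hits.append({
            "marker_a": markers[ia], "marker_b": markers[ib],
            "p_value": p, "f_stat": fstat, "n": n_used,
            "effect": coef_full[-1], "effect_a": coef_full[-3],
            "effect_b": coef_full[-2]})

    if not has_missing:
        rankB = orth_basis(B).shape[1]
        for ia in range(m - 1):
            xa = X[:, ia]
            if xa.std() == 0:
                skipped += m - 1 - ia
                continue
            Q = orth_basis(np.column_stack([B, xa]))
            yr = residualize(Q, yv)
            rss0 = float(yr @ yr)
            Xb = X[:, ia + 1:]
            U = residualize(Q, Xb)
            u2 = np.einsum("ij,ij->j", U, U)
            Z = xa[:, None] * Xb
            Zr = residualize(Q, Z)
            coef_u = np.einsum("ij,ij->j", U, Zr) / np.maximum(u2, _NORM_TOL)
            V = Zr - U * coef_u
            v2 = np.einsum("ij,ij->j", V, V)
            # All four two-locus classes present?
            n11 = xa @ Xb
            n1_ = xa.sum()
            n_1 = Xb.sum(axis=0)
            classes_ok = ((n11 >= 1) & (n1_ - n11 >= 1) & (n_1 - n11 >= 1)
                          & (n - n1_ - n_1 + n11 >= 1))
            estimable = classes_ok & (u2 > _NORM_TOL * n) & (v2 > _NORM_TOL * n)
            skipped += int((~estimable).sum())
            tested += int(estimable.sum())
            du = (U.T @ yr) ** 2 / np.maximum(u2, _NORM_TOL)
            rss_red = np.maximum(rss0 - du, 0.0)
            bint = (V.T @ yr) / np.maximum(v2, _NORM_TOL)
            rss_full = np.maximum(rss_red - bint ** 2 * v2, 0.0)
            df = n - (rankB + 3)
            if df < 1:
                continue
            tol = 1e-12 * max(rss0, 1.0)
            diff = np.maximum(rss_red - rss_full, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fstat = diff / (rss_full / df)
            p = stats.f.sf(fstat, 1, df)
            # Saturated fits: no interaction evidence unless the reduction
            # itself is non-negligible.
            saturated = rss_full <= tol
            p = np.where(saturated & (diff <= tol), 1.0, p)
            p = np.where(saturated & (diff > tol),
                         np.nextafter(0.0, 1.0), p)
            fstat = np.where(saturated, np.where(diff > tol, np.inf, 0.0),
                             fstat)
            p = np.maximum(p, np.nextafter(0.0, 1.0))
            sel = estimable if keep_all else (estimable & (p < threshold))
            for off in np.flatnonzero(sel):
                ib = ia + 1 + off
                X_full = np.column_stack([B, xa, X[:, ib], xa * X[:, ib]])
                _, _, coef = ols_rss(X_full, yv)
                record(ia, ib, float(p[off]), float(fstat[off]), n, coef)
    else:
        for ia in range(m - 1):
            xa = X[:, ia]
            for ib in range(ia + 1, m):
                xb = X[:, ib]
                mask = ~np.isnan(xa) & ~np.isnan(xb)
                a, b = xa[mask], xb[mask]
                n_used = int(mask.sum())
                n11 = float(a @ b)
                four = (n11 >= 1 and a.sum() - n11 >= 1
                        and b.sum() - n11 >= 1
                        and n_used - a.sum() - b.sum() + n11 >= 1)
                if not four:
                    skipped += 1
                    continue
                X_red = np.column_stack([B[mask], a, b])
                X_full = np.column_stack([B[mask], a, b, a * b])
                rss_red, rank_red, _ = ols_rss(X_red, yv[mask])
                rss_full, rank_full, coef = ols_rss(X_full, yv[mask])
                if rank_full == rank_red:
                    skipped += 1
                    continue
                df = n_used - rank_full
                fstat, p = f_test_nested(rss_red, rss_full, 1, df)
                tested += 1
                if keep_all or p < threshold:
                    record(ia, ib, p, fstat, n_used, coef)

    table = pd.DataFrame(
        hits, columns=["marker_a", "marker_b", "p_value", "f_stat", "n",
                       "effect", "effect_a", "effect_b"])
    if gmap is not None and len(table):
        for side in ("a", "b"):
            table[f"group_{side}"] = [
                gmap.group(mk) if gmap.has_marker(mk) else None
                for mk in table[f"marker_{side}"]]
            table[f"cm_{side}"] = [
                gmap.position(mk) if gmap.has_marker(mk) else np.nan
                for mk in table[f"marker_{side}"]]
    table = table.sort_values("p_value").reset_index(drop=True)
    return EpistasisResults(table, threshold, n_linkage_groups, alpha,
                            tested, skipped, stage)


class EpistasisScan:
    """Epistasis scan model.

    ``n_linkage_groups`` defaults to the map's group count ("auto"); the
    threshold is ``alpha / C(2L, 2)`` unless given explicitly.
    """

    def __init__(self, y, genotypes: GenotypeMatrix,
                 gmap: GeneticMap | None = None, alpha: float = 0.05,
                 n_linkage_groups: int | None = None,
                 threshold: float | None = None, thin_cm: float = 0.0):
        self.y = y
        self.genotypes = genotypes
        self.gmap = gmap
        self.alpha = alpha
        if n_linkage_groups is None and gmap is not None:
            n_linkage_groups = gmap.n_groups
        self.n_linkage_groups = n_linkage_groups
        if threshold is None:
            if n_linkage_groups is None:
                raise ValueError(
                    "need a map or n_linkage_groups to set the threshold")
            threshold = epistasis_threshold(n_linkage_groups, alpha)
        self.threshold = threshold
        self.thin_cm = thin_cm

    def fit(self, keep_all: bool = False) -> EpistasisResults:
        stage = self.y.stage if isinstance(self.y, BlueVector) else None
        return scan_pairs(self.y, self.genotypes, self.threshold, self.gmap,
                          self.thin_cm, stage, self.alpha,
                          self.n_linkage_groups, keep_all)
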