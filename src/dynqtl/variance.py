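"""Proportion of genotypic variance explained by detected QTL.

The headline statistic is ``p_G = R2_adj / h2`` (reported in percent): the
adjusted fraction of phenotypic (line-mean) variance explained by the
detected markers beyond the family structure, divided by the entry-mean
heritability, i.e. the share of the *genotypic* variance the markers
account for.  Per-marker shares are sequential partial R2 values from a
simultaneous fit in which markers enter in the order of the strength of
their association (smallest scan p first), so collinear markers do not
double-count variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import family_design, ols_rss
from .genotypes import GenotypeMatrix
from .scan import _align


@dataclass
class VarianceAccount:
    """Explained-genotypic-variance accounting for one stage."""

    stage: str | None
    markers: list                  # in fit order
    r2_adj: float
    h2: float
    p_g: float                     # percent; may exceed 100 (flagged)
    shares: pd.DataFrame           # marker, seq_r2, seq_pg, effect, collinear
    n: int
    k: int                         # independent marker columns fitted
    n_families: int
    exceeds_h2: bool = False
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        head = (f"Explained genotypic variance"
                f"{' for ' + self.stage if self.stage else ''}: "
                f"p_G = {self.p_g:.1f} %  (R2_adj = {self.r2_adj:.3f}, "
                f"h2 = {self.h2:.2f}, {self.k} markers, n = {self.n})")
        if self.exceeds_h2:
            head += "  [R2_adj exceeds h2 - estimator bias, not clamped]"
        return head


def _nested_rss(y, genotypes: GenotypeMatrix, markers) -> tuple:
    """Family-baseline and nested RSS path over the ordered marker list.

    Complete-case over y and *all* listed markers so every nested model is
    fitted on the same lines.
    """
    yv, rows, lines, fam = _align(y, genotypes)
    cols = genotypes.calls[rows][:, [genotypes.marker_index(m)
                                     for m in markers]]
    mask = ~np.isnan(cols).any(axis=1)
    yv = yv[mask]
    cols = cols[mask]
    fam = fam[mask]
    n = len(yv)
    B, _ = family_design(fam)
    rss_fam, rank_fam, _ = ols_rss(B, yv)
    path = [rss_fam]
    ranks = [rank_fam]
    X = B
    for j in range(len(markers)):
        X = np.column_stack([X, cols[:, j]])
        rss, rank, coef = ols_rss(X, yv)
        path.append(rss)
        ranks.append(rank)
    # Effects from the final simultaneous fit (min-norm for collinear sets).
    _, _, coef = ols_rss(X, yv)
    effects = coef[B.shape[1]:]
    return yv, cols, fam, n, B.shape[1], np.array(path), np.array(ranks), \
        effects


def order_by_association(markers, pvalues: pd.Series,
                         genotypes: GenotypeMatrix) -> list:
    """Markers ordered smallest p first; ties broken by map (column) order."""
    key = [(float(pvalues[m]), genotypes.marker_index(m)) for m in markers]
    return [m for _, m in sorted(zip(key, markers))]


def sequential_partial_r2(y, genotypes: GenotypeMatrix, markers,
                          pvalues: pd.Series | None = None) -> pd.DataFrame:
    """Sequential partial R2 per marker relative to the family baseline.

    ``share_i = (RSS_{i-1} - RSS_i) / RSS_family`` with markers entered
    smallest scan p first (ties by map order) when p values are supplied,
    otherwise in the given order.  A marker collinear with those already
    entered contributes exactly 0.
    """
    markers = list(markers)
    if pvalues is not None:
        markers = order_by_association(markers, pvalues, genotypes)
    if not markers:
        return pd.DataFrame(columns=["marker", "seq_r2", "collinear"])
    yv, cols, fam, n, F, path, ranks, effects = _nested_rss(
        y, genotypes, markers)
    rss_fam = path[0]
    shares = (path[:-1] - path[1:]) / rss_fam if rss_fam > 0 else \
        np.zeros(len(markers))
    collinear = np.diff(ranks) == 0
    return pd.DataFrame({"marker": markers, "seq_r2": shares,
                         "effect": effects, "collinear": collinear})


def proportion_genotypic_variance(y, genotypes: GenotypeMatrix, markers,
                                  h2: float,
                                  pvalues: pd.Series | None = None,
                                  stage: str | None = None
                                  ) -> VarianceAccount:
    """p_G of a detected marker set: ``p_G = 100 * R2_adj / h2``.

    The simultaneous fit contains the family effect plus all markers;
    ``R2_D = (RSS_family - RSS_full) / RSS_family`` is adjusted as
    ``R2_adj = 1 - (1 - R2_D) (n - F) / (n - F - k)`` with k the number of
    linearly independent marker columns.  Values above 100 % are flagged,
    not clamped (the estimator's selection bias stays visible; the
    cross-validation module quantifies it).
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    markers = list(markers)
    if not markers:
        shares = pd.DataFrame(columns=["marker", "seq_r2", "seq_pg",
                                       "effect", "collinear"])
        yv, rows, lines, fam = _align(y, genotypes)
        return VarianceAccount(stage, [], 0.0, h2, 0.0, shares, len(yv), 0,
                               len(np.unique(fam)))
    if pvalues is not None:
        markers = order_by_association(markers, pvalues, genotypes)
    yv, cols, fam, n, F, path, ranks, effects = _nested_rss(
        y, genotypes, markers)
    rss_fam, rss_full = path[0], path[-1]
    k = int(ranks[-1] - ranks[0])
    r2_delta = (rss_fam - rss_full) / rss_fam if rss_fam > 0 else 0.0
    denom = n - F - k
    if denom < 1:
        raise ValueError("not enough residual degrees of freedom")
    r2_adj = 1.0 - (1.0 - r2_delta) * (n - F) / denom
    p_g = 100.0 * r2_adj / h2
    seq = (path[:-1] - path[1:]) / rss_fam if rss_fam > 0 else \
        np.zeros(len(markers))
    scale = (r2_adj / r2_delta) if r2_delta > 0 else 0.0
    shares = pd.DataFrame({
        "marker": markers,
        "seq_r2": seq,
        "seq_pg": 100.0 * seq * scale / h2,
        "effect": effects,
        "collinear": np.diff(ranks) == 0,
    })
    return VarianceAccount(stage, markers, float(r2_adj), h2, float(p_g),
                           shares, n, k, F, exceeds_h2=bool(r2_adj > h2),
                           notes={"r2_unadjusted": float(r2_delta)})


def temporal_pg_profile(regions, blues_by_stage: dict, scans_by_stage: dict,
                        genotypes: GenotypeMatrix, h2_by_stage: dict
                        ) -> pd.DataFrame:
    """Per-region p_G trajectory across stages.

    ``regions`` is the matched-region list from the dynamic layer; at each
    stage every region is represented by its member marker with the
    smallest scan p value at that stage, regions enter the sequential fit
    in that order, and the sequential p_G shares are computed with that
    stage's heritability.  Regions whose representative cannot be fitted
    (monomorphic at the stage) get share 0, flagged.
    """
    records = []
    for stage, blues in blues_by_stage.items():
        pvals = scans_by_stage[stage].pvalues() \
            if hasattr(scans_by_stage[stage], "pvalues") \
            else scans_by_stage[stage]
        reps = []
        for region in regions:
            members = [m for m in region.all_members if m in pvals.index]
            members = [m for m in members if np.isfinite(pvals[m])]
            if not members:
                records.append({"region": region.region_id, "stage": stage,
                                "marker": None, "pg_share": 0.0,
                                "flagged": True})
                continue
            best = min(members, key=lambda m: (pvals[m],
                                               genotypes.marker_index(m)))
            reps.append((region.region_id, best, float(pvals[best])))
        reps.sort(key=lambda t: t[2])
        if not reps:
            continue
        account = proportion_genotypic_variance(
            blues, genotypes, [mk for _, mk, _ in reps],
            h2_by_stage[stage], stage=stage)
        share = dict(zip(account.shares["marker"], account.shares["seq_pg"]))
        for region_id, mk, _ in reps:
            records.append({"region": region_id, "stage": stage,
                            "marker": mk, "pg_share": float(share[mk]),
                            "flagged": False})
    return pd.DataFrame(records,
                        columns=["region", "stage", "marker", "pg_share",
                                 "flagged"])
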