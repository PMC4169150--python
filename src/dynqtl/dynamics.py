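"""Dynamic QTL layer: region matching across stages, Venn partitions,
progression-trait scans and sign-change reports.

QTL detected at different developmental stages are declared to belong to
one chromosomal region if they fall within a configurable cM window of
each other on the same linkage group (single-linkage clustering, so chains
of overlapping windows merge).  The default window is +/- 5 cM, i.e. a
10-cM interval surrounding the QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gmap import GeneticMap
from .phenotype import BlueVector
from .scan import AssociationScan, ScanResults

DEFAULT_WINDOW_CM = 5.0


@dataclass
class QTLRegionMatch:
    """A cross-stage QTL region."""

    region_id: str
    group: str
    position: float                 # representative cM (best marker)
    best_marker: str
    best_p: float
    members: dict                   # stage -> DataFrame(marker, cm, p, effect)
    stages: tuple                   # stages where the region is significant
    venn_class: str
    effects: dict = field(default_factory=dict)   # stage -> effect (best)

    @property
    def all_members(self) -> list:
        out = []
        for sub in self.members.values():
            out.extend(sub["marker"].tolist())
        return list(dict.fromkeys(out))


def _significant_frame(scan, stage: str, gmap: GeneticMap | None
                       ) -> pd.DataFrame:
    if isinstance(scan, ScanResults):
        sub = scan.significant_table.copy()
    else:
        sub = pd.DataFrame(scan).copy()
    sub["stage"] = stage
    if len(sub) == 0:
        for col in ("group", "cm"):
            if col not in sub.columns:
                sub[col] = []
        return sub
    needs_map = ("group" not in sub.columns or "cm" not in sub.columns
                 or sub["group"].isna().any() or sub["cm"].isna().any())
    if needs_map and gmap is not None:
        unknown = [m for m in sub["marker"] if not gmap.has_marker(m)]
        if unknown:
            raise ValueError(f"QTL without map position: {unknown[:5]}")
        sub["group"] = [gmap.group(m) for m in sub["marker"]]
        sub["cm"] = [gmap.position(m) for m in sub["marker"]]
    if ("group" not in sub.columns or "cm" not in sub.columns
            or sub[["group", "cm"]].isna().any().any()):
        bad = (sub.loc[sub[["group", "cm"]].isna().any(axis=1), "marker"]
               if "cm" in sub.columns and "group" in sub.columns
               else sub["marker"])
        raise ValueError(f"QTL without map position: {list(bad)[:5]}")
    return sub


def venn_class(stages_present, all_stages) -> str:
    present = [s for s in all_stages if s in stages_present]
    if len(present) == 1:
        return f"{present[0]} only"
    return " & ".join(present)


def match_regions(scans_by_stage: dict, window_cm: float = DEFAULT_WINDOW_CM,
                  gmap: GeneticMap | None = None) -> list:
    """Cluster significant markers of all stages into QTL regions.

    Within each linkage group, markers whose positions differ by at most
    ``window_cm`` are linked; clusters are the connected components
    (single linkage: sorted positions split where the gap exceeds the
    window).  Each cluster is one region; its Venn class records the set of
    stages at which it is significant.
    """
    all_stages = list(scans_by_stage)
    frames = [_significant_frame(scan, stage, gmap)
              for stage, scan in scans_by_stage.items()]
    frames = [f for f in frames if len(f)]
    regions: list[QTLRegionMatch] = []
    if not frames:
        return regions
    pooled = pd.concat(frames, ignore_index=True)
    for g, sub in pooled.groupby("group", sort=False):
        sub = sub.sort_values(["cm", "marker"], kind="stable")
        pos = sub["cm"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_cm)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cluster = sub.iloc[int(lo):int(hi)]
            members = {}
            effects = {}
            for stage in all_stages:
                ssub = cluster[cluster["stage"] == stage]
                if len(ssub):
                    members[stage] = ssub[["marker", "cm", "p_value",
                                           "effect"]].reset_index(drop=True)
                    best_row = ssub.loc[ssub["p_value"].idxmin()]
                    effects[stage] = float(best_row["effect"])
            stages_present = tuple(s for s in all_stages if s in members)
            best = cluster.loc[cluster["p_value"].idxmin()]
            regions.append(QTLRegionMatch(
                region_id=f"{g}@{best['cm']:.1f}",
                group=g, position=float(best["cm"]),
                best_marker=str(best["marker"]),
                best_p=float(best["p_value"]),
                members=members, stages=stages_present,
                venn_class=venn_class(stages_present, all_stages),
                effects=effects))
    regions.sort(key=lambda r: (all_stages_index(r, pooled), r.position))
    return regions


def all_stages_index(region: QTLRegionMatch, pooled: pd.DataFrame) -> int:
    groups = list(dict.fromkeys(pooled["group"]))
    return groups.index(region.group)


def venn_counts(regions, stages=("DS1", "DS2", "DS3")) -> pd.Series:
    """Counts of regions per Venn class (all 2^S - 1 classes reported)."""
    classes = []
    n = len(stages)
    for mask in range(1, 2 ** n):
        present = [stages[i] for i in range(n) if mask >> i & 1]
        classes.append(venn_class(present, stages))
    counts = pd.Series(0, index=pd.Index(classes, name="venn_class"),
                       dtype=int)
    for region in regions:
        counts[region.venn_class] += 1
    return counts


def marker_venn_counts(scans_by_stage: dict,
                       stages=("DS1", "DS2", "DS3")) -> pd.Series:
    """Marker-level Venn counts (no positional clustering)."""
    sets = {}
    for stage, scan in scans_by_stage.items():
        sub = scan.significant_table if isinstance(scan, ScanResults) else scan
        sets[stage] = set(sub["marker"])
    all_markers = set().union(*sets.values()) if sets else set()
    classes = venn_counts([], stages).index
    counts = pd.Series(0, index=classes, dtype=int)
    for mk in all_markers:
        present = [s for s in stages if mk in sets.get(s, set())]
        counts[venn_class(present, stages)] += 1
    return counts


def progression_scan(blues_from: BlueVector, blues_to: BlueVector,
                     genotypes: GenotypeMatrix, gmap: GeneticMap | None = None,
                     alpha: float = 0.05, cofactor_window: float = 10.0
                     ) -> ScanResults:
    """Scan the developmental progression between two stages.

    The progression trait is ``delta = BLUE(to) - BLUE(from)`` per line; the
    full association pipeline (own cofactor selection, own Holm correction)
    runs on delta.  A QTL whose effect changes between the stages appears
    here with (approximately) the effect difference; a QTL with equal
    effects at both stages cancels.
    """
    shared = blues_from.values.index.intersection(blues_to.values.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared lines between stages")
    delta = (blues_to.values.loc[shared] - blues_from.values.loc[shared])
    dv = delta.to_numpy(dtype=float)
    if float(np.max(np.abs(dv))) == 0.0:
        raise ValueError(
            f"constant trait: {blues_to.stage} and {blues_from.stage} are "
            f"identical")
    if np.ptp(dv) <= 1e-10 * max(1.0, float(np.abs(dv).max())):
        # A shift with no between-line variation: nothing to map.  Snap to
        # the exact constant so the scan reports p = 1 everywhere instead
        # of fitting floating-point residue.
        delta = pd.Series(np.full_like(dv, dv.mean()), index=delta.index)
    delta_bv = BlueVector(delta, f"{blues_from.stage}-{blues_to.stage}",
                          blues_from.n_environments, blues_from.replication)
    return AssociationScan(delta_bv, genotypes, gmap, alpha,
                           cofactor_window).fit()


def sign_change_report(regions) -> pd.DataFrame:
    """Regions whose additive effect changes sign between stages.

    Lists every stage pair at which the region is significant with
    opposite effect signs, together with the effect magnitudes.
    """
    rows = []
    for region in regions:
        stages = [s for s in region.stages if np.isfinite(
            region.effects.get(s, np.nan))]
        for i in range(len(stages)):
            for j in range(i + 1, len(stages)):
                ea = region.effects[stages[i]]
                eb = region.effects[stages[j]]
                if ea * eb < 0:
                    rows.append({
                        "region": region.region_id, "group": region.group,
                        "position_cm": region.position,
                        "stage_a": stages[i], "stage_b": stages[j],
                        "effect_a": ea, "effect_b": eb})
    return pd.DataFrame(rows, columns=["region", "group", "position_cm",
                                       "stage_a", "stage_b", "effect_a",
                                       "effect_b"])


def regions_to_frame(regions) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "region": r.region_id, "group": r.group,
            "position_cm": r.position, "best_marker": r.best_marker,
            "best_p": r.best_p, "venn_class": r.venn_class,
            "stages": ",".join(r.stages),
            "n_markers": len(r.all_members),
            **{f"effect_{s}": r.effects.get(s, np.nan) for s in r.members},
        })
    return pd.DataFrame(rows)
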