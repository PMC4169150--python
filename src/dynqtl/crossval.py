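"""Fivefold cross-validation of the QTL detection pipeline.

Marker selection and effect estimation on an estimation set (ES) and
validation of the explained genotypic variance on the held-out test set
(TS) yield an asymptotically unbiased estimate of p_G.  The gap between
the ES- and TS-based estimates is the *relative bias*

    relative_bias = 100 * (p_G-ES - p_G-TS) / p_G-ES  [%],

the model-selection optimism of the in-sample estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import family_design, ols_rss
from .genotypes import GenotypeMatrix
from .gmap import GeneticMap
from .scan import AssociationScan, _align
from .variance import proportion_genotypic_variance


def relative_bias(pg_es: float, pg_ts: float) -> float:
    """``100 * (p_G-ES - p_G-TS) / p_G-ES`` in percent."""
    if pg_es == 0:
        return np.nan
    return 100.0 * (pg_es - pg_ts) / pg_es


@dataclass
class CVSummary:
    """Cross-validation aggregates for one stage."""

    stage: str | None
    qtl_ds: int                    # detected QTL, full data set
    pg_ds: float                   # p_G (%) on the full data set
    qtl_es: float                  # mean detected QTL over estimation sets
    pg_es: float                   # mean p_G (%) over estimation sets
    pg_ts: float                   # mean p_G (%) over test sets
    relative_bias_pct: float
    runs: int
    folds: int
    seed: int | None
    detection: pd.Series           # marker -> number of ES scans detecting it
    fold_records: pd.DataFrame = field(repr=False, default=None)
    h2: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [("QTL_DS", self.qtl_ds), ("p_G-DS", self.pg_ds),
                ("QTL_ES", self.qtl_es), ("p_G-ES", self.pg_es),
                ("p_G-TS", self.pg_ts),
                ("relative_bias", self.relative_bias_pct)]
        return pd.DataFrame(rows, columns=["quantity", self.stage or "value"]
                            ).set_index("quantity")

    def summary(self) -> str:
        return (f"{self.folds}-fold cross-validation"
                f"{' for ' + self.stage if self.stage else ''} "
                f"({self.runs} runs, h2 = {self.h2:.2f}):\n"
                f"  QTL_DS = {self.qtl_ds}   p_G-DS = {self.pg_ds:.1f} %\n"
                f"  QTL_ES = {self.qtl_es:.1f}   p_G-ES = {self.pg_es:.1f} %"
                f"   p_G-TS = {self.pg_ts:.1f} %\n"
                f"  relative bias = {self.relative_bias_pct:.1f} %")


def stratified_folds(families: pd.Series, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by family (each fold +/- 1 line exact)."""
    fold = np.empty(len(families), dtype=int)
    fam = families.to_numpy()
    offset = int(rng.integers(0, n_folds))
    for f in pd.unique(fam):
        idx = np.flatnonzero(fam == f)
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % n_folds
    return fold


def _predict(genotypes: GenotypeMatrix, lines, markers, fam_levels,
             fam_coef, marker_coef) -> pd.Series:
    """ES-model predictions (family mean + sum of marker effects)."""
    sub = genotypes.subset_lines(lines)
    cols = sub.calls[:, [sub.marker_index(m) for m in markers]] \
        if markers else np.zeros((sub.n_lines, 0))
    ok = ~np.isnan(cols).any(axis=1)
    fam_idx = {f: i for i, f in enumerate(fam_levels)}
    fams = sub.families.to_numpy()
    known = np.array([f in fam_idx for f in fams])
    ok &= known
    base = np.array([fam_coef[fam_idx[f]] if f in fam_idx else np.nan
                     for f in fams])
    pred = base + (cols @ marker_coef if markers else 0.0)
    return pd.Series(pred[ok], index=pd.Index(np.asarray(lines)[ok]))


def run_cv(y, genotypes: GenotypeMatrix, gmap: GeneticMap | None, h2: float,
           runs: int = 20, folds: int = 5, seed: int | None = 0,
           alpha: float = 0.05, cofactor_window: float = 10.0,
           ts_estimator: str = "corr_adj", stage: str | None = None
           ) -> CVSummary:
    """Cross-validate the full detection pipeline.

    Per run, lines are split into ``folds`` subsets stratified by family.
    For each fold the estimation set (the other folds) undergoes the full
    pipeline (cofactor selection -> scan -> Holm -> p_G); the fitted model
    (family means + marker effects) predicts the test-set lines, and
    ``p_G-TS = 100 * max(r2_adj, 0) / h2`` from the squared
    prediction-observation correlation adjusted for the test-set size
    (``ts_estimator="corr"`` uses the unadjusted square).  Folds whose ES
    scan finds no QTL contribute p_G-ES = p_G-TS = 0 (counted, not
    dropped).  The heritability is estimated once on the full data and
    reused in every fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if ts_estimator not in ("corr_adj", "corr"):
        raise ValueError("ts_estimator must be 'corr_adj' or 'corr'")
    yv, rows, lines, fam = _align(y, genotypes)
    fam_series = pd.Series(fam, index=lines)
    sizes = fam_series.value_counts()
    if (sizes < folds).any():
        small = list(sizes.index[sizes < folds])
        raise ValueError(f"families smaller than the fold count: {small}")
    geno = genotypes.subset_lines(lines)
    y_series = pd.Series(yv, index=lines)

    # Full-data pipeline.
    full_scan = AssociationScan(y_series, geno, gmap, alpha,
                                cofactor_window).fit()
    detected_ds = full_scan.significant_table["marker"].tolist()
    pg_ds = proportion_genotypic_variance(
        y_series, geno, detected_ds, h2,
        pvalues=full_scan.pvalues()).p_g if detected_ds else 0.0

    rng = np.random.default_rng(seed)
    detection: dict[str, int] = {}
    records = []
    for run in range(runs):
        fold_of = stratified_folds(fam_series, folds, rng)
        for k in range(folds):
            es_lines = lines[fold_of != k]
            ts_lines = lines[fold_of == k]
            geno_es = geno.subset_lines(es_lines)
            y_es = y_series.loc[es_lines]
            scan = AssociationScan(y_es, geno_es, gmap, alpha,
                                   cofactor_window).fit()
            detected = scan.significant_table["marker"].tolist()
            for mk in detected:
                detection[mk] = detection.get(mk, 0) + 1
            if not detected:
                records.append({"run": run, "fold": k, "n_qtl": 0,
                                "pg_es": 0.0, "pg_ts": 0.0})
                continue
            account = proportion_genotypic_variance(
                y_es, geno_es, detected, h2, pvalues=scan.pvalues())
            # Simultaneous ES fit for prediction.
            yv_es, rows_es, lines_es, fam_es = _align(y_es, geno_es)
            cols = geno_es.calls[rows_es][:, [geno_es.marker_index(m)
                                              for m in detected]]
            mask = ~np.isnan(cols).any(axis=1)
            B, fam_levels = family_design(fam_es[mask])
            X = np.column_stack([B, cols[mask]])
            _, _, coef = ols_rss(X, yv_es[mask])
            fam_coef = coef[:B.shape[1]]
            marker_coef = coef[B.shape[1]:]
            pred = _predict(geno, ts_lines, detected, fam_levels, fam_coef,
                            marker_coef)
            obs = y_series.loc[pred.index]
            n_ts = len(pred)
            if n_ts < 3 or np.std(pred) == 0 or np.std(obs) == 0:
                pg_ts = 0.0
            else:
                r = float(stats.pearsonr(pred, obs).statistic)
                r2 = r * r
                if ts_estimator == "corr_adj":
                    r2 = 1.0 - (1.0 - r2) * (n_ts - 1) / (n_ts - 2)
                pg_ts = 100.0 * max(r2, 0.0) / h2
            records.append({"run": run, "fold": k, "n_qtl": len(detected),
                            "pg_es": account.p_g, "pg_ts": pg_ts})
    rec = pd.DataFrame(records)
    pg_es_mean = float(rec["pg_es"].mean())
    pg_ts_mean = float(rec["pg_ts"].mean())
    return CVSummary(
        stage=stage, qtl_ds=len(detected_ds), pg_ds=float(pg_ds),
        qtl_es=float(rec["n_qtl"].mean()), pg_es=pg_es_mean,
        pg_ts=pg_ts_mean,
        relative_bias_pct=relative_bias(pg_es_mean, pg_ts_mean),
        runs=runs, folds=folds, seed=seed,
        detection=pd.Series(detection, dtype=int).sort_values(
            ascending=False),
        fold_records=rec, h2=h2)


def detection_frequency(cv: CVSummary, gmap: GeneticMap | None = None,
                        window_cm: float = 5.0) -> pd.DataFrame:
    """Per-marker detection counts over all ES scans, collapsed to regions.

    Markers detected in at least one ES scan are clustered into regions
    with the dynamic-layer window so that frequency can be read per QTL
    region as well as per marker.
    """
    if cv.fold_records is None or len(cv.fold_records) == 0:
        raise ValueError("no completed cross-validation runs")
    total = cv.runs * cv.folds
    out = cv.detection.rename("count").to_frame()
    out["frequency"] = out["count"] / total
    out.index.name = "marker"
    out = out.reset_index()
    if gmap is not None and len(out):
        out["group"] = [gmap.group(m) if gmap.has_marker(m) else None
                        for m in out["marker"]]
        out["cm"] = [gmap.position(m) if gmap.has_marker(m) else np.nan
                     for m in out["marker"]]
        out = out.sort_values(["group", "cm"], kind="stable")
        region = []
        last_g, last_pos, rid = None, None, 0
        for _, row in out.iterrows():
            if (row["group"] != last_g or last_pos is None
                    or row["cm"] - last_pos > window_cm):
                rid += 1
            region.append(f"R{rid:02d}")
            last_g, last_pos = row["group"], row["cm"]
        out["region"] = region
        out = out.sort_values("count", ascending=False)
    return out.reset_index(drop=True)
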