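"""End-to-end orchestration of the dynamic QTL analysis.

Stages: BLUEs -> variance components -> main-effect scans (per stage) ->
epistasis scans (per stage) -> explained-variance accounting ->
cross-validation -> dynamic layer (region matching, Venn, progression,
sign changes).  Every output table carries the configuration hash; a
machine-readable manifest records versions and the seed.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossval import detection_frequency, run_cv
from .dynamics import (marker_venn_counts, match_regions, progression_scan,
                       regions_to_frame, sign_change_report, venn_counts)
from .epistasis import EpistasisScan
from .io import (RunConfig, families_from_phenotypes, read_genotypes,
                 read_map, read_phenotypes, write_table)
from .phenotype import compute_blues, estimate_variance_components, \
    stage_correlations
from .scan import AssociationScan
from .variance import proportion_genotypic_variance, temporal_pg_profile


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, gmap=None, genotypes=None, pheno=None
                 ) -> dict:
    """Run the full analysis described by ``config``.

    In-memory inputs may be supplied directly (``gmap``, ``genotypes``,
    ``pheno``); otherwise they are read from the configured paths.  Result
    tables are written under ``config.out_dir``; the returned dict holds
    the in-memory result objects.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = {"config_hash": config.config_hash(), "tool": f"dynqtl "
           f"{__version__}"}
    results: dict = {}

    def stage_guard(name):
        class _Guard:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Guard()

    with stage_guard("load"):
        if gmap is None:
            gmap = read_map(config.map)
        if pheno is None:
            pheno = read_phenotypes(config.phenotypes)
        if genotypes is None:
            genotypes = read_genotypes(
                config.genotypes, families_from_phenotypes(pheno), gmap)
        stages = [s for s in config.stages if s in pheno.columns]
        if not stages:
            raise ValueError("no configured stage found in phenotype table")
    results["gmap"], results["genotypes"], results["pheno"] = \
        gmap, genotypes, pheno
    config.to_yaml(out / "config.yaml")

    with stage_guard("blues"):
        blues = {s: compute_blues(pheno, s) for s in stages}
        frame = pd.concat([b.to_frame() for b in blues.values()], axis=1)
        frame.insert(0, "family", families_from_phenotypes(pheno
                                                           ).reindex(
            frame.index))
        frame.index.name = "line"
        write_table(frame, out / "blues.tsv", {**tag, "stage": "blues"},
                    index=True)
    results["blues"] = blues

    with stage_guard("variance_components"):
        vc = {s: estimate_variance_components(pheno, s) for s in stages}
        write_table(pd.concat([v.summary() for v in vc.values()]),
                    out / "variance_components.tsv",
                    {**tag, "stage": "variance_components"})
        if len(stages) > 1:
            corr, corr_p = stage_correlations([blues[s] for s in stages])
            write_table(corr.reset_index(names="stage"),
                        out / "stage_correlations.tsv",
                        {**tag, "stage": "variance_components"})
            results["stage_correlations"] = (corr, corr_p)
    results["variance_components"] = vc

    with stage_guard("scan"):
        scans = {}
        for s in stages:
            scans[s] = AssociationScan(
                blues[s], genotypes, gmap, config.alpha,
                config.cofactor_window_cm).fit()
            write_table(scans[s].table, out / f"qtl_{s}.tsv",
                        {**tag, "stage": f"scan:{s}",
                         "cofactors": ",".join(scans[s].cofactors)})
    results["scans"] = scans

    with stage_guard("episcan"):
        episcans = {}
        for s in stages:
            model = EpistasisScan(
                blues[s], genotypes, gmap, config.alpha,
                n_linkage_groups=config.linkage_groups,
                thin_cm=config.epistasis_thin_cm)
            episcans[s] = model.fit()
            write_table(episcans[s].table, out / f"epistasis_{s}.tsv",
                        {**tag, "stage": f"episcan:{s}",
                         "threshold": f"{model.threshold:.6g}"})
    results["episcans"] = episcans

    with stage_guard("qtl_variance"):
        accounts = {}
        rows = []
        for s in stages:
            detected = scans[s].significant_table["marker"].tolist()
            accounts[s] = proportion_genotypic_variance(
                blues[s], genotypes, detected, vc[s].h2,
                pvalues=scans[s].pvalues(), stage=s)
            sh = accounts[s].shares.copy()
            sh.insert(0, "stage", s)
            rows.append(sh)
        write_table(pd.concat(rows) if rows else pd.DataFrame(),
                    out / "qtl_variance.tsv",
                    {**tag, "stage": "qtl_variance"})
    results["accounts"] = accounts

    with stage_guard("cross_validation"):
        cvs = {}
        rng = np.random.default_rng(config.seed)
        for s in stages:
            cvs[s] = run_cv(blues[s], genotypes, gmap, vc[s].h2,
                            runs=config.cv_runs, folds=config.cv_folds,
                            seed=int(rng.integers(2 ** 31)),
                            alpha=config.alpha,
                            cofactor_window=config.cofactor_window_cm,
                            stage=s)
        table1 = pd.concat([cvs[s].to_frame() for s in stages], axis=1)
        write_table(table1.reset_index(), out / "cross_validation.tsv",
                    {**tag, "stage": "cross_validation"})
        freq = pd.concat([detection_frequency(cvs[s], gmap,
                                              config.overlap_window_cm)
                          .assign(stage=s) for s in stages])
        write_table(freq, out / "detection_frequency.tsv",
                    {**tag, "stage": "cross_validation"})
    results["cv"] = cvs

    with stage_guard("dynamics"):
        regions = match_regions(scans, config.overlap_window_cm, gmap)
        write_table(regions_to_frame(regions), out / "regions.tsv",
                    {**tag, "stage": "dynamics"})
        venn = venn_counts(regions, tuple(stages))
        mvenn = marker_venn_counts(scans, tuple(stages))
        write_table(pd.DataFrame({"venn_class": venn.index,
                                  "regions": venn.to_numpy(),
                                  "markers": mvenn.to_numpy()}),
                    out / "venn.tsv", {**tag, "stage": "dynamics"})
        write_table(sign_change_report(regions), out / "sign_changes.tsv",
                    {**tag, "stage": "dynamics"})
        profile = temporal_pg_profile(
            regions, blues, scans, genotypes,
            {s: vc[s].h2 for s in stages})
        write_table(profile, out / "temporal_pg.tsv",
                    {**tag, "stage": "dynamics"})
        progression = {}
        for a, b in zip(stages[:-1], stages[1:]):
            try:
                prog = progression_scan(blues[a], blues[b], genotypes, gmap,
                                        config.alpha,
                                        config.cofactor_window_cm)
            except ValueError:
                continue
            progression[f"{a}-{b}"] = prog
            write_table(prog.table, out / f"progression_{a}_{b}.tsv",
                        {**tag, "stage": "dynamics"})
    results["regions"] = regions
    results["venn"] = venn
    results["progression"] = progression

    manifest = {
        "tool": "dynqtl",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(stages),
        "n_lines": genotypes.n_lines,
        "n_markers": genotypes.n_markers,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
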