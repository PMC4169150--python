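"""Tabular I/O and run configuration.

Canonical table dialect: tab-separated UTF-8 with ``NA`` as the missing
token; CSV is accepted on read.  Output tables written by the pipeline
carry ``#``-prefixed header comments recording the configuration hash and
pipeline stage, so every file is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .gmap import GeneticMap

NA = "NA"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_table(df: pd.DataFrame, path, comments: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), comment="#", na_values=[NA])


# ---------------------------------------------------------------------------
# Domain readers/writers
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    df = read_table(path)
    df.columns = [c.lower() for c in df.columns]
    return GeneticMap(df[["marker", "group", "cm"]])


def write_map(gmap: GeneticMap, path, comments=None) -> None:
    write_table(gmap.table, path, comments)


def read_genotypes(path, families: pd.Series | None = None,
                   gmap: GeneticMap | None = None) -> GenotypeMatrix:
    """Read a genotype TSV: first column line id, one column per marker.

    Values must be 0, 1 or NA.  Duplicate line ids are an error; non-binary
    values are an error naming the offending cell.  If a map is given,
    markers present in only one of the two are reported as a warning.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#", na_values=[NA],
                     index_col=0)
    if df.index.duplicated().any():
        dups = list(df.index[df.index.duplicated()])[:5]
        raise ValueError(f"duplicate line ids: {dups}")
    calls = df.to_numpy(dtype=float)
    ok = np.isnan(calls) | (calls == 0.0) | (calls == 1.0)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(f"non-binary genotype at line {df.index[i]} "
                         f"marker {df.columns[j]}")
    if families is None:
        families = pd.Series("ALL", index=df.index)
    geno = GenotypeMatrix(calls, df.index, df.columns, families)
    if gmap is not None:
        only_geno = sorted(set(df.columns) - set(gmap.markers))
        only_map = sorted(set(gmap.markers) - set(df.columns))
        if only_geno or only_map:
            warnings.warn(
                f"genotype/map marker mismatch: {len(only_geno)} markers "
                f"only in genotypes {only_geno[:5]}, {len(only_map)} only "
                f"in map {only_map[:5]}")
    return geno


def write_genotypes(geno: GenotypeMatrix, path, comments=None) -> None:
    df = geno.to_frame()
    df.index.name = "line"
    write_table(df, path, comments, index=True)


def read_phenotypes(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"line", "family", "environment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    stages = [c for c in df.columns if c not in required]
    if not stages:
        raise ValueError("phenotype table has no trait columns")
    return df


def write_phenotypes(pheno: pd.DataFrame, path, comments=None) -> None:
    write_table(pheno, path, comments)


def families_from_phenotypes(pheno: pd.DataFrame) -> pd.Series:
    fam = pheno.drop_duplicates("line").set_index("line")["family"]
    return fam


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    genotypes: str = ""
    map: str = ""
    phenotypes: str = ""
    out_dir: str = "dynqtl_out"
    stages: tuple = ("DS1", "DS2", "DS3")
    alpha: float = 0.05
    cofactor_window_cm: float = 10.0
    overlap_window_cm: float = 5.0
    epistasis_thin_cm: float = 0.0
    linkage_groups: int | None = None   # None = from the map
    cv_runs: int = 20
    cv_folds: int = 5
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("cofactor_window_cm", "overlap_window_cm",
                     "epistasis_thin_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.linkage_groups is not None and self.linkage_groups < 1:
            raise ValueError("linkage_groups must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_runs < 1:
            raise ValueError("cv_runs must be >= 1")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if len(self.stages) < 1:
            raise ValueError("need at least one stage label")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras.update(extras)
        if "stages" in kwargs:
            cfg.stages = tuple(kwargs["stages"])
        return cfg.validate()

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        data = asdict(self)
        data["stages"] = list(self.stages)
        data.pop("out_dir", None)
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
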