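"""Simulation of partially connected multi-family DH populations.

The generator emulates a multi-parent doubled-haploid (DH) mapping study:
fully homozygous parents, one meiosis per DH line (Haldane map function, no
interference), and repeated developmental phenotypes driven by persistent,
stage-specific, sign-switching and epistatic QTL on top of a polygenic
background, genotype-by-environment interaction and plot error.

Variance components of the default preset are calibrated analytically so
that entry-mean heritabilities and between-stage correlations of the line
means match the targets stored in :data:`PRESET_TARGETS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gmap import GeneticMap

STAGES = ("DS1", "DS2", "DS3")

#: Calibration targets of the default study preset: entry-mean
#: heritabilities per stage, between-stage correlations of line means,
#: genotypic variances (BBCH**2 units), environments and replication.
PRESET_TARGETS = {
    "h2": np.array([0.90, 0.85, 0.72]),
    "r_blue": np.array([[1.0, 0.84, 0.69],
                        [0.84, 1.0, 0.74],
                        [0.69, 0.74, 1.0]]),
    "sigma2_g": np.array([2.5, 2.0, 1.8]),
    "n_environments": 4,
    "replicate_fraction": 0.2,
    "error_split": 2.0,     # sigma2_eps / sigma2_ge
    "rho_residual": 0.6,    # cross-stage correlation of GE and plot error
    "stage_means": np.array([49.0, 69.0, 81.0]),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CrossingDesign:
    """Parents and families of a (partially connected) crossing design."""

    parents: list
    families: list  # (family label, parent A, parent B, n_lines)

    def __post_init__(self) -> None:
        pset = set(self.parents)
        for fam, pa, pb, n in self.families:
            if pa == pb:
                raise ValueError(f"family {fam}: parents must be distinct")
            if pa not in pset or pb not in pset:
                raise ValueError(f"family {fam}: unknown parent")
            if n < 1:
                raise ValueError(f"family {fam}: n_lines must be >= 1")

    @property
    def n_lines(self) -> int:
        return sum(n for *_, n in self.families)

    @property
    def family_sizes(self) -> dict:
        return {fam: n for fam, _, _, n in self.families}

    def parent_degree(self) -> dict:
        """Number of families each parent contributes to."""
        deg = {p: 0 for p in self.parents}
        for _, pa, pb, _ in self.families:
            deg[pa] += 1
            deg[pb] += 1
        return deg


@dataclass
class QTLEffect:
    marker: str
    effects: np.ndarray       # allele-substitution effect per stage
    qtl_class: str            # persistent | stage_specific | sign_switching

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        b = self.effects
        if self.qtl_class == "persistent":
            if np.any(b == 0.0):
                raise ValueError(
                    f"persistent QTL {self.marker} has a zero-effect stage")
        elif self.qtl_class == "stage_specific":
            if not np.any(b == 0.0):
                raise ValueError(
                    f"stage-specific QTL {self.marker} has no zero stage")
        elif self.qtl_class == "sign_switching":
            nz = b[b != 0.0]
            if len(nz) < 2 or nz.min() >= 0 or nz.max() <= 0:
                raise ValueError(
                    f"sign-switching QTL {self.marker} does not change sign")
        else:
            raise ValueError(f"unknown QTL class {self.qtl_class!r}")


@dataclass
class EpistaticPair:
    marker_a: str
    marker_b: str
    effects: np.ndarray       # interaction effect per stage

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.marker_a == self.marker_b:
            raise ValueError("epistatic pair must involve two distinct markers")


@dataclass
class TraitArchitecture:
    """Time-indexed genetic architecture of the simulated trait.

    ``sigma2_polygenic`` is a stages x stages covariance matrix of the
    normally distributed polygenic background (its off-diagonal entries
    create the between-stage genetic correlation that individual QTL do not
    supply).  ``rho_residual`` correlates the GE and plot-error deviations of
    one plot across stages -- the same plot is scored repeatedly in time.
    """

    stages: tuple = STAGES
    stage_means: np.ndarray = field(
        default_factory=lambda: PRESET_TARGETS["stage_means"].copy())
    qtl: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)
    family_means: dict = field(default_factory=dict)
    sigma2_polygenic: np.ndarray = None
    sigma2_ge: np.ndarray = None
    sigma2_eps: np.ndarray = None
    rho_residual: float = 0.0
    n_environments: int = 4
    replicate_fraction: float = 0.2

    def __post_init__(self) -> None:
        S = len(self.stages)
        self.stage_means = np.asarray(self.stage_means, dtype=float)
        if self.sigma2_polygenic is None:
            self.sigma2_polygenic = np.zeros((S, S))
        if self.sigma2_ge is None:
            self.sigma2_ge = np.zeros(S)
        if self.sigma2_eps is None:
            self.sigma2_eps = np.zeros(S)
        self.sigma2_polygenic = np.asarray(self.sigma2_polygenic, dtype=float)
        self.sigma2_ge = np.asarray(self.sigma2_ge, dtype=float)
        self.sigma2_eps = np.asarray(self.sigma2_eps, dtype=float)
        if np.any(self.sigma2_ge < 0) or np.any(self.sigma2_eps < 0):
            raise ValueError("negative variance component")
        if np.any(np.diag(self.sigma2_polygenic) < 0):
            raise ValueError("negative polygenic variance")
        if np.linalg.eigvalsh(self.sigma2_polygenic).min() < -1e-8:
            raise ValueError("polygenic covariance matrix not PSD")
        for q in self.qtl:
            if len(q.effects) != S:
                raise ValueError(f"QTL {q.marker}: wrong number of stages")

    @property
    def qtl_markers(self) -> list:
        return [q.marker for q in self.qtl]

    def check_markers(self, gmap: GeneticMap) -> None:
        refs = set(self.qtl_markers)
        for pair in self.epistatic_pairs:
            refs.update((pair.marker_a, pair.marker_b))
        unknown = sorted(m for m in refs if not gmap.has_marker(m))
        if unknown:
            raise ValueError(f"architecture markers absent from map: {unknown}")


# ---------------------------------------------------------------------------
# Parent and DH genotype simulation
# ---------------------------------------------------------------------------

def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_parents(gmap: GeneticMap, n_parents: int, seed=None,
                     design: CrossingDesign | None = None,
                     force_segregating=(), max_retries: int = 100
                     ) -> pd.DataFrame:
    """Draw fully homozygous founder haplotypes.

    Alleles are drawn per marker so that every marker is polymorphic among
    the parents of at least one family of ``design`` (or among all parents
    if no design is given); monomorphic columns are resampled up to
    ``max_retries`` times.  Markers in ``force_segregating`` are assigned
    alleles that segregate within *every* family (used for preset QTL so the
    genetic variance they generate is predictable).
    """
    if n_parents < 2:
        raise ValueError("need at least two parents")
    rng = _rng(seed)
    if design is not None:
        names = list(design.parents)
        if len(names) != n_parents:
            raise ValueError("n_parents does not match design")
    else:
        names = [f"P{i + 1}" for i in range(n_parents)]
    m = gmap.n_markers
    alleles = (rng.random((n_parents, m)) < 0.5).astype(float)
    idx = {p: i for i, p in enumerate(names)}

    def _bad_columns() -> np.ndarray:
        if design is None:
            return np.flatnonzero(np.all(alleles == alleles[0], axis=0))
        ok = np.zeros(m, dtype=bool)
        for _, pa, pb, _ in design.families:
            ok |= alleles[idx[pa]] != alleles[idx[pb]]
        return np.flatnonzero(~ok)

    bad = _bad_columns()
    for _ in range(max_retries):
        if bad.size == 0:
            break
        alleles[:, bad] = (rng.random((n_parents, bad.size)) < 0.5)
        bad = _bad_columns()
    if bad.size:
        labels = list(gmap.markers[bad][:10])
        raise RuntimeError(
            f"could not make markers polymorphic after {max_retries} retries: "
            f"{labels}")

    if force_segregating:
        if design is None:
            raise ValueError("force_segregating requires a crossing design")
        col = {mk: j for j, mk in enumerate(gmap.markers)}
        for mk in force_segregating:
            assigned: dict = {}
            for _, pa, pb, _ in design.families:
                if pa in assigned and pb in assigned:
                    if assigned[pa] == assigned[pb]:
                        raise RuntimeError(
                            f"cannot force marker {mk} to segregate in every "
                            f"family: crossing design constrains parents "
                            f"{pa} and {pb} to equal alleles")
                elif pa in assigned:
                    assigned[pb] = 1.0 - assigned[pa]
                elif pb in assigned:
                    assigned[pa] = 1.0 - assigned[pb]
                else:
                    a = float(rng.integers(0, 2))
                    assigned[pa] = a
                    assigned[pb] = 1.0 - a
            j = col[mk]
            for p, a in assigned.items():
                alleles[idx[p], j] = a
    return pd.DataFrame(alleles, index=names, columns=gmap.markers)


def simulate_dh_family(parent_a: pd.Series, parent_b: pd.Series,
                       n_lines: int, gmap: GeneticMap, seed=None
                       ) -> np.ndarray:
    """Simulate DH lines from a biparental cross.

    Each line is one recombinant F1 gamete with its genome doubled:
    homozygous everywhere, alleles drawn from the two parents, with
    recombination between adjacent markers at Haldane probability
    ``r = 0.5 (1 - exp(-2 d / 100))`` independently across intervals and
    lines (no interference).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = _rng(seed)
    for s, name in ((parent_a, "A"), (parent_b, "B")):
        missing = gmap.markers.difference(s.index)
        if len(missing):
            raise KeyError(
                f"parent {name} lacks markers on the map: {list(missing[:5])}")
    a = parent_a.reindex(gmap.markers).to_numpy(dtype=float)
    b = parent_b.reindex(gmap.markers).to_numpy(dtype=float)
    out = np.empty((n_lines, gmap.n_markers))
    table = gmap.table
    for g in gmap.groups:
        cols = np.flatnonzero((table["group"] == g).to_numpy())
        pos = table["cm"].to_numpy()[cols]
        r = haldane_r(np.diff(pos))
        k = len(cols)
        switches = np.empty((n_lines, k))
        switches[:, 0] = rng.integers(0, 2, size=n_lines)
        if k > 1:
            switches[:, 1:] = rng.random((n_lines, k - 1)) < r
        parent_idx = np.cumsum(switches, axis=1) % 2
        out[:, cols] = np.where(parent_idx == 0, a[cols], b[cols])
    return out


def simulate_genotypes(gmap: GeneticMap, design: CrossingDesign, seed=None,
                       force_segregating=(), parents: pd.DataFrame | None = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate all families of a crossing design (complete calls)."""
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    children = ss.spawn(1 + len(design.families))
    if parents is None:
        parents = simulate_parents(
            gmap, len(design.parents), np.random.default_rng(children[0]),
            design=design, force_segregating=force_segregating)
    blocks, lines, fams = [], [], []
    for (fam, pa, pb, n), child in zip(design.families, children[1:]):
        blocks.append(simulate_dh_family(
            parents.loc[pa], parents.loc[pb], n, gmap,
            np.random.default_rng(child)))
        lines.extend(f"{fam}_{i + 1:03d}" for i in range(n))
        fams.extend([fam] * n)
    calls = np.vstack(blocks)
    geno = GenotypeMatrix(calls, pd.Index(lines), gmap.markers,
                          pd.Series(fams, index=lines))
    return geno, parents


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def _compound_symmetric_cov(sd: np.ndarray, rho: float) -> np.ndarray:
    S = len(sd)
    R = np.full((S, S), rho)
    np.fill_diagonal(R, 1.0)
    return R * np.outer(sd, sd)


def _chol(cov: np.ndarray) -> np.ndarray:
    # Tolerant Cholesky: zero-variance stages are allowed.
    S = cov.shape[0]
    if not np.any(cov):
        return np.zeros_like(cov)
    jitter = 1e-12 * np.trace(cov) / S
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(S))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))


def genetic_values(genotypes: GenotypeMatrix, arch: TraitArchitecture
                   ) -> pd.DataFrame:
    """True genetic value per line and stage (family mean + QTL + pairs).

    The polygenic deviation is *not* included here; it is drawn inside
    :func:`simulate_phenotypes` so that genetic values stay a pure function
    of the genotypes.
    """
    S = len(arch.stages)
    g = np.zeros((genotypes.n_lines, S))
    fam = genotypes.families.to_numpy()
    for f, means in arch.family_means.items():
        g[fam == f] += np.asarray(means, dtype=float)
    for q in arch.qtl:
        x = genotypes.column(q.marker)
        if np.isnan(x).any():
            raise ValueError(f"missing calls at architecture marker {q.marker}")
        g += np.outer(x, q.effects)
    for pair in arch.epistatic_pairs:
        xa = genotypes.column(pair.marker_a)
        xb = genotypes.column(pair.marker_b)
        if np.isnan(xa).any() or np.isnan(xb).any():
            raise ValueError(
                f"missing calls at architecture markers "
                f"{pair.marker_a}/{pair.marker_b}")
        g += np.outer(xa * xb, pair.effects)
    return pd.DataFrame(g, index=genotypes.lines, columns=list(arch.stages))


def simulate_phenotypes(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                        seed=None, round_bbch: bool = False,
                        return_truth: bool = False):
    """Simulate plot-level phenotypes.

    For line i, environment j, stage t::

        y_ijt = stage_mean_t + family_mean_f(i),t + sum_q x_iq b_q(t)
                + sum_(q,q') x_iq x_iq' b_qq'(t) + polygenic_i(t)
                + ge_ij(t) + eps_ijt

    with ``ge ~ N(0, sigma2_ge(t))`` and ``eps ~ N(0, sigma2_eps(t))``, both
    correlated across stages with ``rho_residual`` (one plot is scored at
    all stages).  A fraction ``replicate_fraction`` of lines is observed
    twice per environment (partial replication); the rest once.

    Returns a long-format DataFrame with columns
    ``line, family, environment, replicate`` plus one column per stage.
    With ``return_truth=True`` also returns the per-line total genetic
    values (QTL + polygenic) per stage.
    """
    rng = _rng(seed)
    S = len(arch.stages)
    n = genotypes.n_lines
    E = arch.n_environments
    g = genetic_values(genotypes, arch).to_numpy()

    poly = rng.standard_normal((n, S)) @ _chol(arch.sigma2_polygenic).T
    g_total = g + poly

    ge_cov = _compound_symmetric_cov(np.sqrt(arch.sigma2_ge), arch.rho_residual)
    ge = rng.standard_normal((n, E, S)) @ _chol(ge_cov).T

    rows_line, rows_env, rows_rep = [], [], []
    n_rep = int(round(arch.replicate_fraction * n))
    for j in range(E):
        rows_line.append(np.arange(n))
        rows_env.append(np.full(n, j))
        rows_rep.append(np.ones(n, dtype=int))
        if n_rep:
            extra = rng.choice(n, size=n_rep, replace=False)
            rows_line.append(extra)
            rows_env.append(np.full(n_rep, j))
            rows_rep.append(np.full(n_rep, 2, dtype=int))
    li = np.concatenate(rows_line)
    ej = np.concatenate(rows_env)
    rep = np.concatenate(rows_rep)

    eps_cov = _compound_symmetric_cov(np.sqrt(arch.sigma2_eps),
                                      arch.rho_residual)
    eps = rng.standard_normal((len(li), S)) @ _chol(eps_cov).T

    y = arch.stage_means[None, :] + g_total[li] + ge[li, ej] + eps
    if round_bbch:
        y = np.round(y)
    pheno = pd.DataFrame({
        "line": genotypes.lines.to_numpy()[li],
        "family": genotypes.families.to_numpy()[li],
        "environment": np.array([f"E{j + 1}" for j in ej]),
        "replicate": rep,
    })
    for s, stage in enumerate(arch.stages):
        pheno[stage] = y[:, s]
    pheno = pheno.sort_values(
        ["environment", "line", "replicate"], kind="stable").reset_index(
        drop=True)
    if return_truth:
        truth = pd.DataFrame(g_total, index=genotypes.lines,
                             columns=list(arch.stages))
        return pheno, truth
    return pheno


# ---------------------------------------------------------------------------
# Analytic calibration
# ---------------------------------------------------------------------------

def architecture_moments(arch: TraitArchitecture, family_props: dict
                         ) -> np.ndarray:
    """Stages x stages covariance of the marker-determined genetic value.

    Assumes every QTL segregates at frequency 1/2 within every family and
    that distinct QTL blocks (single markers, epistatic pairs) are unlinked
    -- exactly how the default preset places them.  Family-mean differences
    are included.
    """
    S = len(arch.stages)
    cov = np.zeros((S, S))
    pair_members = set()
    for pair in arch.epistatic_pairs:
        pair_members.update((pair.marker_a, pair.marker_b))
    mains = {q.marker: q.effects for q in arch.qtl}
    for q in arch.qtl:
        if q.marker in pair_members:
            continue
        cov += 0.25 * np.outer(q.effects, q.effects)
    for pair in arch.epistatic_pairs:
        a1 = mains.get(pair.marker_a, np.zeros(S))
        a2 = mains.get(pair.marker_b, np.zeros(S))
        c = pair.effects
        # Enumerate the four equi-probable two-locus classes.
        vals = np.array([np.zeros(S), a2, a1, a1 + a2 + c])  # (4, S)
        mu = vals.mean(axis=0)
        cov += (vals - mu).T @ (vals - mu) / 4.0
    if arch.family_means:
        props = np.array([family_props[f] for f in arch.family_means])
        means = np.array([np.asarray(arch.family_means[f], dtype=float)
                          for f in arch.family_means])
        mbar = props @ means
        cov += (means - mbar).T @ ((means - mbar) * props[:, None])
    return cov


def calibrate_architecture(arch: TraitArchitecture, design: CrossingDesign,
                           sigma2_g: np.ndarray, h2: np.ndarray,
                           r_blue: np.ndarray, error_split: float,
                           rho_residual: float) -> TraitArchitecture:
    """Fill in polygenic, GE and error variances to hit the targets.

    Solves the entry-mean identities for the study design: with E
    environments and harmonic-mean replication r_bar, the line-mean error
    variance is ``err = s2_ge/E + s2_eps/(E r_bar)`` and
    ``h2 = s2_g / (s2_g + err)``.  The polygenic covariance absorbs whatever
    genotypic variance and between-stage covariance the markers do not
    supply.
    """
    S = len(arch.stages)
    sigma2_g = np.asarray(sigma2_g, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    total = design.n_lines
    props = {f: n / total for f, n in design.family_sizes.items()}
    cov_m = architecture_moments(arch, props)

    E = arch.n_environments
    frac = arch.replicate_fraction
    r_bar = 1.0 / (1.0 - frac + frac / 2.0)
    err = sigma2_g * (1.0 / h2 - 1.0)
    s2_ge = err / (1.0 / E + error_split / (E * r_bar))
    s2_eps = error_split * s2_ge

    P = sigma2_g + err
    poly = np.empty((S, S))
    for t in range(S):
        for u in range(S):
            if t == u:
                poly[t, t] = sigma2_g[t] - cov_m[t, t]
            else:
                cov_blue = r_blue[t, u] * np.sqrt(P[t] * P[u])
                cov_err = rho_residual * np.sqrt(err[t] * err[u])
                poly[t, u] = cov_blue - cov_err - cov_m[t, u]
    if np.any(np.diag(poly) <= 0):
        raise ValueError(
            "marker architecture already exceeds the target genotypic "
            "variance; reduce effects or raise sigma2_g")
    if np.linalg.eigvalsh(poly).min() < -1e-8:
        raise ValueError("calibrated polygenic covariance is not PSD")
    arch.sigma2_polygenic = poly
    arch.sigma2_ge = s2_ge
    arch.sigma2_eps = s2_eps
    arch.rho_residual = rho_residual
    return arch


# ---------------------------------------------------------------------------
# Default study preset
# ---------------------------------------------------------------------------

def default_map(markers_per_chromosome: int = 48) -> GeneticMap:
    """21 nominal chromosomes (1A-7A, 1B-7B, 1R-7R), 140 cM each.

    Chromosome 5R is represented as two linkage groups (5R.1, 5R.2), giving
    L = 22 linkage groups in total.
    """
    chroms = [f"{i}{g}" for g in "ABR" for i in range(1, 8)]
    rows = []
    for c in chroms:
        if c == "5R":
            half = markers_per_chromosome // 2
            for part in ("5R.1", "5R.2"):
                pos = np.linspace(0.0, 67.0, half)
                rows += [(f"{part}_{i:02d}", part, float(p))
                         for i, p in enumerate(pos)]
        else:
            pos = np.linspace(0.0, 140.0, markers_per_chromosome)
            rows += [(f"{c}_{i:02d}", c, float(p))
                     for i, p in enumerate(pos)]
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "group", "cm"]))


def default_design() -> CrossingDesign:
    """Four partially connected families (131/120/200/196) from six parents.

    Families F1 and F2 share parent P1; families F3 and F4 share parent P4
    (two parents of crossing degree 2, four of degree 1).
    """
    return CrossingDesign(
        parents=["P1", "P2", "P3", "P4", "P5", "P6"],
        families=[("F1", "P1", "P2", 131),
                  ("F2", "P1", "P3", 120),
                  ("F3", "P4", "P5", 200),
                  ("F4", "P4", "P6", 196)])


def default_study_preset(markers_per_chromosome: int = 48
                         ) -> tuple[GeneticMap, CrossingDesign,
                                    TraitArchitecture]:
    """Map, crossing design and calibrated trait architecture of the preset.

    The QTL set covers all three temporal classes plus one epistatic pair:

    ========  ==========  ======================  =======================
    marker    group       class                   effects (DS1, DS2, DS3)
    ========  ==========  ======================  =======================
    2A_24     2A          persistent              0.80, 0.70, 0.65
    5R.1_12   5R.1        persistent              0.70, 0.60, 0.55
    4R_24     4R          persistent              -0.60, -0.55, -0.50
    6R_24     6R          stage_specific (DS1)    0.75, 0, 0
    7R_24     7R          stage_specific (DS3)    0, 0, 0.70
    6A_24     6A          sign_switching          0.70, 0, -0.60
    1B_24     1B          persistent (pair main)  0.30, 0.30, 0.30
    5R.2_12   5R.2        persistent (pair main)  0.30, 0.30, 0.30
    1B_24 x 5R.2_12       epistatic interaction   1.10, 1.10, 1.10
    ========  ==========  ======================  =======================

    Effects are in BBCH units per allele dose.  All QTL lie on distinct
    linkage groups and are forced to segregate within every family.
    """
    gmap = default_map(markers_per_chromosome)
    design = default_design()
    mid = markers_per_chromosome // 2
    q = markers_per_chromosome // 4

    def mk(chrom, i):
        return f"{chrom}_{i:02d}"

    qtl = [
        QTLEffect(mk("2A", mid), [0.80, 0.70, 0.65], "persistent"),
        QTLEffect(mk("5R.1", q), [0.70, 0.60, 0.55], "persistent"),
        QTLEffect(mk("4R", mid), [-0.60, -0.55, -0.50], "persistent"),
        QTLEffect(mk("6R", mid), [0.75, 0.0, 0.0], "stage_specific"),
        QTLEffect(mk("7R", mid), [0.0, 0.0, 0.70], "stage_specific"),
        QTLEffect(mk("6A", mid), [0.70, 0.0, -0.60], "sign_switching"),
        QTLEffect(mk("1B", mid), [0.30, 0.30, 0.30], "persistent"),
        QTLEffect(mk("5R.2", q), [0.30, 0.30, 0.30], "persistent"),
    ]
    pairs = [EpistaticPair(mk("1B", mid), mk("5R.2", q), [1.10, 1.10, 1.10])]
    t = PRESET_TARGETS
    arch = TraitArchitecture(
        qtl=qtl,
        epistatic_pairs=pairs,
        family_means={"F1": [0.25] * 3, "F2": [-0.25] * 3,
                      "F3": [0.15] * 3, "F4": [-0.15] * 3},
        n_environments=t["n_environments"],
        replicate_fraction=t["replicate_fraction"],
    )
    arch.check_markers(gmap)
    calibrate_architecture(arch, design, t["sigma2_g"], t["h2"], t["r_blue"],
                           t["error_split"], t["rho_residual"])
    return gmap, design, arch


# ---------------------------------------------------------------------------
# One-call study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    gmap: GeneticMap
    design: CrossingDesign
    arch: TraitArchitecture
    parents: pd.DataFrame
    genotypes: GenotypeMatrix        # with missing calls injected
    genotypes_complete: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: pd.DataFrame              # per-line genetic values per stage
    seed: int | None = None


def simulate_study(seed=None, gmap: GeneticMap | None = None,
                   design: CrossingDesign | None = None,
                   arch: TraitArchitecture | None = None,
                   missing_rate: float = 0.02,
                   round_bbch: bool = False) -> SimulatedStudy:
    """Simulate a complete study (genotypes, phenotypes, truth).

    Phenotypes are generated from the complete genotype calls; missing
    genotype data (default 2 % of calls, emulating failed marker assays) is
    injected afterwards into the genotype matrix handed to analyses.
    """
    if gmap is None or design is None or arch is None:
        pm, pd_, pa = default_study_preset()
        gmap = gmap or pm
        design = design or pd_
        arch = arch or pa
    arch.check_markers(gmap)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    geno_ss, pheno_ss, miss_ss = ss.spawn(3)
    force = sorted({q.marker for q in arch.qtl}
                   | {m for p in arch.epistatic_pairs
                      for m in (p.marker_a, p.marker_b)})
    geno_true, parents = simulate_genotypes(gmap, design, geno_ss,
                                            force_segregating=force)
    pheno, truth = simulate_phenotypes(
        geno_true, arch, np.random.default_rng(pheno_ss),
        round_bbch=round_bbch, return_truth=True)
    calls = geno_true.calls.copy()
    if missing_rate > 0:
        mask = np.random.default_rng(miss_ss).random(calls.shape) < missing_rate
        calls[mask] = np.nan
    geno = GenotypeMatrix(calls, geno_true.lines, geno_true.markers,
                          geno_true.families)
    return SimulatedStudy(gmap, design, arch, parents, geno, geno_true,
                          pheno, truth, seed)
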