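"""Phenotypic layer: line BLUEs, variance components, heritability.

Plot-level observations are reduced per stage to adjusted line means
(BLUEs) from a two-way fixed-effects model (line + environment), and a
random model ``y = mu + env + line + line x env + eps`` (environment fixed,
line and line x env random) is fitted by REML to estimate the genotypic
variance, the genotype-by-environment interaction variance and the plot
error, from which the entry-mean heritability

    h2 = s2_G / (s2_G + s2_GxE / E + s2_eps / (E * r_bar))

follows, with E environments and r_bar the harmonic-mean number of
replicates per line-environment cell.

The REML implementation exploits that, conditional on the environment
means, lines are independent: after collapsing to cell means the marginal
covariance is block diagonal with one small block per line, so the
restricted likelihood costs O(n_lines) per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------

@dataclass
class BlueVector:
    """Per-line adjusted means for one stage.

    ``values`` is indexed by line.  ``n_environments`` and
    ``replication`` (mean plots per line) record the design that produced
    the estimates; ``dropped_lines`` lists lines without any observation.
    """

    values: pd.Series
    stage: str
    n_environments: int
    replication: float
    dropped_lines: list = field(default_factory=list)

    @property
    def lines(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename(self.stage).to_frame()


def _check_stage(pheno: pd.DataFrame, stage: str) -> pd.DataFrame:
    if stage not in pheno.columns:
        raise KeyError(f"stage {stage!r} absent from phenotype table")
    sub = pheno[["line", "environment", stage]].dropna(subset=[stage])
    return sub


def compute_blues(pheno: pd.DataFrame, stage: str) -> BlueVector:
    """Adjusted line means across environments for one stage.

    Fits ``y = line + environment`` by least squares with sum-to-zero
    environment effects, so each line's BLUE is its expected value in an
    average environment.  With balanced data this equals the raw line mean.
    """
    sub = _check_stage(pheno, stage)
    if sub.empty:
        raise ValueError(f"no observations for stage {stage!r}")
    y = sub[stage].to_numpy(dtype=float)
    line_codes, line_levels = pd.factorize(sub["line"], sort=False)
    env_codes, env_levels = pd.factorize(sub["environment"], sort=False)
    E = len(env_levels)

    if E > 1:
        # Sum-coded environment design, line effects absorbed (FWL).
        Z = np.zeros((len(y), E - 1))
        for j in range(E - 1):
            Z[env_codes == j, j] = 1.0
        Z[env_codes == E - 1, :] = -1.0
        counts = np.bincount(line_codes).astype(float)
        y_c = y - (np.bincount(line_codes, weights=y) / counts)[line_codes]
        Z_c = Z.copy()
        for j in range(E - 1):
            Z_c[:, j] -= (np.bincount(line_codes, weights=Z[:, j])
                          / counts)[line_codes]
        gamma, *_ = np.linalg.lstsq(Z_c, y_c, rcond=None)
        tau = np.concatenate([gamma, [-gamma.sum()]])
    else:
        tau = np.zeros(1)
    adj = y - tau[env_codes]
    counts = np.bincount(line_codes).astype(float)
    blues = np.bincount(line_codes, weights=adj) / counts

    all_lines = pd.unique(pheno["line"])
    dropped = [ln for ln in all_lines if ln not in set(line_levels)]
    values = pd.Series(blues, index=pd.Index(line_levels, name="line"))
    values = values.reindex([ln for ln in all_lines if ln in set(line_levels)])
    return BlueVector(values, stage, E, float(counts.mean()), dropped)


# ---------------------------------------------------------------------------
# Variance components (REML)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsResults:
    """Estimated components, heritability and boundary-corrected LRT p."""

    stage: str
    sigma2_g: float
    sigma2_ge: float | None
    sigma2_eps: float
    n_environments: int
    r_bar: float
    h2: float
    p_g: float | None
    p_ge: float | None
    loglik: float
    n_lines: int

    def summary(self) -> pd.DataFrame:
        rows = [
            ("sigma2_G", self.sigma2_g, self.p_g),
            ("sigma2_GxE", self.sigma2_ge, self.p_ge),
            ("sigma2_eps", self.sigma2_eps, None),
            ("E", self.n_environments, None),
            ("r_bar", self.r_bar, None),
            ("h2", self.h2, None),
        ]
        return pd.DataFrame(rows, columns=["component", "estimate", "p_value"]
                            ).assign(stage=self.stage)


def _cell_blocks(pheno: pd.DataFrame, stage: str):
    """Collapse plots to line x environment cell means.

    Returns grouped structures keyed by the (environment subset, replicate
    pattern) of each line, plus the pooled within-cell sum of squares that
    identifies the plot error.
    """
    sub = _check_stage(pheno, stage)
    cells = sub.groupby(["line", "environment"], sort=False)[stage].agg(
        ["mean", "count", "var"])
    cells["var"] = cells["var"].fillna(0.0)
    ssw = float((cells["var"] * (cells["count"] - 1)).sum())
    n_within = int((cells["count"] - 1).sum())
    env_levels = list(pd.unique(sub["environment"]))
    env_index = {e: j for j, e in enumerate(env_levels)}

    groups: dict = {}
    for line, block in cells.groupby(level=0, sort=False):
        envs = tuple(env_index[e] for e in block.index.get_level_values(1))
        reps = tuple(int(c) for c in block["count"])
        key = (envs, reps)
        groups.setdefault(key, []).append(block["mean"].to_numpy())
    grouped = {k: np.asarray(v) for k, v in groups.items()}
    return grouped, len(env_levels), ssw, n_within, cells


def _reml_objective(grouped: dict, n_env: int, ssw: float, n_within: int):
    """Return f(log-variances) = -2 * restricted log-likelihood (+const)."""

    scale = max(np.var(np.concatenate(
        [Y.ravel() for Y in grouped.values()])), _VAR_FLOOR)

    def nll(theta: np.ndarray, fix_g=None, fix_ge=None) -> float:
        # Relative floors keep V invertible when a component runs to zero.
        floor = 1e-10 * scale
        s2g = np.exp(theta[0]) if fix_g is None else fix_g
        s2ge = np.exp(theta[1]) if fix_ge is None else fix_ge
        s2e = np.exp(theta[2])
        s2g, s2ge, s2e = max(s2g, floor), max(s2ge, floor), max(s2e, floor)
        logdet = 0.0
        xtvix = np.zeros((n_env, n_env))
        xtviy = np.zeros(n_env)
        ytviy = 0.0
        for (envs, reps), Y in grouped.items():
            k = len(envs)
            d = s2ge + s2e / np.asarray(reps, dtype=float)
            V = np.full((k, k), s2g) + np.diag(d)
            sign, ld = np.linalg.slogdet(V)
            Vi = np.linalg.inv(V)
            m = Y.shape[0]
            logdet += m * ld
            cols = np.asarray(envs)
            xtvix[np.ix_(cols, cols)] += m * Vi
            s = Y.sum(axis=0)
            xtviy[cols] += Vi @ s
            ytviy += float(np.einsum("ij,jk,ik->", Y, Vi, Y))
        sign, ld_x = np.linalg.slogdet(xtvix)
        beta = np.linalg.solve(xtvix, xtviy)
        quad = ytviy - float(beta @ xtviy)
        val = logdet + ld_x + quad
        if n_within > 0:
            val += n_within * np.log(s2e) + ssw / s2e
        return val

    return nll


def _fit_reml(nll, start: np.ndarray, fix_g=None, fix_ge=None):
    def wrapped(t):
        theta = start.copy()
        theta[free] = t
        return nll(theta, fix_g=fix_g, fix_ge=fix_ge)

    free = np.ones(3, dtype=bool)
    if fix_g is not None:
        free[0] = False
    if fix_ge is not None:
        free[1] = False
    res = optimize.minimize(wrapped, start[free], method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 4000})
    theta = start.copy()
    theta[free] = res.x
    return theta, float(res.fun)


class VarianceComponentsModel:
    """REML fit of ``y = mu + env + line + line x env + eps`` for one stage."""

    def __init__(self, pheno: pd.DataFrame, stage: str):
        sub = _check_stage(pheno, stage)
        if sub["line"].nunique() < 2:
            raise ValueError("need at least two lines")
        self.pheno = pheno
        self.stage = stage

    def fit(self) -> VarianceComponentsResults:
        grouped, n_env, ssw, n_within, cells = _cell_blocks(
            self.pheno, self.stage)
        n_lines = int(sum(v.shape[0] for v in grouped.values()))
        r_bar = float(len(cells) / (1.0 / cells["count"]).sum())

        if n_env < 2:
            return self._fit_single_env(grouped, ssw, n_within, cells,
                                        n_lines, r_bar)

        # Moment-based starting values.
        line_means = cells["mean"].groupby(level=0).mean()
        v_tot = float(line_means.var())
        s2e0 = ssw / max(n_within, 1) if n_within else 0.25 * max(v_tot, 1.0)
        s2e0 = max(s2e0, 1e-3 * max(v_tot, 1.0))
        resid = cells["mean"] - cells["mean"].groupby(level=0).transform("mean")
        s2ge0 = max(float(resid.var()) - s2e0, 0.1 * s2e0)
        s2g0 = max(v_tot - s2ge0 / n_env - s2e0 / n_env, 0.1 * max(v_tot, 1.0))
        start = np.log(np.array([s2g0, s2ge0, s2e0]) + _VAR_FLOOR)

        nll = _reml_objective(grouped, n_env, ssw, n_within)
        theta, f_full = _fit_reml(nll, start)
        s2g, s2ge, s2e = np.exp(theta)

        # Boundary-corrected LRTs against the models without each term.
        _, f_nog = _fit_reml(nll, theta.copy(), fix_g=_VAR_FLOOR)
        _, f_noge = _fit_reml(nll, theta.copy(), fix_ge=_VAR_FLOOR)
        lrt_g = max(f_nog - f_full, 0.0)
        lrt_ge = max(f_noge - f_full, 0.0)
        p_g = 0.5 * float(stats.chi2.sf(lrt_g, 1))
        p_ge = 0.5 * float(stats.chi2.sf(lrt_ge, 1))

        # Clamp numerically-boundary components at zero.
        scale = s2g + s2ge + s2e
        s2g = 0.0 if s2g < 1e-8 * scale else float(s2g)
        s2ge = 0.0 if s2ge < 1e-8 * scale else float(s2ge)
        denom = s2g + s2ge / n_env + s2e / (n_env * r_bar)
        h2 = s2g / denom if denom > 0 else np.nan
        return VarianceComponentsResults(
            self.stage, s2g, s2ge, float(s2e), n_env, r_bar, float(h2),
            p_g, p_ge, -0.5 * f_full, n_lines)

    def _fit_single_env(self, grouped, ssw, n_within, cells, n_lines, r_bar):
        # GxE inestimable with one environment; reduced model line + eps.
        nll = _reml_objective(grouped, 1, ssw, n_within)
        line_means = cells["mean"].groupby(level=0).mean()
        v_tot = float(line_means.var()) or 1.0
        start = np.log(np.array([0.5 * v_tot, _VAR_FLOOR, 0.5 * v_tot])
                       + _VAR_FLOOR)
        theta, f_full = _fit_reml(nll, start, fix_ge=_VAR_FLOOR)
        s2g, _, s2e = np.exp(theta)
        _, f_nog = _fit_reml(nll, theta.copy(), fix_g=_VAR_FLOOR,
                             fix_ge=_VAR_FLOOR)
        p_g = 0.5 * float(stats.chi2.sf(max(f_nog - f_full, 0.0), 1))
        denom = s2g + s2e / r_bar
        h2 = s2g / denom if denom > 0 else np.nan
        return VarianceComponentsResults(
            self.stage, float(s2g), None, float(s2e), 1, r_bar, float(h2),
            p_g, None, -0.5 * f_full, n_lines)


def estimate_variance_components(pheno: pd.DataFrame, stage: str
                                 ) -> VarianceComponentsResults:
    """Convenience wrapper around :class:`VarianceComponentsModel`."""
    return VarianceComponentsModel(pheno, stage).fit()


def entry_mean_h2(sigma2_g: float, sigma2_ge: float, sigma2_eps: float,
                  n_env: int, r_bar: float) -> float:
    """Entry-mean heritability from given components and design numbers."""
    return sigma2_g / (sigma2_g + sigma2_ge / n_env
                       + sigma2_eps / (n_env * r_bar))


# ---------------------------------------------------------------------------
# Between-stage correlations
# ---------------------------------------------------------------------------

def stage_correlations(blues: list[BlueVector]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between stage BLUEs on shared lines.

    Returns ``(r, p)`` DataFrames indexed by stage.  Requires at least
    three shared lines per pair.
    """
    stages = [b.stage for b in blues]
    r = pd.DataFrame(np.eye(len(blues)), index=stages, columns=stages)
    p = pd.DataFrame(np.zeros((len(blues), len(blues))), index=stages,
                     columns=stages)
    for i in range(len(blues)):
        for j in range(i + 1, len(blues)):
            shared = blues[i].values.index.intersection(blues[j].values.index)
            if len(shared) < 3:
                raise ValueError(
                    f"fewer than 3 shared lines between {stages[i]} "
                    f"and {stages[j]}")
            res = stats.pearsonr(blues[i].values.loc[shared],
                                 blues[j].values.loc[shared])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return r, p
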