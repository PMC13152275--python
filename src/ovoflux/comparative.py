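"""Comparative statistics: PGLS, simulation-based phylogenetic ANOVA,
group-variance tests, Gaussian model selection, and repeatability (ICC).

The phylogenetic ANOVA follows the Monte-Carlo scheme in which the
observed one-way F statistic is compared against a null distribution
obtained by simulating traits under Brownian motion on the phylogeny
(rate set to the ML Brownian rate of the observed data) with group
labels held fixed.  Simulation p-values use the (1 + exceedances)/(nsim
+ 1) convention so they are never exactly zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ovoflux.phylo import PhyloCovariance, Tree, vcv_matrix
from ovoflux.trait_models import _align, _chol_with_ridge, aicc, akaike_weights

logger = logging.getLogger(__name__)

__all__ = [
    "PGLSFit",
    "AnovaResult",
    "RepeatabilityResult",
    "ModelSelectionTable",
    "pgls",
    "phylo_anova",
    "group_variance_test",
    "glm_model_selection",
    "repeatability_icc",
]


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """Generalized least squares fit under a phylogenetic covariance."""

    params: pd.Series          # coefficient estimates
    bse: pd.Series             # standard errors
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    residuals: pd.Series       # keyed by species
    sigma2: float
    cov_model: str
    n: int
    df_resid: int


def pgls(
    y: Mapping[str, float] | pd.Series,
    X: pd.DataFrame,
    C: PhyloCovariance,
    cov_model: str = "custom",
    add_intercept: bool = True,
) -> PGLSFit:
    """Phylogenetic generalized least squares regression.

    ``y`` is keyed by species; ``X`` is indexed by species.  Rows are
    aligned to the covariance's label order.  With ``C`` the identity the
    estimates coincide with ordinary least squares.
    """
    labels = list(C.labels)
    yv = np.array([float(dict(y)[lab]) for lab in labels])
    Xd = X.loc[labels].copy()
    if add_intercept and "intercept" not in Xd.columns:
        Xd.insert(0, "intercept", 1.0)
    Xm = Xd.to_numpy(dtype=float)
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        corr = np.corrcoef(Xm, rowvar=False)
        bad = [Xd.columns[j] for j in range(p)
               if any(abs(corr[j, k]) > 1 - 1e-10 for k in range(p) if k != j)]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad or list(Xd.columns)}")

    L, _ = _chol_with_ridge(C.matrix)
    Wy = linalg.solve_triangular(L, yv, lower=True)
    WX = linalg.solve_triangular(L, Xm, lower=True)
    beta, _, _, _ = np.linalg.lstsq(WX, Wy, rcond=None)
    e = yv - Xm @ beta
    We = Wy - WX @ beta
    rss = float(We @ We)
    df = n - p
    sigma2 = rss / df if df > 0 else np.nan
    XtCiX_inv = np.linalg.inv(WX.T @ WX)
    bse = np.sqrt(np.maximum(sigma2 * np.diag(XtCiX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)

    # null model: GLS intercept only
    ones = np.ones((n, 1))
    W1 = linalg.solve_triangular(L, ones, lower=True)
    b0 = float((W1[:, 0] @ Wy) / (W1[:, 0] @ W1[:, 0]))
    We0 = Wy - W1[:, 0] * b0
    rss0 = float(We0 @ We0)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    cols = list(Xd.columns)
    return PGLSFit(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        tvalues=pd.Series(tvals, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        r_squared=r2,
        residuals=pd.Series(e, index=labels),
        sigma2=sigma2,
        cov_model=cov_model,
        n=n,
        df_resid=df,
    )


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA and variance test
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p_parametric: float
    p_simulation: float
    nsim: int
    degenerate: bool = False


def _anova_f(x: np.ndarray, gidx: np.ndarray, ngroups: int) -> float:
    """One-way ANOVA F; x may be (n,) or (n, nsim) for vectorised nulls."""
    x = np.atleast_2d(x.T).T  # (n, m)
    n = x.shape[0]
    grand = x.mean(axis=0)
    ssb = np.zeros(x.shape[1])
    ssw = np.zeros(x.shape[1])
    for g in range(ngroups):
        sel = x[gidx == g]
        gm = sel.mean(axis=0)
        ssb += sel.shape[0] * (gm - grand) ** 2
        ssw += ((sel - gm) ** 2).sum(axis=0)
    dfb = ngroups - 1
    dfw = n - ngroups
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    out = np.where(ssw <= 0, np.inf, F)
    return out if out.size > 1 else float(out[0])


def _bm_null_samples(tree: Tree, xv: np.ndarray, labels: Sequence[str],
                     nsim: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate nsim BM trait vectors at the ML Brownian rate of xv."""
    C = vcv_matrix(tree).reorder(list(labels))
    from ovoflux.trait_models import _profile_loglik  # local to avoid cycle

    _, s2, _ = _profile_loglik(xv, C.matrix)
    L, _ = _chol_with_ridge(C.matrix)
    Z = rng.standard_normal((len(labels), nsim))
    return math.sqrt(s2) * (L @ Z)


def _simulation_anova(
    tree: Tree,
    x: Mapping[str, float],
    groups: Mapping[str, str],
    nsim: int,
    seed: int,
    statistic: str,
) -> AnovaResult:
    labels = [lab for lab in tree.tip_labels if lab in x and lab in groups]
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    labels = sub.tip_labels
    xv = np.array([float(x[lab]) for lab in labels])
    cats = sorted({groups[lab] for lab in labels})
    gidx = np.array([cats.index(groups[lab]) for lab in labels])
    counts = np.bincount(gidx, minlength=len(cats))
    if len(cats) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups each with >= 2 members")

    def stat(v: np.ndarray) -> np.ndarray | float:
        if statistic == "levene":
            v = np.atleast_2d(v.T).T
            dev = np.empty_like(v)
            for g in range(len(cats)):
                sel = gidx == g
                dev[sel] = np.abs(v[sel] - np.median(v[sel], axis=0))
            return _anova_f(dev, gidx, len(cats))
        return _anova_f(v, gidx, len(cats))

    F_obs = float(np.asarray(stat(xv)))
    degenerate = not np.isfinite(F_obs)
    dfb, dfw = len(cats) - 1, len(labels) - len(cats)
    p_param = float(stats.f.sf(F_obs, dfb, dfw)) if np.isfinite(F_obs) else 0.0

    rng = np.random.default_rng(seed)
    nulls = _bm_null_samples(sub, xv, labels, nsim, rng)
    F_null = np.asarray(stat(nulls))
    if degenerate:
        warnings.warn("degenerate ANOVA (zero within-group variance); "
                      "p set to 1/(nsim+1)", stacklevel=2)
        p_sim = 1.0 / (nsim + 1)
    else:
        p_sim = (1.0 + np.sum(F_null >= F_obs)) / (nsim + 1.0)
    return AnovaResult(F=F_obs, df_num=dfb, df_den=dfw, p_parametric=p_param,
                       p_simulation=float(p_sim), nsim=nsim, degenerate=degenerate)


def phylo_anova(tree: Tree, x: Mapping[str, float], groups: Mapping[str, str],
                nsim: int = 1000, seed: int = 0) -> AnovaResult:
    """Simulation-based phylogenetic ANOVA of a trait across categories."""
    return _simulation_anova(tree, x, groups, nsim, seed, statistic="anova")


def group_variance_test(residuals: Mapping[str, float], groups: Mapping[str, str],
                        tree: Tree, nsim: int = 1000, seed: int = 0) -> AnovaResult:
    """Levene-type test of variance heterogeneity across categories.

    The F statistic is a one-way ANOVA on absolute deviations from group
    medians; its null distribution comes from the same Brownian-motion
    simulation scheme as :func:`phylo_anova`.
    """
    return _simulation_anova(tree, residuals, groups, nsim, seed, statistic="levene")


# ---------------------------------------------------------------------------
# Gaussian model selection over predictor sets
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionTable:
    table: pd.DataFrame  # predictors, k, loglik, AICc, dAICc, weight

    def best(self) -> pd.Series:
        return self.table.iloc[0]


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Treatment-coded design matrix with alphabetical reference levels."""
    cols = [pd.Series(1.0, index=table.index, name="intercept")]
    for p in predictors:
        col = table[p]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            logger.info("treatment coding %s with reference level %r", p, levels[0])
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).astype(float).rename(f"{p}[{lev}]"))
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1)


def glm_model_selection(
    table: pd.DataFrame,
    response: str,
    candidate_sets: Sequence[Sequence[str]],
) -> ModelSelectionTable:
    """Rank Gaussian linear models over candidate predictor sets by AICc.

    Each candidate is a list of column names (empty = intercept only);
    categorical predictors are expanded to treatment contrasts.  The
    Gaussian log-likelihood counts the error variance as a parameter.
    """
    missing = {p for s in candidate_sets for p in s} - set(table.columns)
    if missing:
        raise KeyError(f"predictors not in table: {sorted(missing)}")
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    rows = []
    for cand in candidate_sets:
        X = _design(table, list(cand)).to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / n
        ll = -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)
        k = X.shape[1] + 1  # + error variance
        rows.append({
            "predictors": "+".join(cand) if cand else "1",
            "k": k, "loglik": ll, "AICc": aicc(ll, k, n),
        })
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["weight"] = akaike_weights(df["AICc"].to_numpy())
    return ModelSelectionTable(df)


# ---------------------------------------------------------------------------
# Repeatability (intraclass correlation)
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    R: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    lrt: float
    lrt_p: float
    n_groups: int
    n_reps: float  # mean replicates per group


def _icc_anova(values: pd.DataFrame) -> tuple[float, float, float, float, float]:
    """One-way ANOVA decomposition: returns (R, SSB, SSW, g, k0).

    ``k0`` is the effective replicate count (equals k for balanced
    designs; otherwise the standard unequal-n adjustment)."""
    grouped = values.groupby("group")["value"]
    g = grouped.ngroups
    counts = grouped.count().to_numpy(dtype=float)
    n = counts.sum()
    grand = values["value"].mean()
    means = grouped.mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((values["value"] - means.loc[values["group"]].to_numpy()) ** 2).sum())
    k0 = (n - (counts ** 2).sum() / n) / (g - 1)
    msb = ssb / (g - 1)
    dfw = n - g
    msw = ssw / dfw if dfw > 0 else 0.0
    if msw <= 0:
        return 1.0, ssb, ssw, g, k0
    R = (msb - msw) / (msb + (k0 - 1) * msw)
    return min(max(R, 0.0), 1.0), ssb, ssw, g, k0


def _one_way_ml_loglik(ssw: float, ssb: float, g: int, k: float, n: float,
                       between_zero: bool) -> float:
    """ML log-likelihood of the balanced one-way random-effects model.

    Profile over (σ²_w, σ²_b): unconstrained maxima are SSW/(n−g) for the
    within term and SSB/g for τ = σ²_w + k σ²_b; the boundary case pools
    everything into a single variance."""
    if between_zero:
        s2 = (ssw + ssb) / n
        s2 = max(s2, np.finfo(float).tiny)
        return -0.5 * (n * math.log(2 * math.pi * s2) + n)
    w = max(ssw / (n - g), np.finfo(float).tiny)
    tau = max(ssb / g, np.finfo(float).tiny)
    if tau < w:  # boundary: between-variance estimate <= 0
        return _one_way_ml_loglik(ssw, ssb, g, k, n, between_zero=True)
    return -0.5 * (n * math.log(2 * math.pi) + g * math.log(tau)
                   + (n - g) * math.log(w) + ssb / tau + ssw / w)


def repeatability_icc(
    values: pd.DataFrame,
    nboot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RepeatabilityResult:
    """Intraclass correlation from replicate measurements.

    ``values`` has columns ``group`` and ``value``.  R is the one-way
    ANOVA estimator (MSB − MSW)/(MSB + (k−1)·MSW), truncated to [0, 1]
    and reported as 0 when the between-group variance estimate is
    non-positive.  The CI is a group-level bootstrap; the LRT tests the
    between-group variance component against zero with the
    ½χ²₀ + ½χ²₁ boundary mixture.
    """
    if not {"group", "value"}.issubset(values.columns):
        raise ValueError("values must have 'group' and 'value' columns")
    counts = values.groupby("group")["value"].count()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).all():
        raise ValueError("all groups are singletons; replicates required")

    R, ssb, ssw, g, k0 = _icc_anova(values)
    n = float(len(values))

    ll1 = _one_way_ml_loglik(ssw, ssb, g, k0, n, between_zero=False)
    ll0 = _one_way_ml_loglik(ssw, ssb, g, k0, n, between_zero=True)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    lrt_p = 1.0 if lrt <= 1e-12 else 0.5 * float(stats.chi2.sf(lrt, df=1))

    if nboot > 0:
        rng = np.random.default_rng(seed)
        group_ids = counts.index.to_numpy()
        by_group = {gid: sub["value"].to_numpy() for gid, sub in values.groupby("group")}
        boots = np.empty(nboot)
        for b in range(nboot):
            pick = rng.choice(group_ids, size=len(group_ids), replace=True)
            frames = pd.DataFrame({
                "group": np.repeat(np.arange(len(pick)), [len(by_group[p]) for p in pick]),
                "value": np.concatenate([by_group[p] for p in pick]),
            })
            boots[b], *_ = _icc_anova(frames)
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, R), max(hi, R)
    else:
        lo = hi = float("nan")
    return RepeatabilityResult(
        R=R, ci_level=ci_level, ci_lower=float(lo), ci_upper=float(hi),
        lrt=lrt, lrt_p=lrt_p, n_groups=int(g), n_reps=float(counts.mean()),
    )
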