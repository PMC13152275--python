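"""Maximum-likelihood fitting of continuous-trait evolution models.

Each model defines a tip covariance structure σ²·C(θ) where θ is a single
shape parameter (λ for Pagel's model, α for OU, the decay rate a for
early burst; Brownian motion has none).  Given θ, the root state z₀ and
the rate σ² have closed-form maximum-likelihood estimates (GLS mean and
ML variance), so fitting reduces to a bounded one-dimensional search over
θ, which is done with a coarse grid pre-scan followed by Brent
refinement.

Trees are rescaled to unit height internally (this conditions the α
search); σ², α and a are transformed back to the original time scale on
return.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import linalg, optimize, stats

from ovoflux.phylo import PhyloCovariance, Tree, transform_covariance, vcv_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvolutionModelFit",
    "mvn_loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "phylo_signal_lambda",
    "MODELS",
]

MODELS = ("BM", "lambda", "OU", "EB")

# bounded search ranges on the unit-height tree
_LAMBDA_RANGE = (0.0, 1.0)
_LN_ALPHA_RANGE = (math.log(1e-4), math.log(1e2))
_EB_RANGE = (-10.0, 0.0)
_GRID_POINTS = 20
_XTOL = 1e-6
_RIDGE = 1e-10


@dataclass
class EvolutionModelFit:
    """Result of a single-model maximum-likelihood fit."""

    model: str
    sigma2: float
    shape: Optional[float]   # λ, α, or a; None for BM
    z0: float
    loglik: float
    k: int
    aic: float
    aicc: float
    n: int
    converged: bool

    @property
    def shape_name(self) -> Optional[str]:
        return {"BM": None, "lambda": "lambda", "OU": "alpha", "EB": "a"}[self.model]


def _chol_with_ridge(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of C, adding a small ridge once if near-singular."""
    try:
        return linalg.cholesky(C, lower=True), 0.0
    except linalg.LinAlgError:
        ridge = _RIDGE * float(np.mean(np.diag(C)))
        logger.warning("covariance near-singular; adding ridge %.3g", ridge)
        try:
            return linalg.cholesky(C + ridge * np.eye(C.shape[0]), lower=True), ridge
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "covariance singular even after ridge; check for duplicate tips "
                "or zero-length terminal branches"
            ) from exc


def mvn_loglik(
    x: Mapping[str, float] | np.ndarray,
    C: PhyloCovariance,
    sigma2: float,
    z0: float,
) -> float:
    """Log density of tip values under N(z₀·1, σ²·C), via Cholesky."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    xv = _align(x, C)
    n = C.n
    L, _ = _chol_with_ridge(C.matrix)
    r = xv - z0
    u = linalg.solve_triangular(L, r, lower=True)
    quad = float(u @ u) / sigma2
    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + n * math.log(sigma2)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def _align(x: Mapping[str, float] | np.ndarray, C: PhyloCovariance) -> np.ndarray:
    if isinstance(x, np.ndarray):
        xv = np.asarray(x, dtype=float)
        if xv.shape != (C.n,):
            raise ValueError("trait vector length does not match covariance")
        return xv
    try:
        xv = np.array([float(x[lab]) for lab in C.labels])
    except KeyError as exc:
        raise KeyError(f"trait vector missing tip {exc}") from exc
    if not np.all(np.isfinite(xv)):
        raise ValueError("trait values must be finite")
    return xv


def _profile_loglik(xv: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Concentrated log-likelihood with z₀ (GLS) and σ² (ML) profiled out.

    Returns (loglik, sigma2_hat, z0_hat).
    """
    n = len(xv)
    L, _ = _chol_with_ridge(C)
    ones = np.ones(n)
    w1 = linalg.solve_triangular(L, ones, lower=True)
    wx = linalg.solve_triangular(L, xv, lower=True)
    z0 = float(w1 @ wx) / float(w1 @ w1)
    u = wx - z0 * w1
    s2 = float(u @ u) / n
    if s2 <= 0:
        s2 = np.finfo(float).tiny
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2) + n + logdet)
    return ll, s2, z0


def _shape_to_params(model: str, theta: float) -> dict:
    if model == "lambda":
        return {"lam": theta}
    if model == "OU":
        return {"alpha": math.exp(theta)}  # theta is ln alpha
    if model == "EB":
        return {"a": theta}
    return {}


def fit_model(
    tree: Tree,
    x: Mapping[str, float],
    model: str,
    C_bm: Optional[PhyloCovariance] = None,
) -> EvolutionModelFit:
    """Fit one trait-evolution model by maximum likelihood.

    ``x`` maps tip labels to (typically log-transformed) trait values;
    tips absent from ``x`` are pruned from the tree.  ``C_bm`` lets a
    caller reuse a precomputed Brownian covariance for the matched tips.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    labels = [lab for lab in (tree.tip_labels if C_bm is None else C_bm.labels) if lab in x]
    if len(labels) < 3:
        raise ValueError(f"need >= 3 matched tips, got {len(labels)}")
    if C_bm is None:
        sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
        C_bm = vcv_matrix(sub)
        labels = C_bm.labels
    xv = _align(x, C_bm)
    n = len(labels)

    height = float(np.max(np.diag(C_bm.matrix)))
    if height <= 0:
        raise ValueError("tree has zero height")
    C_unit = PhyloCovariance(C_bm.matrix / height, list(C_bm.labels))

    if model == "BM":
        ll, s2, z0 = _profile_loglik(xv, C_unit.matrix)
        k = 2
        return EvolutionModelFit(
            model="BM", sigma2=s2 / height, shape=None, z0=z0, loglik=ll,
            k=k, aic=2 * k - 2 * ll,
            aicc=aicc(ll, k, n) if n > k + 1 else float("inf"),
            n=n, converged=True,
        )

    lo, hi = {"lambda": _LAMBDA_RANGE, "OU": _LN_ALPHA_RANGE, "EB": _EB_RANGE}[model]

    def negll(theta: float) -> float:
        Ct = transform_covariance(C_unit, model, _shape_to_params(model, theta))
        try:
            ll, _, _ = _profile_loglik(xv, Ct.matrix)
        except linalg.LinAlgError:
            return np.inf
        return -ll

    grid = np.linspace(lo, hi, _GRID_POINTS)
    grid_vals = np.array([negll(t) for t in grid])
    if not np.any(np.isfinite(grid_vals)):
        raise RuntimeError(f"non-finite likelihood across the whole {model} parameter range")
    i = int(np.argmin(grid_vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(blo, bhi), method="bounded", options={"xatol": _XTOL}
    )
    theta = float(res.x)
    if negll(theta) > grid_vals[i]:  # guard against a failed refinement
        theta = float(grid[i])
    converged = bool(getattr(res, "success", True))

    Ct = transform_covariance(C_unit, model, _shape_to_params(model, theta))
    ll, s2, z0 = _profile_loglik(xv, Ct.matrix)

    # back-transform to the original time scale
    if model == "lambda":
        shape, sigma2 = theta, s2 / height
    elif model == "OU":
        shape, sigma2 = math.exp(theta) / height, s2 / height
    else:  # EB
        shape, sigma2 = theta / height, s2 / height
    k = 3
    return EvolutionModelFit(
        model=model, sigma2=sigma2, shape=shape, z0=z0, loglik=ll,
        k=k, aic=2 * k - 2 * ll,
        aicc=aicc(ll, k, n) if n > k + 1 else float("inf"),
        n=n, converged=converged,
    )


def fit_all_models(tree: Tree, x: Mapping[str, float]) -> dict[str, EvolutionModelFit]:
    """Fit all four models to one trait and return them keyed by name."""
    labels = [lab for lab in tree.tip_labels if lab in x]
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    C_bm = vcv_matrix(sub)
    return {m: fit_model(sub, x, m, C_bm=C_bm) for m in MODELS}


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (n={n}, k={k})")
    aic = 2 * k - 2 * loglik
    return aic + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalised relative support wᵢ = exp(−Δᵢ/2) / Σⱼ exp(−Δⱼ/2)."""
    v = np.asarray(list(aicc_values), dtype=float)
    if v.size == 0 or not np.any(np.isfinite(v)):
        raise ValueError("need at least one finite AICc value")
    delta = v - np.nanmin(v[np.isfinite(v)])
    w = np.where(np.isfinite(delta), np.exp(-0.5 * delta), 0.0)
    return w / w.sum()


@dataclass
class LambdaSignal:
    lam: float
    loglik: float
    loglik0: float
    lrt: float
    p: float
    degenerate: bool


def phylo_signal_lambda(tree: Tree, x: Mapping[str, float]) -> LambdaSignal:
    """Pagel's λ estimate with a likelihood-ratio test against λ = 0.

    On a star tree the off-diagonal covariances vanish for every λ, so λ
    is unidentifiable; the returned result then carries
    ``degenerate=True``.  The LRT statistic 2(ℓ(λ̂) − ℓ(0)) is referred
    to χ²₁; under the null about half the mass sits at λ̂ = 0 where the
    statistic is exactly zero.
    """
    labels = [lab for lab in tree.tip_labels if lab in x]
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    C_bm = vcv_matrix(sub)
    off = C_bm.matrix[~np.eye(C_bm.n, dtype=bool)]
    degenerate = bool(np.allclose(off, 0.0))
    fit = fit_model(sub, x, "lambda", C_bm=C_bm)
    xv = _align(x, C_bm)
    C0 = transform_covariance(C_bm, "lambda", {"lam": 0.0})
    ll0, _, _ = _profile_loglik(xv, C0.matrix)
    lrt = max(0.0, 2.0 * (fit.loglik - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    if degenerate:
        warnings.warn("star tree: Pagel's lambda is unidentifiable", stacklevel=2)
    return LambdaSignal(
        lam=float(fit.shape), loglik=fit.loglik, loglik0=ll0, lrt=lrt, p=p,
        degenerate=degenerate,
    )
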