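"""Negative-binomial GLM machinery shared by both DE engines.

Log-link NB regression (Var = mu + alpha*mu^2) fitted by iteratively
reweighted least squares with per-sample offsets and optional observation
weights, plus median-of-ratios size factors and the Wald / likelihood-ratio
tests. Coefficients are kept on the natural-log scale internally; callers
convert to log2 at the reporting boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "DesignInfo",
    "GLMFit",
    "size_factors_median_ratio",
    "nb_loglik",
    "fit_nb_glm",
    "fit_nb_glm_many",
    "wald_test",
    "lrt_test",
    "two_group_design",
]

_ETA_MIN, _ETA_MAX = -30.0, 30.0
_BOUNDARY = 20.0  # |beta| beyond this (natural log) is a separation boundary


@dataclass(frozen=True)
class DesignInfo:
    X: np.ndarray  # samples x p
    coef_names: tuple

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] >= X.shape[0]:
            raise ValueError("design must be n x p with p < n")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if len(self.coef_names) != X.shape[1]:
            raise ValueError("coef_names length mismatch")


def two_group_design(group_indicator) -> DesignInfo:
    """Intercept + group-B indicator design for a two-group comparison."""
    g = np.asarray(group_indicator, dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    return DesignInfo(X, ("intercept", "group"))


def size_factors_median_ratio(counts) -> np.ndarray:
    """Median-of-ratios normalization.

    s_j = median over transcripts with all-positive counts of
    counts[i, j] / geometric_mean_i. Raises when no transcript is positive
    in every sample.
    """
    mat = np.asarray(getattr(counts, "counts", counts), dtype=float)
    all_pos = np.all(mat > 0, axis=1)
    if not all_pos.any():
        raise ValueError("no transcript with strictly positive counts in all samples")
    logs = np.log(mat[all_pos])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_ratios, axis=0))


def nb_loglik(y, mu, alpha: float, weights=None) -> float:
    """Sum of (optionally weighted) NB log-probabilities.

    Continuous in alpha with the Poisson limit at alpha -> 0; alpha below
    1e-9 is evaluated with the exact Poisson log-likelihood for stability.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    if np.any(mu <= 0):
        raise ValueError("means must be positive")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if alpha < 1e-9:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        r = 1.0 / alpha
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    return float(np.sum(w * ll))


@dataclass
class GLMFit:
    beta: np.ndarray  # natural-log scale
    cov_beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    weights_used: np.ndarray


def _initial_beta(y, X, offsets):
    z = np.log(np.asarray(y, dtype=float) + 0.5) - offsets
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def fit_nb_glm(y, design: DesignInfo, offsets=None, alpha: float = 0.0, weights=None) -> GLMFit:
    """Fit one transcript's NB GLM by IRLS with step-halving.

    Convergence: relative coefficient change < 1e-8 within 100 iterations.
    All-zero responses and separated groups are flagged as boundary fits
    (infinite SE on the affected coefficients).
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = X.shape
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")

    if np.all(y == 0):
        mu = np.full(n, 1e-8)
        cov = np.full((p, p), np.inf)
        return GLMFit(np.zeros(p), cov, mu, nb_loglik(y, mu, alpha, w), True, True, w)

    beta = _initial_beta(y, X, offsets)
    mu = np.exp(np.clip(X @ beta + offsets, _ETA_MIN, _ETA_MAX))
    ll = nb_loglik(y, mu, alpha, w)
    converged = False
    for _ in range(100):
        W = w * mu / (1.0 + alpha * mu)
        z = (X @ beta) + (y - mu) / mu
        A = X.T @ (W[:, None] * X)
        b = X.T @ (W * z)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + 1e-10 * np.eye(p), b)
        step = beta_new - beta
        # step-halving on likelihood decrease
        for _half in range(12):
            cand = beta + step
            mu_c = np.exp(np.clip(X @ cand + offsets, _ETA_MIN, _ETA_MAX))
            ll_c = nb_loglik(y, mu_c, alpha, w)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        rel = np.max(np.abs(step) / np.maximum(np.abs(beta) + np.abs(step), 1e-8))
        beta = beta + step
        mu = np.exp(np.clip(X @ beta + offsets, _ETA_MIN, _ETA_MAX))
        ll = nb_loglik(y, mu, alpha, w)
        if rel < 1e-8:
            converged = True
            break

    W = w * mu / (1.0 + alpha * mu)
    A = X.T @ (W[:, None] * X)
    boundary = bool(np.any(np.abs(beta) > _BOUNDARY))
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
        boundary = True
    if boundary:
        cov = cov.copy()
        bad = np.abs(beta) > _BOUNDARY
        cov[bad, :] = np.inf
        cov[:, bad] = np.inf
    return GLMFit(beta, cov, mu, ll, converged, boundary, w)


def fit_nb_glm_many(Y, design: DesignInfo, offsets=None, alpha=None, weights=None,
                    max_iter: int = 60, tol: float = 1e-8) -> dict:
    """Vectorized IRLS across transcripts (rows of ``Y``).

    Same model as :func:`fit_nb_glm`; used by the engines for speed. Eta is
    clipped instead of step-halved, which is adequate on the engines' paths
    (agreement with the scalar fitter is tested).

    Returns dict with beta (G,p), cov (G,p,p), mu (G,n), loglik (G,),
    boundary (G,) and se (G,p).
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    X = design.X
    p = X.shape[1]
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = np.broadcast_to(offsets, (G, n))
    alpha = np.zeros(G) if alpha is None else np.broadcast_to(np.asarray(alpha, dtype=float), (G,))
    W_obs = np.ones((G, n)) if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros((G, p))
    z0 = np.log(Y + 0.5) - offsets
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T

    eye = np.eye(p)
    for _ in range(max_iter):
        eta = beta @ X.T + offsets
        mu = np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX))
        W = W_obs * mu / (1.0 + alpha[:, None] * mu)
        z = (beta @ X.T) + (Y - mu) / mu
        A = np.einsum("gn,np,nq->gpq", W, X, X)
        b = np.einsum("gn,np->gp", W * z, X)
        beta_new = np.linalg.solve(A + 1e-12 * eye, b[..., None])[..., 0]
        delta = np.abs(beta_new - beta).max(axis=1)
        scale = np.abs(beta).max(axis=1) + 1.0
        beta = np.clip(beta_new, -_BOUNDARY - 5, _BOUNDARY + 5)
        if np.all(delta / scale < tol):
            break

    eta = beta @ X.T + offsets
    mu = np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX))
    W = W_obs * mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,np,nq->gpq", W, X, X)
    cov = np.linalg.inv(A + 1e-12 * eye)
    boundary = np.abs(beta) > _BOUNDARY
    se = np.sqrt(np.maximum(np.einsum("gpp->gp", cov), 0.0))
    se[boundary] = np.inf
    ll = _loglik_many(Y, mu, alpha, W_obs)
    all_zero = np.all(Y == 0, axis=1)
    if all_zero.any():
        beta[all_zero] = 0.0
        se[all_zero] = np.inf
    return {
        "beta": beta,
        "cov": cov,
        "mu": mu,
        "loglik": ll,
        "boundary": boundary.any(axis=1) | all_zero,
        "se": se,
    }


def _loglik_many(Y, mu, alpha, weights=None) -> np.ndarray:
    """Row-wise weighted NB log-likelihood, Poisson-stable at tiny alpha."""
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    w = np.ones_like(Y) if weights is None else weights
    tiny = alpha < 1e-9
    a = np.where(tiny, 1.0, alpha)
    r = 1.0 / a
    ll_nb = (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu))
    )
    ll_pois = Y * np.log(mu) - mu - gammaln(Y + 1.0)
    return np.sum(w * np.where(tiny, ll_pois, ll_nb), axis=1)


def wald_test(beta_hat: float, se: float) -> float:
    """Two-sided normal test of beta = 0; NaN when the SE is unusable."""
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2.0 * stats.norm.sf(abs(beta_hat / se)))


def lrt_test(loglik_full: float, loglik_reduced: float, df: int = 1) -> float:
    """Chi-square test of twice the log-likelihood gap of nested fits."""
    if df <= 0:
        raise ValueError("df must be positive")
    if loglik_full < loglik_reduced - 1e-6:
        raise ValueError("full model log-likelihood below reduced (non-nested fits?)")
    lam = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return float(stats.chi2.sf(lam, df))
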