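"""The two differential-expression engines under comparison.

``shrink`` — NB GLM with median-of-ratios offsets, Cox-Reid genewise
dispersions shrunk toward a 1/mean trend by an empirical-Bayes MAP step,
ridge-style LFC shrinkage toward a zero-centered normal prior, Wald test by
default.

``robust`` — NB GLM with raw library-size offsets, conditional-likelihood
common dispersion, tagwise dispersions moderated toward the shared
likelihood by a prior-degrees-of-freedom weight, Huber observation weights
on Pearson residuals iterated with the fit, LRT by default. ``classic`` is
the same engine without observation weights.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, polygamma

from .containers import CountMatrix
from .metrics import bh_adjust
from .nb_core import (
    DesignInfo,
    _loglik_many,
    fit_nb_glm,
    fit_nb_glm_many,
    size_factors_median_ratio,
    two_group_design,
)

__all__ = [
    "EngineConfig",
    "DispersionSet",
    "estimate_genewise_dispersion",
    "fit_dispersion_trend",
    "map_dispersion",
    "shrink_lfc",
    "run_shrink_engine",
    "estimate_common_dispersion",
    "moderate_tagwise_dispersion",
    "estimate_prior_df",
    "observation_weights",
    "run_robust_engine",
    "run_engine",
    "compare_tests",
]

LN2 = np.log(2.0)
ALPHA_MIN, ALPHA_MAX = 1e-8, 10.0
_GRID = np.exp(np.linspace(np.log(ALPHA_MIN), np.log(ALPHA_MAX), 49))
_LOGGRID = np.log(_GRID)
PRIOR_DF_CAP = 1e6


@dataclass(frozen=True)
class EngineConfig:
    engine: str = "shrink"  # {shrink, robust, classic}
    test: str | None = None  # {wald, lrt}; None = engine default
    prior_df: float | str = 10.0  # number or "estimated" (robust/classic only)
    fdr: float = 0.05
    lfc_shrink: bool = True

    def resolved_test(self) -> str:
        if self.test is not None:
            return self.test
        return "wald" if self.engine == "shrink" else "lrt"

    def label(self) -> str:
        if self.engine == "shrink":
            return "shrink"
        pdf = self.prior_df if isinstance(self.prior_df, str) else f"{self.prior_df:g}"
        return f"{self.engine}_df{pdf}"


@dataclass
class DispersionSet:
    genewise: np.ndarray
    final: np.ndarray
    trend_coef: tuple | None = None
    common: float | None = None
    prior_df: float | None = None
    prior_var_logdisp: float | None = None
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


# --------------------------------------------------------------------------
# shared numerics
# --------------------------------------------------------------------------

def _argmax_parabolic(obj: np.ndarray) -> np.ndarray:
    """Per-row argmax over the dispersion grid refined by a parabola in
    log-alpha; returns alphas clipped to the grid range."""
    G, K = obj.shape
    k = np.argmax(obj, axis=1)
    rows = np.arange(G)
    interior = (k > 0) & (k < K - 1)
    x = _LOGGRID[k].astype(float)
    h = _LOGGRID[1] - _LOGGRID[0]
    ki = np.clip(k, 1, K - 2)
    y0, y1, y2 = obj[rows, ki - 1], obj[rows, ki], obj[rows, ki + 1]
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * h * (y0 - y2) / denom
    good = interior & np.isfinite(shift) & (denom < 0) & (np.abs(shift) <= h)
    x = np.where(good, _LOGGRID[ki] + np.where(good, shift, 0.0), x)
    return np.exp(np.clip(x, _LOGGRID[0], _LOGGRID[-1]))


def _mom_alpha(Y: np.ndarray, offsets: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion start values (only seeds the mean fit)."""
    ynorm = Y * np.exp(-offsets)
    alphas = np.full(Y.shape[0], 0.1)
    means = []
    sqdev = []
    for g in np.unique(group):
        cols = group == g
        m = ynorm[:, cols].mean(axis=1)
        means.append(cols.sum() * m)
        sqdev.append(((ynorm[:, cols] - m[:, None]) ** 2).sum(axis=1))
    m = sum(means) / Y.shape[1]
    v = sum(sqdev) / max(Y.shape[1] - len(np.unique(group)), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - m) / m**2
    ok = np.isfinite(a) & (m > 0)
    alphas[ok] = np.clip(a[ok], 1e-4, ALPHA_MAX)
    return alphas


def _cr_apl_matrix(Y, design: DesignInfo, mu, grid=_GRID, weights=None) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood on a dispersion grid with the
    fitted means held fixed: ll(alpha) - 0.5*logdet(X'WX)."""
    G = Y.shape[0]
    X = design.X
    w = np.ones_like(np.asarray(Y, dtype=float)) if weights is None else weights
    out = np.empty((G, len(grid)))
    for j, a in enumerate(grid):
        alpha = np.full(G, a)
        ll = _loglik_many(Y, mu, alpha, w)
        W = w * mu / (1.0 + a * mu)
        A = np.einsum("gn,np,nq->gpq", W, X, X)
        sign, logdet = np.linalg.slogdet(A + 1e-12 * np.eye(X.shape[1]))
        out[:, j] = ll - 0.5 * logdet
    return out


def _cr_apl_scalar(y, design: DesignInfo, mu, alpha: float, weights=None) -> float:
    row = _cr_apl_matrix(
        np.asarray(y, dtype=float)[None, :], design, np.asarray(mu, dtype=float)[None, :],
        grid=np.array([alpha]), weights=None if weights is None else np.asarray(weights)[None, :],
    )
    return float(row[0, 0])


# --------------------------------------------------------------------------
# shrink-engine components
# --------------------------------------------------------------------------

def estimate_genewise_dispersion(y, design: DesignInfo, offsets=None, weights=None) -> float:
    """Maximize the Cox-Reid adjusted profile likelihood of the dispersion
    for one transcript, over alpha in [1e-8, 10] (log-scale bounded search).

    The fitted means come from an initial GLM fit at a moments-based start
    value and are held fixed during the 1-D search. All-zero transcripts
    raise: their dispersion is undefined and is assigned the trend value
    downstream.
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == 0):
        raise ValueError("dispersion undefined for an all-zero transcript")
    n = len(y)
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    group = design.X[:, -1] if design.X.shape[1] > 1 else np.zeros(n)
    a0 = float(_mom_alpha(y[None, :], offsets, group)[0])
    fit = fit_nb_glm(y, design, offsets, alpha=a0, weights=weights)
    mu = fit.mu

    def neg(logalpha):
        return -_cr_apl_scalar(y, design, mu, float(np.exp(logalpha)), weights)

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def fit_dispersion_trend(means, genewise, mean_floor: float = 0.5):
    """Fit alpha_tr(mu) = a0 + a1/mu by Gamma-family regression on 1/mean,
    with one outlier-exclusion refit pass; coefficients clipped to >= 0.

    Falls back to a flat median trend (with a warning) when fewer than 10
    usable transcripts remain.
    """
    means = np.asarray(means, dtype=float)
    genewise = np.asarray(genewise, dtype=float)
    use = np.isfinite(genewise) & (means > mean_floor) & (genewise > 10 * ALPHA_MIN)
    if use.sum() < 10:
        warnings.warn("too few usable transcripts for a dispersion trend; "
                      "using flat median dispersion", stacklevel=2)
        med = float(np.median(genewise[np.isfinite(genewise)])) if np.isfinite(genewise).any() else 0.1
        return (max(med, ALPHA_MIN), 0.0)

    def _gamma_fit(mask):
        import statsmodels.api as sm
        Xd = np.column_stack([np.ones(mask.sum()), 1.0 / means[mask]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(genewise[mask], Xd,
                               family=sm.families.Gamma(link=sm.families.links.Identity()))
                res = model.fit(start_params=[np.median(genewise[mask]), 0.1], maxiter=200)
                coef = res.params
        except Exception:
            coef, *_ = np.linalg.lstsq(Xd, genewise[mask], rcond=None)
        return np.maximum(coef, 0.0)

    a0, a1 = _gamma_fit(use)
    if a0 == 0 and a1 == 0:
        a0 = float(np.median(genewise[use]))
    # outlier-exclusion second pass
    trend = a0 + a1 / np.maximum(means, mean_floor)
    ratio = np.where(trend > 0, genewise / trend, np.inf)
    keep = use & (ratio > 1e-4) & (ratio < 15.0)
    if keep.sum() >= 10 and keep.sum() < use.sum():
        a0, a1 = _gamma_fit(keep)
        if a0 == 0 and a1 == 0:
            a0 = float(np.median(genewise[keep]))
    return (float(a0), float(a1))


def map_dispersion(genewise: float, trend_value: float, prior_var_logdisp: float,
                   y, design: DesignInfo, offsets=None, weights=None) -> float:
    """MAP dispersion: Cox-Reid adjusted likelihood plus a log-normal prior
    centered at the trend, maximized over alpha."""
    if trend_value <= 0:
        raise ValueError("trend value must be positive")
    y = np.asarray(y, dtype=float)
    if np.all(y == 0):
        return float(trend_value)
    n = len(y)
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    fit = fit_nb_glm(y, design, offsets, alpha=max(genewise, ALPHA_MIN), weights=weights)
    mu = fit.mu
    pv = max(prior_var_logdisp, 1e-12)

    def neg(logalpha):
        pen = (logalpha - np.log(trend_value)) ** 2 / (2.0 * pv)
        return -(_cr_apl_scalar(y, design, mu, float(np.exp(logalpha)), weights) - pen)

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def estimate_prior_sd(lfc_mle, se, q: float = 0.95, floor: float = 0.1) -> float:
    """Global LFC prior width: match the q-quantile of |MLE LFC| over
    finite-SE transcripts, floored at ``floor`` log2 units."""
    lfc_mle = np.asarray(lfc_mle, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(se) & np.isfinite(lfc_mle)
    if not ok.any():
        warnings.warn("no finite-SE transcripts; LFC prior sd set to floor", stacklevel=2)
        return floor
    target = float(np.quantile(np.abs(lfc_mle[ok]), q))
    return max(target / float(stats.norm.ppf(0.5 + q / 2.0)), floor)


def shrink_lfc(lfc_mle, se, prior_sd: float):
    """Ridge (quadratic-approximation MAP) shrinkage toward N(0, prior_sd^2).

    Returns (lfc_final, se_final). Infinite-SE transcripts pass through with
    lfc_final = 0 and se_final = inf.
    """
    lfc_mle = np.asarray(lfc_mle, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    finite = np.isfinite(se) & (se > 0)
    c = np.zeros_like(lfc_mle)
    c[finite] = prior_sd**2 / (prior_sd**2 + se[finite] ** 2)
    lfc_final = np.where(finite, lfc_mle * c, 0.0)
    se_final = np.full_like(np.atleast_1d(se).astype(float), np.inf)
    se_final[finite] = se[finite] * np.sqrt(c[finite])
    return lfc_final, se_final


def _shrink_dispersions(Y, design, offsets, weights=None):
    group = design.X[:, -1]
    alpha0 = _mom_alpha(Y, offsets, group)
    fit0 = fit_nb_glm_many(Y, design, offsets, alpha=alpha0, weights=weights)
    mu = np.maximum(fit0["mu"], 1e-8)
    cr = _cr_apl_matrix(Y, design, mu, weights=weights)
    genewise = _argmax_parabolic(cr)
    all_zero = np.all(Y == 0, axis=1)
    genewise[all_zero] = np.nan

    base_mean = (Y * np.exp(-offsets)).mean(axis=1)
    a0, a1 = fit_dispersion_trend(base_mean, genewise)
    trend = a0 + a1 / np.maximum(base_mean, 0.5)
    trend = np.maximum(trend, ALPHA_MIN)

    n, p = design.X.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.log(genewise) - np.log(trend)
    ok = np.isfinite(resid)
    if ok.any():
        mad = np.median(np.abs(resid[ok] - np.median(resid[ok])))
        robust_var = (1.4826 * mad) ** 2
    else:
        robust_var = 0.0
    sampling_var = float(polygamma(1, (n - p) / 2.0))
    prior_var = max(robust_var - sampling_var, 0.25)

    penalty = (_LOGGRID[None, :] - np.log(trend)[:, None]) ** 2 / (2.0 * prior_var)
    final = _argmax_parabolic(cr - penalty)
    final[all_zero] = trend[all_zero]
    return DispersionSet(
        genewise=genewise, final=final, trend_coef=(a0, a1),
        prior_var_logdisp=prior_var, flagged=all_zero,
    )


def _assemble_result(index, mean_norm, lfc_mle, lfc_final, lfc_se, disp, stat,
                     pvalue, fdr) -> pd.DataFrame:
    pvalue = np.asarray(pvalue, dtype=float)
    padj = bh_adjust(pvalue)
    res = pd.DataFrame(
        {
            "mean_norm_count": mean_norm,
            "lfc_mle": lfc_mle,
            "lfc_final": lfc_final,
            "lfc_se": lfc_se,
            "dispersion": disp,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "called": padj <= fdr,
        },
        index=index,
    )
    return res


def _two_group_setup(counts: CountMatrix):
    labels = counts.group_labels()
    if len(labels) != 2:
        raise ValueError("DE engines need exactly two groups")
    g = (counts.groups == labels[1]).to_numpy().astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    return g, two_group_design(g)


def run_shrink_engine(counts: CountMatrix, config: EngineConfig | None = None) -> pd.DataFrame:
    """LFC-shrinkage engine; returns one row per transcript."""
    config = config or EngineConfig(engine="shrink")
    g, design = _two_group_setup(counts)
    Y = counts.counts.to_numpy().astype(float)
    s = size_factors_median_ratio(counts)
    offsets = np.log(s)

    disp = _shrink_dispersions(Y, design, offsets)
    fit = fit_nb_glm_many(Y, design, offsets, alpha=disp.final)
    lfc_mle = fit["beta"][:, 1] / LN2
    se = fit["se"][:, 1] / LN2

    prior_sd = estimate_prior_sd(lfc_mle, se)
    lfc_final, se_final = shrink_lfc(lfc_mle, se, prior_sd)
    if not config.lfc_shrink:
        lfc_final, se_final = lfc_mle.copy(), se.copy()

    test = config.resolved_test()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(np.isfinite(se_final) & (se_final > 0), lfc_final / se_final, 0.0)
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    p_wald[~(np.isfinite(se_final) & (se_final > 0))] = 1.0

    reduced = DesignInfo(np.ones((len(g), 1)), ("intercept",))
    fit_red = fit_nb_glm_many(Y, reduced, offsets, alpha=disp.final)
    lam = np.maximum(2.0 * (fit["loglik"] - fit_red["loglik"]), 0.0)
    p_lrt = stats.chi2.sf(lam, 1)

    if test == "wald":
        stat, pvalue = z, p_wald
    elif test == "lrt":
        stat, pvalue = lam, p_lrt
    else:
        raise ValueError(f"unknown test {test!r}")

    mean_norm = (Y / s[None, :]).mean(axis=1)
    res = _assemble_result(counts.transcript_ids, mean_norm, lfc_mle, lfc_final,
                           se_final, disp.final, stat, pvalue, config.fdr)
    res["p_wald"] = p_wald
    res["p_lrt"] = p_lrt
    res.attrs["prior_sd"] = float(prior_sd)
    return res


# --------------------------------------------------------------------------
# robust / classic engine components
# --------------------------------------------------------------------------

def _round_half_away(x):
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def _pseudo_counts(Y: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Mean-preserving rescale of counts to the geometric-mean library size
    (simplified quantile adjustment) so the equal-library-size conditional
    likelihood applies to first order."""
    geo = np.exp(np.mean(np.log(lib)))
    return _round_half_away(Y * (geo / lib)[None, :])


def _cond_loglik_matrix(Yp: np.ndarray, group: np.ndarray, grid=_GRID) -> np.ndarray:
    """Per-transcript conditional log-likelihood of the dispersion given the
    group totals (equal library sizes assumed), on the grid."""
    out = np.zeros((Yp.shape[0], len(grid)))
    for g in np.unique(group):
        cols = group == g
        yg = Yp[:, cols]
        ng = int(cols.sum())
        zg = yg.sum(axis=1)
        for j, a in enumerate(grid):
            r = 1.0 / a
            out[:, j] += (
                gammaln(yg + r).sum(axis=1)
                - ng * gammaln(r)
                + gammaln(ng * r)
                - gammaln(zg + ng * r)
            )
    return out


def _cond_setup(counts: CountMatrix):
    labels = counts.group_labels()
    group = counts.groups.map({labels[0]: 0, labels[1]: 1}).to_numpy() if len(labels) == 2 \
        else np.zeros(counts.n_samples, dtype=int)
    Y = counts.counts.to_numpy().astype(float)
    Yp = _pseudo_counts(Y, counts.lib_size.to_numpy().astype(float))
    return Yp, group


def estimate_common_dispersion(counts: CountMatrix) -> float:
    """Single dispersion maximizing the summed conditional log-likelihood."""
    sizes = counts.group_sizes()
    if max(sizes.values()) < 2:
        raise ValueError("common dispersion needs replication in some group")
    Yp, group = _cond_setup(counts)
    total = _cond_loglik_matrix(Yp, group).mean(axis=0, keepdims=True)
    return float(_argmax_parabolic(total)[0])


def moderate_tagwise_dispersion(counts: CountMatrix, prior_df: float) -> np.ndarray:
    """Moderate per-transcript dispersions toward the shared likelihood:
    maximize l_g(alpha) + (prior_df/df_res) * mean_g(l_g)(alpha)."""
    if prior_df < 0:
        raise ValueError("prior_df must be non-negative")
    Yp, group = _cond_setup(counts)
    df_res = counts.n_samples - len(np.unique(group))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    L = _cond_loglik_matrix(Yp, group)
    lbar = L.mean(axis=0)
    return _argmax_parabolic(L + (prior_df / df_res) * lbar[None, :])


def estimate_prior_df(counts: CountMatrix) -> float:
    """Moment-matching prior-DF estimate from the spread of log tagwise
    dispersions: solve var(log alpha_g) = trigamma(df_res/2) + trigamma(d0/2)
    for d0; capped at 1e6 when the observed spread is within sampling noise.
    """
    Yp, group = _cond_setup(counts)
    totals = Yp.sum(axis=1)
    use = totals > 0
    if use.sum() < 30:
        raise ValueError("need >= 30 transcripts with positive totals")
    df_res = counts.n_samples - len(np.unique(group))
    L = _cond_loglik_matrix(Yp[use], group)
    tagwise = _argmax_parabolic(L)
    logd = np.log(tagwise)
    mad = np.median(np.abs(logd - np.median(logd)))
    var_obs = (1.4826 * mad) ** 2
    samp_var = float(polygamma(1, df_res / 2.0))
    excess = var_obs - samp_var
    # spread within Monte-Carlo noise of the sampling variance -> cap
    if excess <= 0.05 * samp_var:
        return PRIOR_DF_CAP

    def f(logd0):
        return float(polygamma(1, np.exp(logd0) / 2.0)) - excess

    lo, hi = np.log(1e-3), np.log(PRIOR_DF_CAP)
    sol = optimize.brentq(f, lo, hi, xtol=1e-10)
    return float(np.exp(sol))


def observation_weights(y, mu, alpha: float, k: float = 1.345) -> np.ndarray:
    """Huber weights on Pearson residuals: w = min(1, k/|r|)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or alpha < 0:
        raise ValueError("mu must be positive and alpha non-negative")
    r = (y - mu) / np.sqrt(mu + alpha * mu**2)
    with np.errstate(divide="ignore"):
        return np.minimum(1.0, k / np.maximum(np.abs(r), 1e-300))


def run_robust_engine(counts: CountMatrix, config: EngineConfig | None = None) -> pd.DataFrame:
    """Robust-weights engine (or its classic, unweighted variant)."""
    config = config or EngineConfig(engine="robust")
    robust = config.engine != "classic"
    g, design = _two_group_setup(counts)
    Y = counts.counts.to_numpy().astype(float)
    lib = counts.lib_size.to_numpy().astype(float)
    offsets = np.log(lib)
    df_res = counts.n_samples - 2

    if config.prior_df == "estimated":
        prior_df = estimate_prior_df(counts)
    else:
        prior_df = float(config.prior_df)
        if prior_df < 0:
            raise ValueError("prior_df must be non-negative")

    common = estimate_common_dispersion(counts)
    finals = moderate_tagwise_dispersion(counts, prior_df)

    weights = np.ones_like(Y)
    fit = fit_nb_glm_many(Y, design, offsets, alpha=finals, weights=weights)
    if robust:
        for _cycle in range(3):
            mu = np.maximum(fit["mu"], 1e-8)
            r = (Y - mu) / np.sqrt(mu + finals[:, None] * mu**2)
            with np.errstate(divide="ignore"):
                w_new = np.minimum(1.0, 1.345 / np.maximum(np.abs(r), 1e-300))
            if np.max(np.abs(w_new - weights)) < 1e-4:
                weights = w_new
                break
            weights = w_new
            # weighted dispersion refit on the profile likelihood, moderated
            # by the same shared-likelihood weight
            Lw = np.stack(
                [_loglik_many(Y, mu, np.full(Y.shape[0], a), weights) for a in _GRID],
                axis=1,
            )
            finals = _argmax_parabolic(Lw + (prior_df / df_res) * Lw.mean(axis=0)[None, :])
            fit = fit_nb_glm_many(Y, design, offsets, alpha=finals, weights=weights)

    reduced = DesignInfo(np.ones((len(g), 1)), ("intercept",))
    fit_red = fit_nb_glm_many(Y, reduced, offsets, alpha=finals, weights=weights)
    lam = np.maximum(2.0 * (fit["loglik"] - fit_red["loglik"]), 0.0)
    p_lrt = stats.chi2.sf(lam, 1)

    lfc = fit["beta"][:, 1] / LN2
    se = fit["se"][:, 1] / LN2
    test = config.resolved_test()
    if test == "lrt":
        stat, pvalue = lam, p_lrt
    elif test == "wald":
        with np.errstate(invalid="ignore"):
            z = np.where(np.isfinite(se) & (se > 0), lfc / se, 0.0)
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
        pvalue[~(np.isfinite(se) & (se > 0))] = 1.0
        stat = z
    else:
        raise ValueError(f"unknown test {test!r}")

    mean_norm = (Y / (lib / lib.mean())[None, :]).mean(axis=1)
    res = _assemble_result(counts.transcript_ids, mean_norm, lfc, lfc, se,
                           finals, stat, pvalue, config.fdr)
    res.attrs["prior_df"] = float(prior_df)
    res.attrs["common_dispersion"] = float(common)
    return res


def run_engine(counts: CountMatrix, config: EngineConfig) -> pd.DataFrame:
    if config.engine == "shrink":
        return run_shrink_engine(counts, config)
    if config.engine in ("robust", "classic"):
        return run_robust_engine(counts, config)
    raise ValueError(f"unknown engine {config.engine!r}")


def compare_tests(counts: CountMatrix, classes=None, config: EngineConfig | None = None):
    """Wald vs LRT p-values from one shrink-engine fit.

    Returns (per-transcript DataFrame, per-stratum summary DataFrame).
    """
    config = config or EngineConfig(engine="shrink")
    res = run_shrink_engine(counts, config)
    table = res[["p_wald", "p_lrt"]].copy()
    strata = {"all": table.index}
    if classes is not None:
        strata["low"] = classes.stratum("low")
        strata["high"] = classes.stratum("high")
    rows = []
    for name, idx in strata.items():
        sub = table.loc[idx]
        with np.errstate(divide="ignore"):
            ratio = np.log10(np.maximum(sub["p_wald"], 1e-300)) - np.log10(
                np.maximum(sub["p_lrt"], 1e-300)
            )
        rows.append(
            {
                "stratum": name,
                "n": len(sub),
                "frac_wald_smaller": float((sub["p_wald"] < sub["p_lrt"]).mean()) if len(sub) else np.nan,
                "median_log10_ratio": float(np.median(ratio)) if len(sub) else np.nan,
            }
        )
    return table, pd.DataFrame(rows)
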