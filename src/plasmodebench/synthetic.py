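"""Synthetic negative-binomial count matrices with a low-count-heavy shape.

Counts are drawn from a Gamma-Poisson mixture so that
``Var(Y) = mu + alpha * mu**2``, with per-transcript baseline means
``q_i ~ LogNormal(location, scale)`` and a dispersion trend
``alpha(mu) = disp_a0 + disp_a1 / mu`` that decreases with abundance.
A heavy-tailed log-normal concentrates most reads in few transcripts,
leaving a large low-count tail that holds only a small share of reads.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = ["SimConfig", "default_config", "generate_counts", "generate_null_counts"]


@dataclass(frozen=True)
class SimConfig:
    n_transcripts: int = 2000
    n_per_group: int = 4
    logmean_location: float = 3.5
    logmean_scale: float = 2.0
    disp_a0: float = 0.04
    disp_a1: float = 0.2
    disp_lognorm_sd: float = 1.2  # transcript-level scatter around the trend
    libsize_factors: tuple = (0.7, 1.4)  # per-sample multipliers, or a (lo, hi) range
    frac_group_only: float = 0.0
    true_lfc_map: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_transcripts <= 0 or self.n_per_group < 2:
            raise ValueError("need n_transcripts >= 1 and n_per_group >= 2")
        if self.disp_a0 < 0 or self.disp_a1 < 0 or self.disp_lognorm_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.disp_a0 == 0 and self.disp_a1 == 0:
            raise ValueError("alpha(mu) must be positive; set disp_a0 or disp_a1 > 0")
        if not (0 <= self.frac_group_only < 1):
            raise ValueError("frac_group_only must be in [0, 1)")
        fac = np.asarray(self.libsize_factors, dtype=float)
        if np.any(fac <= 0):
            raise ValueError("library-size factors must be positive")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group


def default_config(**overrides) -> SimConfig:
    """Shipped default: ~2000 transcripts, 4+4 design, heavy low-count tail."""
    return replace(SimConfig(), **overrides)


def _substreams(seed: int):
    """One global seed -> independent named substreams (params, counts, structure)."""
    ss = np.random.SeedSequence(seed)
    params, counts, structure = ss.spawn(3)
    return (
        np.random.default_rng(params),
        np.random.default_rng(counts),
        np.random.default_rng(structure),
    )


def _libsize_factors(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    fac = np.asarray(config.libsize_factors, dtype=float)
    n = config.n_samples
    if fac.shape == (2,) and n != 2:
        return rng.uniform(fac[0], fac[1], size=n)
    if fac.shape != (n,):
        raise ValueError(f"libsize_factors must be a (lo, hi) range or length-{n} vector")
    return fac


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + alpha*mean^2 (Poisson when alpha ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    # Gamma shape 1/alpha, scale alpha*mean has mean `mean`, variance alpha*mean^2.
    lam = np.where(tiny, mean, rng.gamma(1.0 / np.where(tiny, 1.0, alpha),
                                         np.where(tiny, 1.0, alpha) * mean))
    out[:] = rng.poisson(lam)
    return out


def generate_counts(config: SimConfig) -> CountMatrix:
    """Simulate a two-group count matrix under the configured NB model.

    Counts ~ NB(mean = s_j * q_i * 2**(delta_i * g_j), dispersion = alpha(q_i))
    with group indicator g_j in {0, 1}. Transcripts designated "group-only"
    have all counts zeroed in group B after the draw.
    """
    rng_params, rng_counts, rng_struct = _substreams(config.seed)
    G, n = config.n_transcripts, config.n_samples

    q = rng_params.lognormal(config.logmean_location, config.logmean_scale, size=G)
    alpha = config.disp_a0 + config.disp_a1 / q
    if config.disp_lognorm_sd > 0:
        # genuine transcript-level dispersion heterogeneity around the trend
        alpha = alpha * rng_params.lognormal(0.0, config.disp_lognorm_sd, size=G)
    s = _libsize_factors(config, rng_params)

    tids = pd.Index([f"tx{i:06d}" for i in range(G)], name="transcript_id")
    sids = pd.Index([f"A{j + 1}" for j in range(config.n_per_group)]
                    + [f"B{j + 1}" for j in range(config.n_per_group)])
    g_j = np.r_[np.zeros(config.n_per_group), np.ones(config.n_per_group)]

    delta = np.zeros(G)
    if config.true_lfc_map:
        lut = pd.Series(config.true_lfc_map)
        hit = lut.index.intersection(tids)
        delta[tids.get_indexer(hit)] = lut.loc[hit].to_numpy()

    mean = s[None, :] * q[:, None] * 2.0 ** (delta[:, None] * g_j[None, :])
    counts = _draw_nb(rng_counts, mean, alpha[:, None])

    n_go = int(round(config.frac_group_only * G))
    if n_go:
        idx = rng_struct.choice(G, size=n_go, replace=False)
        counts[np.ix_(idx, np.flatnonzero(g_j == 1))] = 0

    groups = pd.Series(["A"] * config.n_per_group + ["B"] * config.n_per_group, index=sids)
    return CountMatrix(pd.DataFrame(counts, index=tids, columns=sids), groups)


def generate_null_counts(config: SimConfig) -> CountMatrix:
    """As :func:`generate_counts` with no effects and no group-only transcripts."""
    cfg = replace(config, true_lfc_map=None, frac_group_only=0.0)
    return generate_counts(cfg)
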