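"""Plasmode construction: balanced null repartitions of one condition's
samples, plus DE plasmodes made by spiking harvested log2 fold changes."""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "Partition",
    "PlasmodeDataset",
    "EffectPool",
    "enumerate_null_partitions",
    "build_null_plasmode",
    "harvest_effect_sizes",
    "spike_de_plasmode",
]


@dataclass(frozen=True)
class Partition:
    group_a: tuple
    group_b: tuple

    @property
    def samples(self) -> tuple:
        return self.group_a + self.group_b


@dataclass
class PlasmodeDataset:
    counts: CountMatrix
    partition_id: int
    replicate_id: int
    truth: pd.Series  # transcript -> spiked log2 fold change (0 = null)
    seed: int | None = None

    @property
    def n_spiked(self) -> int:
        return int((self.truth != 0).sum())


@dataclass
class EffectPool:
    effects: np.ndarray  # harvested log2 fold-change estimates
    source_fdr: float

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.size == 0:
            raise ValueError("effect pool is empty")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effect pool contains non-finite values")

    def __len__(self) -> int:
        return self.effects.size


def enumerate_null_partitions(sample_ids) -> list[Partition]:
    """All unordered partitions of the samples into two equal halves.

    The partition list is canonical: the lexicographically smallest sample
    always sits in group A, so each unordered split appears exactly once
    (count = C(n, n/2) / 2).
    """
    ids = sorted(sample_ids)
    n = len(ids)
    if n < 2 or n % 2:
        raise ValueError("need an even number (>= 2) of samples to partition")
    anchor, rest = ids[0], ids[1:]
    parts = []
    for combo in combinations(rest, n // 2 - 1):
        a = (anchor, *combo)
        b = tuple(s for s in ids if s not in a)
        parts.append(Partition(a, b))
    return parts


def build_null_plasmode(
    counts: CountMatrix, source_group, partition: Partition, partition_id: int = 0
) -> PlasmodeDataset:
    """Relabel one condition's samples into arbitrary groups A/B; counts
    are untouched and the truth table is all-null."""
    source = set(counts.samples_of(source_group))
    if set(partition.samples) != source:
        raise ValueError("partition does not cover exactly the source group's samples")
    order = list(partition.group_a) + list(partition.group_b)
    groups = pd.Series(
        ["A"] * len(partition.group_a) + ["B"] * len(partition.group_b), index=order
    )
    sub = counts.subset_samples(order, groups=groups)
    truth = pd.Series(0.0, index=sub.transcript_ids)
    return PlasmodeDataset(sub, partition_id=partition_id, replicate_id=0, truth=truth)


def harvest_effect_sizes(de_result: pd.DataFrame, fdr: float = 0.05) -> EffectPool:
    """Pool the LFC estimates of transcripts declared DE at the given FDR."""
    if not {"padj", "lfc_final"} <= set(de_result.columns):
        raise ValueError("DE result must have 'padj' and 'lfc_final' columns")
    sel = de_result[(de_result["padj"] <= fdr) & np.isfinite(de_result["lfc_final"])]
    if sel.empty:
        raise ValueError(
            f"no transcripts declared DE at FDR={fdr}; cannot harvest an effect "
            "pool — use source data with larger effects"
        )
    return EffectPool(sel["lfc_final"].to_numpy(), source_fdr=fdr)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def spike_de_plasmode(
    null_pl: PlasmodeDataset,
    pool: EffectPool,
    pi: float = 0.2,
    seed: int = 0,
    replicate_id: int = 0,
) -> PlasmodeDataset:
    """Spike round(pi*G) randomly chosen transcripts with effects sampled
    without replacement from the pool.

    For a chosen transcript with effect delta, every group-B count y becomes
    round(y * 2**delta) — i.e. delta is added on the log2 scale and
    back-transformed; zero counts stay zero.
    """
    if (null_pl.truth != 0).any():
        raise ValueError("source plasmode is not null (truth has nonzero deltas)")
    G = null_pl.counts.n_transcripts
    m = int(np.floor(pi * G + 0.5))
    if len(pool) < m:
        raise ValueError(f"effect pool ({len(pool)}) smaller than spike count ({m})")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(null_pl.partition_id, replicate_id))
    )
    chosen = rng.choice(G, size=m, replace=False)
    effects = rng.choice(pool.effects, size=m, replace=False)

    cm = null_pl.counts
    mat = cm.counts.to_numpy().astype(float)
    b_cols = np.flatnonzero((cm.groups == "B").to_numpy())
    scale = 2.0 ** effects
    mat[np.ix_(chosen, b_cols)] = _round_half_away(mat[np.ix_(chosen, b_cols)] * scale[:, None])
    spiked = CountMatrix(
        pd.DataFrame(mat.astype(np.int64), index=cm.transcript_ids, columns=cm.sample_ids),
        cm.groups.copy(),
    )
    truth = pd.Series(0.0, index=cm.transcript_ids)
    truth.iloc[chosen] = effects
    return PlasmodeDataset(
        spiked,
        partition_id=null_pl.partition_id,
        replicate_id=replicate_id,
        truth=truth,
        seed=seed,
    )
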