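"""Abundance stratification (low/mid/high) and the RP / CPM filtering rules."""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "AbundanceClasses",
    "FilterResult",
    "classify_abundance",
    "rp_filter",
    "compute_cpm",
    "cpm_filter",
    "apply_filter",
]


@dataclass
class AbundanceClasses:
    """Partition of transcripts into {low, mid, high} total-count classes.

    ``low_cutoff_total`` / ``high_cutoff_total`` are the realized count
    thresholds: every transcript with total <= low cutoff is "low", every
    transcript with total >= high cutoff is "high" (ties included, so class
    sizes may exceed the nominal percentiles).
    """

    label: pd.Series
    low_cutoff_total: int
    high_cutoff_total: int
    cum_curve: pd.DataFrame  # columns: cum_frac_transcripts, cum_frac_reads

    def stratum(self, name: str) -> pd.Index:
        return self.label.index[self.label == name]


@dataclass
class FilterResult:
    rule: str  # {"rp", "cpm", "none"}
    params: dict
    kept: pd.Series

    @property
    def n_removed(self) -> int:
        return int((~self.kept).sum())


def classify_abundance(
    counts: CountMatrix, low_pctile: float = 0.60, high_pctile: float = 0.03
) -> AbundanceClasses:
    """Rank transcripts by total count (descending) and cut at percentiles.

    The high class is the top ``high_pctile`` fraction (threshold = total of
    the transcript at rank ceil(high_pctile*G)); the low class is the bottom
    ``low_pctile`` fraction (threshold = total at the first rank past the
    top 1-low_pctile). Ties at either threshold join the respective class.
    """
    if not (0 < high_pctile < 1 and 0 < low_pctile < 1):
        raise ValueError("percentiles must be in (0, 1)")
    if low_pctile + high_pctile >= 1:
        raise ValueError("low_pctile + high_pctile must be < 1")
    G = counts.n_transcripts
    if G < 2:
        raise ValueError("need at least 2 transcripts to stratify")

    totals = counts.counts.sum(axis=1)
    order = totals.sort_values(ascending=False, kind="mergesort")
    sorted_totals = order.to_numpy()

    high_rank = math.ceil(high_pctile * G)  # 1-indexed from the top
    low_rank = math.floor((1.0 - low_pctile) * G) + 1  # first low-class rank
    low_rank = min(low_rank, G)
    if high_rank >= low_rank:
        raise ValueError("percentile ranks collide; too few transcripts")
    high_cutoff = int(sorted_totals[high_rank - 1])
    low_cutoff = int(sorted_totals[low_rank - 1])
    if low_cutoff >= high_cutoff:
        raise ValueError(
            f"abundance cutoffs collide (low {low_cutoff} >= high {high_cutoff}); "
            "data too uniform to stratify"
        )

    label = pd.Series("mid", index=totals.index)
    label[totals >= high_cutoff] = "high"
    label[totals <= low_cutoff] = "low"

    grand = float(sorted_totals.sum())
    cum_reads = np.concatenate([[0.0], np.cumsum(sorted_totals) / grand]) if grand > 0 else np.linspace(0, 1, G + 1)
    cum_tx = np.arange(G + 1) / G
    curve = pd.DataFrame({"cum_frac_transcripts": cum_tx, "cum_frac_reads": cum_reads})
    return AbundanceClasses(label, low_cutoff, high_cutoff, curve)


def rp_filter(counts: CountMatrix) -> FilterResult:
    """Reads-present rule: drop a transcript detected (count > 0) in fewer
    samples than one treatment group's size."""
    sizes = counts.group_sizes()
    if len(sizes) != 2:
        raise ValueError("RP filtering needs exactly two groups")
    vals = list(sizes.values())
    if vals[0] != vals[1]:
        warnings.warn(
            "unequal group sizes; RP threshold uses the larger group size",
            stacklevel=2,
        )
    threshold = max(vals)
    n_present = (counts.counts > 0).sum(axis=1)
    kept = n_present >= threshold
    return FilterResult("rp", {"threshold": threshold}, kept)


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """counts / library size * 1e6, library size = raw column sums."""
    lib = counts.lib_size
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts.counts / lib * 1e6


def cpm_filter(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples_below: int = 2
) -> FilterResult:
    """Drop a transcript when >= ``min_samples_below`` samples sit below
    ``min_cpm`` counts-per-million."""
    if min_samples_below > counts.n_samples:
        raise ValueError("min_samples_below exceeds the number of samples")
    cpm = compute_cpm(counts)
    n_below = (cpm < min_cpm).sum(axis=1)
    kept = n_below < min_samples_below
    return FilterResult("cpm", {"min_cpm": min_cpm, "min_samples_below": min_samples_below}, kept)


def apply_filter(counts: CountMatrix, rule: str = "none", **params) -> FilterResult:
    if rule == "none":
        return FilterResult("none", {}, pd.Series(True, index=counts.transcript_ids))
    if rule == "rp":
        return rp_filter(counts)
    if rule == "cpm":
        return cpm_filter(counts, **params)
    raise ValueError(f"unknown filter rule {rule!r}")
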