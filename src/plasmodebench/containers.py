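"""Core data container: an integer count matrix with sample grouping."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Transcripts x samples read-count matrix with a two-group annotation.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, one row per transcript, one
        column per sample. Row index = transcript ids, columns = sample ids.
    groups
        Mapping (Series) from sample id to group label.
    """

    counts: pd.DataFrame
    groups: pd.Series
    lib_size: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size == 0:
            raise ValueError("empty count matrix")
        if np.any(arr < 0):
            raise ValueError("count matrix contains negative entries")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("count matrix contains non-integral entries")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.groups = pd.Series(self.groups)
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.columns]
        self.counts = self.counts.astype(np.int64)
        self.lib_size = self.counts.sum(axis=0)

    # -- convenience accessors -------------------------------------------
    @property
    def transcript_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_labels(self) -> list:
        """Distinct group labels, in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def samples_of(self, group) -> list:
        return list(self.groups.index[self.groups == group])

    def group_sizes(self) -> dict:
        return {g: int((self.groups == g).sum()) for g in self.group_labels()}

    def subset_samples(self, sample_ids, groups: pd.Series | None = None) -> "CountMatrix":
        """Restrict to the given samples, optionally relabeling their groups."""
        sample_ids = list(sample_ids)
        sub = self.counts[sample_ids]
        grp = self.groups.loc[sample_ids] if groups is None else pd.Series(groups).loc[sample_ids]
        return CountMatrix(sub.copy(), grp.copy())

    def subset_transcripts(self, keep_mask: pd.Series) -> "CountMatrix":
        keep = pd.Series(keep_mask).reindex(self.counts.index)
        if keep.isna().any():
            raise ValueError("mask does not cover all transcripts")
        return CountMatrix(self.counts.loc[keep.astype(bool)].copy(), self.groups.copy())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups.equals(other.groups)
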