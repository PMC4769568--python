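"""Plain-text (TSV / YAML) readers and writers for the pipeline formats."""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import CountMatrix

COUNTS_INDEX = "transcript_id"


def write_counts(cm: CountMatrix, counts_path, groups_path=None) -> None:
    df = cm.counts.copy()
    df.index.name = COUNTS_INDEX
    df.to_csv(counts_path, sep="\t")
    if groups_path is not None:
        g = cm.groups.rename("group")
        g.index.name = "sample_id"
        g.to_csv(groups_path, sep="\t")


def read_counts(counts_path, groups_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return CountMatrix(df, groups)


def write_mask(kept: pd.Series, path) -> None:
    out = kept.astype(int).rename("kept")
    out.index.name = COUNTS_INDEX
    out.to_csv(path, sep="\t")


def read_mask(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["kept"].astype(bool)


def write_truth(truth: pd.Series, path) -> None:
    out = truth.rename("delta")
    out.index.name = COUNTS_INDEX
    out.to_csv(path, sep="\t")


def read_truth(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["delta"].astype(float)


def write_results(res: pd.DataFrame, path) -> None:
    out = res.copy()
    out.index.name = COUNTS_INDEX
    out.to_csv(path, sep="\t", float_format="%.10e")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
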