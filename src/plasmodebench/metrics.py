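"""Benjamini-Hochberg adjustment and confusion-matrix performance metrics."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionTable",
    "bh_adjust",
    "confusion",
    "performance",
    "stratified_performance",
]

METRIC_NAMES = ("FPR", "TPR", "PPV", "NPV", "ACC")


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for v in (self.TP, self.FP, self.TN, self.FN):
            if v < 0:
                raise ValueError("confusion cells must be non-negative")

    @property
    def S1(self) -> int:  # truly spiked
        return self.TP + self.FN

    @property
    def S0(self) -> int:  # truly null
        return self.FP + self.TN

    @property
    def R1(self) -> int:  # declared DE
        return self.TP + self.FP

    @property
    def R0(self) -> int:  # declared not DE
        return self.TN + self.FN

    @property
    def G(self) -> int:
        return self.S0 + self.S1


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values (NaN) are passed through and excluded from the count of
    tests. Raises on values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[ok] = unsorted
    return out


def confusion(calls: pd.Series, truth: pd.Series) -> ConfusionTable:
    """Cross-tabulate DE calls against spiked truth (delta != 0 = true DE)."""
    calls = pd.Series(calls).astype(bool)
    truth = pd.Series(truth).astype(float)
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth cover different transcript sets")
    truth = truth.loc[calls.index]
    spiked = truth != 0
    return ConfusionTable(
        TP=int((calls & spiked).sum()),
        FP=int((calls & ~spiked).sum()),
        TN=int((~calls & ~spiked).sum()),
        FN=int((~calls & spiked).sum()),
    )


def performance(ct: ConfusionTable) -> dict:
    """Table-2 style metric set; zero-denominator metrics come back as NaN
    (flagged undefined, never silently coerced)."""
    if ct.G == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "FPR": ratio(ct.FP, ct.S0),
        "TPR": ratio(ct.TP, ct.S1),
        "PPV": ratio(ct.TP, ct.R1),
        "NPV": ratio(ct.TN, ct.R0),
        "ACC": ratio(ct.TP + ct.TN, ct.G),
    }


def stratified_performance(calls: pd.Series, truth: pd.Series, classes=None) -> pd.DataFrame:
    """Confusion + metrics on all transcripts and on each abundance stratum.

    ``classes`` is an AbundanceClasses computed on the *source* data, so
    stratum membership is frozen before any spiking; its labels must cover
    the evaluated transcripts.
    """
    calls = pd.Series(calls).astype(bool)
    truth = pd.Series(truth)
    strata = {"all": calls.index}
    if classes is not None:
        for name in ("low", "high"):
            strata[name] = classes.stratum(name).intersection(calls.index)
    rows = []
    for name, idx in strata.items():
        if len(idx) == 0:
            row = {"stratum": name, "n": 0, "empty": True}
            row.update({m: float("nan") for m in METRIC_NAMES})
            rows.append(row)
            continue
        ct = confusion(calls.loc[idx], truth.loc[idx])
        row = {"stratum": name, "n": ct.G, "empty": False,
               "TP": ct.TP, "FP": ct.FP, "TN": ct.TN, "FN": ct.FN}
        row.update(performance(ct))
        rows.append(row)
    return pd.DataFrame(rows)
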