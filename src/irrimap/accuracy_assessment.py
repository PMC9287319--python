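"""Pixel-wise validation of a binary irrigation map against reference samples.

The irrigated class is the positive class throughout.  Producer's
accuracy (PA) is truth-conditional recall (1 - omission error), user's
accuracy (UA) prediction-conditional precision (1 - commission error);
overall accuracy, Cohen's kappa (standard two-class chance correction)
and the F1 score (harmonic mean of PA and UA) complete the report.
Reports are rounded to 3 decimal places.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_model import Grid

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics",
           "f1_from_pa_ua", "load_samples"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    producers_accuracy: float
    users_accuracy: float
    overall_accuracy: float
    kappa: float
    f1: float

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        return MetricsReport(*(round(v, ndigits) for v in self.__dict__.values()))

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def load_samples(path) -> pd.DataFrame:
    """Read a sample CSV with columns row,col,truth[,year] or x,y,truth[,year]."""
    df = pd.read_csv(path)
    if not ({"row", "col", "truth"} <= set(df.columns)
            or {"x", "y", "truth"} <= set(df.columns)):
        raise ValueError("sample file needs columns row,col,truth or x,y,truth")
    return df


def _sample_pixels(grid: Grid, samples: pd.DataFrame):
    if {"row", "col"} <= set(samples.columns):
        rows = samples["row"].to_numpy(dtype=int)
        cols = samples["col"].to_numpy(dtype=int)
    else:
        t = grid.transform
        # containing-cell lookup, no interpolation
        cols = np.floor((samples["x"].to_numpy(float) - t.x0) / t.dx).astype(int)
        rows = np.floor((samples["y"].to_numpy(float) - t.y0) / t.dy).astype(int)
    nr, nc = grid.shape
    if ((rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)).any():
        raise ValueError("sample point falls outside the map extent")
    return rows, cols


def confusion(map_grid: Grid, samples: pd.DataFrame) -> ConfusionCounts:
    """Confusion counts of the map against labeled sample points.

    ``samples`` carries either pixel addresses (row, col) or coordinates
    (x, y) mapped to the containing cell, plus a 0/1 ``truth`` column.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set: metrics undefined")
    rows, cols = _sample_pixels(map_grid, samples)
    pred = map_grid.values[rows, cols] != 0
    truth = samples["truth"].to_numpy() != 0
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fn=int((~pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """PA, UA, OA, kappa and F1 for the irrigated (positive) class.

    Undefined metrics (zero denominators) are reported as NaN with a
    warning rather than silently as zero.
    """
    n = c.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    pa = _ratio(c.tp, c.tp + c.fn, "producer's accuracy")
    ua = _ratio(c.tp, c.tp + c.fp, "user's accuracy")
    oa = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)) / n**2
    kappa = _ratio(oa - p_e, 1 - p_e, "kappa")
    f1 = f1_from_pa_ua(pa, ua)
    return MetricsReport(pa, ua, oa, kappa, f1)


def f1_from_pa_ua(pa: float, ua: float) -> float:
    """Harmonic mean of producer's and user's accuracy."""
    if np.isnan(pa) or np.isnan(ua) or pa + ua == 0:
        warnings.warn("F1 undefined", stacklevel=2)
        return float("nan")
    return 2 * pa * ua / (pa + ua)
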