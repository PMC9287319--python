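"""Coarse-grid irrigated-fraction trends over a stack of yearly binary maps.

Yearly 0/1 maps are aggregated to a coarse lattice (block mean: the
irrigated fraction of each coarse cell), each cell's fraction series is
regressed on calendar year by ordinary least squares, and cells are
masked when the trend is insignificant (two-sided p > 0.05) or the cell
never reaches a 5% irrigated fraction.  No multiple-testing correction
is applied across cells — a deliberately simple per-cell rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .grid_model import Grid, GridError, GridTransform

__all__ = ["TrendGrid", "aggregate_fraction", "linear_trend", "trend_map"]


@dataclass
class TrendGrid:
    """Per-coarse-cell slope, p-value, max fraction and mask flag."""

    slope: np.ndarray  # fraction / year
    p_value: np.ndarray
    max_fraction: np.ndarray
    masked: np.ndarray  # True where the cell should not be shown
    transform: GridTransform
    crs_tag: str = "EPSG:4326"
    p_threshold: float = 0.05
    min_fraction: float = 0.05


def _coarse_transform(t: GridTransform, factor: int) -> GridTransform:
    return GridTransform(t.x0, t.y0, t.dx * factor, t.dy * factor)


def aggregate_fraction(map_grid: Grid, factor: int) -> Grid:
    """Block-mean aggregation of a 0/1 map to an irrigated-fraction grid.

    Coarse cells average the 0/1 values of their ``factor``×``factor``
    fine cells.  Edge blocks where the dimensions do not divide evenly
    average only the existing fine cells.
    """
    if factor < 1:
        raise ValueError(f"aggregation factor must be >= 1, got {factor}")
    vals = (map_grid.values != 0).astype(float)
    nr, nc = vals.shape
    out_r, out_c = -(-nr // factor), -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = vals
    blocks = padded.reshape(out_r, factor, out_c, factor).transpose(0, 2, 1, 3)
    with np.errstate(invalid="ignore"):
        frac = np.nanmean(blocks.reshape(out_r, out_c, -1), axis=2)
    return Grid(frac, transform=_coarse_transform(map_grid.transform, factor),
                crs_tag=map_grid.crs_tag, nodata=float("nan"))


def linear_trend(years, fractions) -> tuple[float, float]:
    """OLS slope of fraction on calendar year and its two-sided p-value.

    Needs at least 3 distinct years.  A constant series has slope 0 and
    p = 1 (no evidence of trend).
    """
    years = np.asarray(years, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if years.size != y.size:
        raise ValueError("years and fractions differ in length")
    if np.unique(years).size < 3:
        raise ValueError("need at least 3 distinct years for a trend")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(years, y)
    return float(res.slope), float(res.pvalue)


def trend_map(
    maps: Mapping[int, Grid],
    factor: int,
    p_threshold: float = 0.05,
    min_fraction: float = 0.05,
    cropland_mask: Grid | None = None,
) -> TrendGrid:
    """Per-coarse-cell irrigated-fraction trend with display masking.

    ``maps`` is year -> binary map on one shared lattice.  With
    ``cropland_mask`` given, fractions use cropland pixels as the
    denominator (cells with no cropland are fully masked); by default the
    denominator is all fine pixels of the block.  A cell is masked when
    p > ``p_threshold`` or its maximum fraction over the years is below
    ``min_fraction``.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 yearly maps")
    years = sorted(maps)
    base = maps[years[0]]
    for y in years[1:]:
        if not base.same_lattice(maps[y]):
            raise GridError(f"map for year {y} not co-registered")

    crop_frac = None
    if cropland_mask is not None:
        crop_frac = aggregate_fraction(
            Grid(cropland_mask.values.astype(np.uint8), transform=base.transform,
                 crs_tag=base.crs_tag), factor).values

    frac_stack = []
    for y in years:
        f = aggregate_fraction(maps[y], factor).values
        if crop_frac is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(crop_frac > 0, f / crop_frac, np.nan)
        frac_stack.append(f)
    fracs = np.stack(frac_stack)  # (years, R, C)

    coarse_t = _coarse_transform(base.transform, factor)
    shape = fracs.shape[1:]
    slope = np.zeros(shape)
    pval = np.ones(shape)
    yr = np.asarray(years, dtype=float)
    for r in range(shape[0]):
        for c in range(shape[1]):
            series = fracs[:, r, c]
            if np.isnan(series).any():
                slope[r, c], pval[r, c] = np.nan, np.nan
                continue
            slope[r, c], pval[r, c] = linear_trend(yr, series)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN coarse cells
        max_frac = np.nanmax(fracs, axis=0)
    with np.errstate(invalid="ignore"):
        masked = np.isnan(pval) | (pval > p_threshold) | (max_frac < min_fraction)
    return TrendGrid(slope, pval, max_frac, masked, transform=coarse_t,
                     crs_tag=base.crs_tag, p_threshold=p_threshold,
                     min_fraction=min_fraction)
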