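"""Greenness-index computation, time-series smoothing, and annual-peak compositing.

The greenness index (GI) is the ratio of near-infrared to green surface
reflectance, a chlorophyll-sensitive proxy for canopy greenness.  A year
of 8-day composites (46 periods) is smoothed per pixel with a
Savitzky-Golay filter, and the annual maximum of the smoothed series is
the per-pixel irrigation indicator: irrigated crops reach higher annual
peaks than rainfed crops in the same region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .grid_model import Grid, GridError, GridTransform

__all__ = [
    "PERIODS_PER_YEAR",
    "ReflectanceComposite",
    "GITimeStack",
    "compute_gi",
    "smooth_series",
    "smooth_stack",
    "annual_peak",
]

PERIODS_PER_YEAR = 46  # 8-day composites per calendar year
GREEN_EPSILON = 1e-6  # reflectance guard against division by ~zero

DEFAULT_WINDOW = 7
DEFAULT_POLYORDER = 2


@dataclass
class ReflectanceComposite:
    """One 8-day composite: co-registered NIR and green reflectance bands."""

    nir: Grid
    green: Grid
    period_index: int = 1

    def __post_init__(self):
        if not self.nir.same_lattice(self.green):
            raise GridError("nir and green bands are not co-registered")


@dataclass
class GITimeStack:
    """Ordered GI grids for one year as a (T, rows, cols) float array.

    Invalid cells are NaN; temporal order follows the first axis.
    """

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    crs_tag: str = "EPSG:4326"
    year: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError(f"time stack must be 3-D (time, rows, cols), got {self.values.shape}")

    @classmethod
    def from_grids(cls, grids: Sequence[Grid], year: int = 0) -> "GITimeStack":
        if not grids:
            raise GridError("empty GI stack")
        base = grids[0]
        arr = np.empty((len(grids), *base.shape), dtype=float)
        for i, g in enumerate(grids):
            if not base.same_lattice(g):
                raise GridError(f"composite {i} not co-registered with the first")
            vals = g.values.astype(float)
            vals[~g.valid_mask()] = np.nan
            arr[i] = vals
        return cls(arr, transform=base.transform, crs_tag=base.crs_tag, year=year)

    def __len__(self) -> int:
        return self.values.shape[0]


def compute_gi(composite: ReflectanceComposite) -> Grid:
    """Per-pixel NIR/green ratio; invalid where green <= epsilon or either band nodata."""
    nir, green = composite.nir, composite.green
    n = nir.values.astype(float)
    g = green.values.astype(float)
    valid = nir.valid_mask() & green.valid_mask() & (g > GREEN_EPSILON)
    gi = np.full(n.shape, np.nan)
    gi[valid] = n[valid] / g[valid]
    return Grid(gi, transform=nir.transform, crs_tag=nir.crs_tag, nodata=float("nan"))


def _check_sg_params(length: int, window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if polyorder < 0 or polyorder >= window:
        raise ValueError(f"polyorder must satisfy 0 <= polyorder < window, got {polyorder}")
    if length < window:
        raise ValueError(f"series length {length} shorter than window {window}")


def smooth_series(
    series: Sequence[float],
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> np.ndarray:
    """Savitzky-Golay smoothing of one series.

    A local least-squares polynomial of the given order is fitted in a
    sliding window; the ends are handled by evaluating the polynomial
    fitted to the edge window (scipy's ``interp`` mode), so length is
    preserved and polynomials up to ``polyorder`` pass through unchanged.
    """
    x = np.asarray(series, dtype=float)
    _check_sg_params(x.size, window, polyorder)
    return savgol_filter(x, window, polyorder, mode="interp")


def smooth_stack(
    stack: GITimeStack,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> GITimeStack:
    """Smooth every pixel's series along time.

    Pixels with missing composites are linearly interpolated over time
    before filtering and re-masked afterwards, so holes neither block the
    filter nor gain invented values.
    """
    vals = stack.values
    _check_sg_params(vals.shape[0], window, polyorder)
    nan_mask = np.isnan(vals)
    work = vals
    if nan_mask.any():
        work = vals.copy()
        t = np.arange(vals.shape[0])
        holes = nan_mask.any(axis=0) & ~nan_mask.all(axis=0)
        for r, c in zip(*np.nonzero(holes)):
            m = nan_mask[:, r, c]
            work[m, r, c] = np.interp(t[m], t[~m], vals[~m, r, c])
    smoothed = savgol_filter(work, window, polyorder, axis=0, mode="interp")
    smoothed[nan_mask] = np.nan
    return GITimeStack(smoothed, transform=stack.transform, crs_tag=stack.crs_tag, year=stack.year)


def annual_peak(stack: GITimeStack) -> Grid:
    """Per-pixel maximum GI over the year's valid composites.

    Pixels with no valid composite at all become NaN (nodata).
    """
    if len(stack) == 0:
        raise GridError("empty GI stack")
    with np.errstate(invalid="ignore"):
        all_nan = np.isnan(stack.values).all(axis=0)
        peak = np.full(stack.values.shape[1:], np.nan)
        peak[~all_nan] = np.nanmax(stack.values[:, ~all_nan], axis=0)
    return Grid(peak, transform=stack.transform, crs_tag=stack.crs_tag, nodata=float("nan"))
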