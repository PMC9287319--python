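"""Area-constrained threshold allocation: the core downscaling step.

Within each administrative region, cropland pixels are ranked in
descending order of a per-pixel rank field (annual peak GI in step one,
the multi-product agreement score in step two).  Distinct rank levels are
accumulated from the top until the cumulative pixel area is closest to
the region's reported irrigated area; all pixels at or above that
threshold are labeled irrigated.  Tie groups are taken whole — the
selection is always a superlevel set of the rank field — and when two
cumulative areas are equidistant from the target the smaller one wins
(higher threshold), a conservative choice given that reported areas tend
to underestimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .grid_model import Grid, GridError

__all__ = ["AllocationTrace", "allocate_region", "allocate_map"]


@dataclass
class AllocationTrace:
    """Audit record of one region's allocation."""

    region_id: int = 0
    levels: np.ndarray = field(default_factory=lambda: np.array([]))
    cumulative_area: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: Optional[float] = None
    achieved_area: float = 0.0
    target_area: float = 0.0
    n_pixels: int = 0
    n_selected: int = 0

    def to_rows(self):
        """(level, cumulative_area) rows for CSV export."""
        return list(zip(self.levels.tolist(), self.cumulative_area.tolist()))


def allocate_region(
    ranks,
    pixel_area: float,
    target: float,
    region_id: int = 0,
    quantize_decimals: Optional[int] = None,
):
    """Select the superlevel set of ``ranks`` whose area best matches ``target``.

    Parameters
    ----------
    ranks : 1-D array of rank values for the region's valid cropland pixels.
    pixel_area : area of one pixel in hectares (> 0).
    target : the region's reported irrigated area in hectares (>= 0).
    quantize_decimals : optionally round ranks before grouping, emulating
        discrete index levels for continuous fields.

    Returns
    -------
    (threshold, selected, trace) where ``selected`` is a boolean array
    aligned with ``ranks``.  ``threshold`` is None for an empty selection.
    A zero target selects nothing; a target at or beyond the total
    cropland area selects everything (the closest reachable area).
    """
    if pixel_area <= 0:
        raise ValueError(f"pixel_area must be positive, got {pixel_area}")
    if target < 0:
        raise ValueError(f"target area must be non-negative, got {target}")
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 1:
        raise ValueError("ranks must be 1-D")
    if quantize_decimals is not None:
        ranks = np.round(ranks, quantize_decimals)

    trace = AllocationTrace(region_id=region_id, target_area=float(target),
                            n_pixels=int(ranks.size))
    if ranks.size == 0 or target == 0:
        return None, np.zeros(ranks.shape, dtype=bool), trace

    levels, counts = np.unique(ranks, return_counts=True)
    levels, counts = levels[::-1], counts[::-1]  # descending rank order
    cumulative = np.cumsum(counts) * float(pixel_area)
    gaps = np.abs(cumulative - target)
    best = int(np.argmin(gaps))  # first minimum -> smaller cumulative on ties
    threshold = float(levels[best])
    selected = ranks >= threshold

    trace.levels = levels
    trace.cumulative_area = cumulative
    trace.threshold = threshold
    trace.achieved_area = float(cumulative[best])
    trace.n_selected = int(selected.sum())
    return threshold, selected, trace


def allocate_map(
    ranks: Grid,
    mask: Grid,
    regions: Grid,
    targets: Mapping[int, float],
    pixel_area: float,
    quantize_decimals: Optional[int] = None,
):
    """Apply allocate_region independently in every labeled region.

    Non-cropland pixels and label 0 (outside the study area) stay 0.
    Regions holding cropland but missing from ``targets`` are warned
    about and left empty.  Returns the binary irrigation map and a dict
    of per-region AllocationTraces.
    """
    if not (ranks.same_lattice(mask) and ranks.same_lattice(regions)):
        raise GridError("rank field, mask and region labels must share one lattice")

    cropland = mask.values.astype(bool)
    valid = cropland & ranks.valid_mask()
    labels = regions.values
    out = np.zeros(ranks.shape, dtype=np.uint8)
    traces: dict[int, AllocationTrace] = {}

    for rid in np.unique(labels[labels > 0]):
        in_region = valid & (labels == rid)
        if not in_region.any():
            continue
        if rid not in targets:
            warnings.warn(f"region {rid}: cropland present but no target area; left empty",
                          stacklevel=2)
            traces[int(rid)] = AllocationTrace(region_id=int(rid),
                                               n_pixels=int(in_region.sum()))
            continue
        region_ranks = ranks.values[in_region].astype(float)
        _, selected, trace = allocate_region(
            region_ranks, pixel_area, targets[rid], region_id=int(rid),
            quantize_decimals=quantize_decimals,
        )
        sel_map = np.zeros(ranks.shape, dtype=bool)
        sel_map[in_region] = selected
        out[sel_map] = 1
        traces[int(rid)] = trace

    return Grid(out, transform=ranks.transform, crs_tag=ranks.crs_tag, nodata=None), traces
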