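"""Per-region irrigated-area statistics: loading, gap-filling, level resolution.

Reported irrigated areas come at county, municipal, or provincial level
with gaps in some years.  Interior gaps are filled by linear interpolation
between the nearest reported years; leading and trailing gaps take the
nearest reported value.  County-level records are used in priority; when
absent, the coarser level's total is apportioned to counties in proportion
to their cropland pixel counts (configurable), so the fine-grained
allocator keeps a uniform per-region contract and coarse totals are
conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "StatRecord",
    "StatTable",
    "load_stats",
    "fill_missing_years",
    "resolve_level",
]

LEVELS = ("county", "municipal", "provincial")


@dataclass(frozen=True)
class StatRecord:
    region_id: int
    year: int
    area_ha: float
    level: str = "county"
    source: str = "reported"

    def __post_init__(self):
        if self.area_ha < 0:
            raise ValueError(f"negative irrigated area: {self.area_ha}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown admin level {self.level!r}")


class StatTable:
    """Collection of StatRecords keyed by (region_id, year, level)."""

    def __init__(self, records=()):
        self._records: dict[tuple[int, int, str], StatRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: StatRecord) -> None:
        key = (rec.region_id, rec.year, rec.level)
        if key in self._records:
            raise ValueError(f"duplicate statistics record for {key}")
        self._records[key] = rec

    def get(self, region_id: int, year: int, level: str) -> Optional[StatRecord]:
        return self._records.get((region_id, year, level))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.region_id, r.year, r.area_ha, r.level, r.source) for r in self],
            columns=["region_id", "year", "area_ha", "level", "source"],
        )

    def targets_for_year(self, year: int, level: str = "county") -> dict[int, float]:
        """region_id -> area for one year at one level."""
        return {
            r.region_id: r.area_ha for r in self if r.year == year and r.level == level
        }


def load_stats(path, unit_factor: float = 1.0) -> StatTable:
    """Read a CSV with columns region_id, year, area_ha, level [, source].

    ``unit_factor`` converts the file's area unit to hectares (e.g. 1000
    for files in thousand hectares).  Negative areas and duplicate
    (region, year, level) keys are rejected.
    """
    df = pd.read_csv(path)
    required = {"region_id", "year", "area_ha", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"statistics file missing columns: {sorted(missing)}")
    if df[["region_id", "year", "area_ha"]].isna().any().any():
        raise ValueError("statistics file contains malformed (missing) values")
    table = StatTable()
    for row in df.itertuples(index=False):
        table.add(
            StatRecord(
                region_id=int(row.region_id),
                year=int(row.year),
                area_ha=float(row.area_ha) * unit_factor,
                level=str(row.level),
                source=str(getattr(row, "source", "reported")),
            )
        )
    return table


def fill_missing_years(series: Mapping[int, float], years) -> dict[int, float]:
    """Complete a year -> area series over an inclusive year range.

    Interior gaps: linear interpolation between the nearest reported
    neighbors.  Leading/trailing gaps: constant extrapolation of the
    nearest reported value.  Reported values pass through unchanged.
    """
    if not series:
        raise ValueError("cannot fill an empty statistics series")
    years = list(years)
    obs_years = np.array(sorted(series))
    obs_vals = np.array([series[y] for y in obs_years], dtype=float)
    filled = np.interp(np.asarray(years, dtype=float), obs_years, obs_vals)
    return {int(y): float(v) for y, v in zip(years, filled)}


def _cropland_share(
    region_id: int,
    parent: int,
    hierarchy: Mapping[int, int],
    cropland_counts: Mapping[int, float],
) -> float:
    siblings = [r for r, p in hierarchy.items() if p == parent]
    total = sum(cropland_counts.get(r, 0) for r in siblings)
    if total <= 0:
        # no cropland information: split evenly among siblings
        return 1.0 / len(siblings) if siblings else 1.0
    return cropland_counts.get(region_id, 0) / total


def resolve_level(
    table: StatTable,
    region_id: int,
    year: int,
    hierarchy: Mapping[int, int],
    cropland_counts: Optional[Mapping[int, float]] = None,
    apportion: bool = True,
) -> StatRecord:
    """Effective irrigated area for one county and year.

    Strict county -> municipal -> provincial fallback.  A coarse-level
    total is apportioned to the county by its cropland share among the
    coarse region's children (``apportion=True``), or passed through
    whole (``apportion=False``, treating the coarse region as a single
    allocation unit).  Provenance is recorded in ``source``.
    """
    rec = table.get(region_id, year, "county")
    if rec is not None:
        return rec

    child = region_id
    for level in ("municipal", "provincial"):
        parent = hierarchy.get(child)
        if parent is None:
            break
        rec = table.get(parent, year, level)
        if rec is not None:
            if not apportion:
                return StatRecord(region_id, year, rec.area_ha, "county",
                                  source=f"{level}:{parent} (whole)")
            share = _cropland_share(region_id, parent, _descendants_map(hierarchy, level),
                                    cropland_counts or {})
            return StatRecord(region_id, year, rec.area_ha * share, "county",
                              source=f"{level}:{parent} (share {share:.4f})")
        child = parent
    raise KeyError(f"no statistics at any admin level for region {region_id}, year {year}")


def _descendants_map(hierarchy: Mapping[int, int], level: str) -> Mapping[int, int]:
    """child -> ancestor map at the requested fallback depth.

    For municipal fallback the hierarchy's direct county->municipality
    edges suffice; for provincial fallback counties are re-keyed to their
    province (two levels up) so shares are computed among all counties of
    the province.
    """
    if level == "municipal":
        return hierarchy
    out = {}
    for child, parent in hierarchy.items():
        grand = hierarchy.get(parent)
        if grand is not None:
            out[child] = grand
    return out


def apportioned_targets(
    table: StatTable,
    region_ids,
    year: int,
    hierarchy: Mapping[int, int],
    cropland_counts: Optional[Mapping[int, float]] = None,
    apportion: bool = True,
) -> dict[int, float]:
    """Resolve every region's effective target for one year; regions with
    no statistics at any level are dropped with a warning."""
    out: dict[int, float] = {}
    for rid in region_ids:
        try:
            out[rid] = resolve_level(table, rid, year, hierarchy, cropland_counts, apportion).area_ha
        except KeyError:
            warnings.warn(f"region {rid}: no statistics for {year} at any level", stacklevel=2)
    return out
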