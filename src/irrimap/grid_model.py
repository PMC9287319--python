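"""Core single-band raster model shared by every pipeline stage.

All layers of one study area live on a single lattice (same shape,
transform and CRS tag); reprojection between coordinate systems is treated
as upstream preprocessing and refused here.  Grids are stored as GeoTIFF
(single band, north-up affine georeference); binary irrigation maps are
8-bit with 1 = irrigated, 0 = non-irrigated and no nodata tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "Grid",
    "GridError",
    "read_grid",
    "write_grid",
    "apply_mask",
    "align_nearest",
    "pixel_area_ha",
]

# GeoTIFF / GDAL tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic
_GT_RASTER_TYPE = 1025  # 1 = PixelIsArea
_GEOGRAPHIC_TYPE = 2048
_PROJECTED_CS_TYPE = 3072


class GridError(ValueError):
    """Raised for invalid grids, lattice mismatches, or bad raster files."""


class GridTransform(NamedTuple):
    """North-up affine georeference of a grid.

    ``(x0, y0)`` is the outer corner of pixel (0, 0) (upper-left);
    ``dx`` is the pixel width (> 0) and ``dy`` the signed row step
    (negative for the usual north-up orientation).
    """

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = -1.0

    def cell_center(self, row, col):
        """Map (row, col) -> (x, y) of the cell center."""
        return (
            self.x0 + (np.asarray(col) + 0.5) * self.dx,
            self.y0 + (np.asarray(row) + 0.5) * self.dy,
        )


@dataclass
class Grid:
    """A single-band raster: values + georeference + nodata sentinel."""

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    crs_tag: str = "EPSG:4326"
    nodata: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridError(f"grid values must be 2-D, got shape {self.values.shape}")
        if not isinstance(self.transform, GridTransform):
            self.transform = GridTransform(*self.transform)
        if self.transform.dx <= 0 or self.transform.dy == 0:
            raise GridError(f"cell size must be strictly positive: {self.transform}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean array of cells carrying a valid (non-nodata) value."""
        valid = np.ones(self.shape, dtype=bool)
        if self.values.dtype.kind == "f":
            valid &= ~np.isnan(self.values)
        if self.nodata is not None and not (
            isinstance(self.nodata, float) and math.isnan(self.nodata)
        ):
            valid &= self.values != self.nodata
        return valid

    def same_lattice(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.crs_tag == other.crs_tag
            and np.allclose(self.transform, other.transform)
        )

    def copy_with(self, values: np.ndarray, **kw) -> "Grid":
        return replace(self, values=values, **kw)


def _require_same_lattice(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_lattice(g):
            raise GridError(
                f"lattice mismatch: {first.shape}/{first.transform} vs {g.shape}/{g.transform}"
            )


def _geokeys_for(crs_tag: str) -> Optional[tuple[int, ...]]:
    """Minimal GeoKeyDirectory for an EPSG:<code> tag, or None."""
    if not crs_tag or not crs_tag.upper().startswith("EPSG:"):
        return None
    try:
        code = int(crs_tag.split(":", 1)[1])
    except ValueError:
        return None
    geographic = 4000 <= code < 5000  # EPSG geographic CRS block (4326 etc.)
    keys = [
        (_GT_MODEL_TYPE, 0, 1, 2 if geographic else 1),
        (_GT_RASTER_TYPE, 0, 1, 1),
    ]
    keys.append((_GEOGRAPHIC_TYPE if geographic else _PROJECTED_CS_TYPE, 0, 1, code))
    header = (1, 1, 0, len(keys))
    flat: list[int] = list(header)
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def _crs_from_geokeys(values) -> str:
    vals = list(values)
    for i in range(4, len(vals) - 3, 4):
        key, loc, _count, value = vals[i : i + 4]
        if loc == 0 and key in (_GEOGRAPHIC_TYPE, _PROJECTED_CS_TYPE):
            return f"EPSG:{value}"
    return ""


def write_grid(grid: Grid, path) -> None:
    """Write a grid as a single-band GeoTIFF.

    Binary/boolean grids are stored as 8-bit unsigned integers with 1/0
    semantics and no nodata tag; other grids keep their dtype and carry
    the nodata sentinel in the GDAL nodata tag.
    """
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    t = grid.transform
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.dx, abs(t.dy), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
    ]
    geokeys = _geokeys_for(grid.crs_tag)
    if geokeys is not None:
        extratags.append((_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys))
    if grid.nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, str(grid.nodata)))
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_grid(path, expected_kind: str = "continuous") -> Grid:
    """Read a single-band GeoTIFF as a Grid.

    expected_kind:
        ``continuous`` — any numeric raster (nodata honored);
        ``binary``     — values must be {0, 1}; returned as uint8;
        ``labels``     — non-negative integer region identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise GridError(f"no such raster: {path}")
    try:
        tif = tifffile.TiffFile(str(path))
    except Exception as exc:  # corrupt / not a TIFF
        raise GridError(f"unreadable raster {path}: {exc}") from exc
    with tif:
        if len(tif.pages) != 1:
            raise GridError(f"{path}: expected a single-band raster, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise GridError(f"{path}: expected a single band, found {page.samplesperpixel}")
        values = page.asarray()
        tags = page.tags
        scale = tags.valueof(_MODEL_PIXEL_SCALE)
        tiepoint = tags.valueof(_MODEL_TIEPOINT)
        if scale is not None and tiepoint is not None:
            transform = GridTransform(
                x0=float(tiepoint[3]), y0=float(tiepoint[4]),
                dx=float(scale[0]), dy=-float(scale[1]),
            )
        else:
            transform = GridTransform()
        geokeys = tags.valueof(_GEO_KEY_DIRECTORY)
        crs_tag = _crs_from_geokeys(geokeys) if geokeys is not None else ""
        nodata_raw = tags.valueof(_GDAL_NODATA)
        nodata = None
        if nodata_raw is not None:
            nodata = float(nodata_raw)
            if values.dtype.kind in "iu" and float(nodata).is_integer():
                nodata = int(nodata)

    if expected_kind == "binary":
        if nodata is not None:
            raise GridError(f"{path}: binary maps must not carry nodata")
        if not np.isin(values, (0, 1)).all():
            bad = np.unique(values[~np.isin(values, (0, 1))])
            raise GridError(f"{path}: binary raster contains values outside {{0,1}}: {bad}")
        values = values.astype(np.uint8)
    elif expected_kind == "labels":
        if values.dtype.kind not in "iu":
            raise GridError(f"{path}: region-label raster must be integer, got {values.dtype}")
        if (values < 0).any():
            raise GridError(f"{path}: region labels must be non-negative")
    elif expected_kind != "continuous":
        raise GridError(f"unknown expected_kind {expected_kind!r}")

    return Grid(values=values, transform=transform, crs_tag=crs_tag, nodata=nodata)


def apply_mask(grid: Grid, mask: Grid) -> Grid:
    """Set cells outside the cropland mask invalid.

    Continuous grids get the nodata sentinel (NaN if none is declared and
    the dtype is float); binary/integer grids get 0, matching the
    convention that missing = non-irrigated in the deposited products.
    """
    _require_same_lattice(grid, mask)
    keep = mask.values.astype(bool)
    values = grid.values.copy()
    if values.dtype.kind == "f":
        fill = grid.nodata if grid.nodata is not None else np.nan
        values[~keep] = fill
        nodata = grid.nodata if grid.nodata is not None else float("nan")
        return grid.copy_with(values, nodata=nodata)
    values[~keep] = grid.nodata if grid.nodata is not None else 0
    return grid.copy_with(values)


def align_nearest(source: Grid, template: Grid) -> Grid:
    """Resample ``source`` onto ``template``'s lattice by nearest cell center.

    Both grids must share a CRS tag and overlap; template cells falling
    outside the source extent get the source nodata (0 for integer grids
    without one).  A template center equidistant from several source
    centers (on a cell boundary) takes the cell containing it.  Never
    interpolates: every output value occurs in the source.
    """
    if source.crs_tag != template.crs_tag:
        raise GridError(f"CRS mismatch: {source.crs_tag!r} vs {template.crs_tag!r}")
    st, tt = source.transform, template.transform
    rows, cols = template.shape
    cx, cy = tt.cell_center(*np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"))
    # index of the source cell containing each template center == nearest center
    src_col = np.floor((cx - st.x0) / st.dx).astype(int)
    src_row = np.floor((cy - st.y0) / st.dy).astype(int)
    inside = (
        (src_row >= 0) & (src_row < source.shape[0])
        & (src_col >= 0) & (src_col < source.shape[1])
    )
    if not inside.any():
        raise GridError("disjoint extents: no template cell falls inside the source")
    if source.nodata is not None:
        fill = source.nodata
    elif source.values.dtype.kind == "f":
        fill = np.nan
    else:
        fill = 0
    out = np.full(template.shape, fill, dtype=source.values.dtype)
    out[inside] = source.values[src_row[inside], src_col[inside]]
    return Grid(out, transform=tt, crs_tag=template.crs_tag, nodata=source.nodata)


def pixel_area_ha(transform: GridTransform, unit_to_m: float = 1.0) -> float:
    """Pixel area in hectares: |dx * dy| in projected units, scaled to meters.

    The default study grid uses 500-m pixels, i.e. 25 ha per pixel.
    """
    return abs(transform.dx * transform.dy) * unit_to_m**2 / 10_000.0
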