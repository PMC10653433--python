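"""Grid model and raster I/O shared by every pipeline stage.

All rasters live on an axis-aligned, north-up grid of square cells
(nominally 1 km).  Cell values refer to the whole cell; a point belongs to
the cell whose half-open footprint ``[x, x + size) x (y - size, y]``
contains it, so extraction is deterministic on cell boundaries.  Row 0 is
the northernmost row and ``origin_x/origin_y`` name the outer corner of
the top-left cell, matching the common GeoTIFF layout.

GeoTIFFs are read and written with :mod:`tifffile`, using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON
payload in ImageDescription carrying the CRS identifier, units and, for
categorical rasters, the legend.  The CRS is treated as an opaque string:
no reprojection is performed anywhere, and every stage hard-fails on grid
misalignment instead of resampling silently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "CategoricalRaster",
    "ContinuousRaster",
    "GridError",
    "read_categorical",
    "write_categorical",
    "read_continuous",
    "write_continuous",
    "resample_nearest",
    "extract_at_points",
]

logger = logging.getLogger(__name__)

CATEGORICAL_NODATA = -1

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Raised when a raster lacks grid metadata or grids are misaligned."""


@dataclass(frozen=True)
class Grid:
    """Georeferenced raster grid (north-up, square cells).

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates of the top-left corner of the top-left cell.
    pixel_size
        Cell edge length in map units; must be positive.
    n_rows, n_cols
        Raster dimensions.
    crs_id
        Opaque CRS identifier (never interpreted).
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise GridError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned(self, other: "Grid") -> bool:
        return self == other

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys): per-column center x and per-row center y."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return xs, ys

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) arrays of cell-center x and y."""
        xs, ys = self.cell_centers()
        return np.broadcast_to(xs, self.shape).copy(), np.broadcast_to(
            ys[:, None], self.shape
        ).copy()

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); may fall outside the raster."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(int)
        # half-open in both axes; a cell's left and top edges belong to it
        row = np.floor((self.origin_y - y) / self.pixel_size).astype(int)
        return row, col

    def contains_rowcol(self, row, col) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def _check_shape(grid: Grid, arr: np.ndarray) -> None:
    if arr.shape != grid.shape:
        raise GridError(f"array shape {arr.shape} does not match grid {grid.shape}")


@dataclass
class CategoricalRaster:
    """Integer class codes on a grid, with a code -> label legend."""

    grid: Grid
    codes: np.ndarray
    nodata: int = CATEGORICAL_NODATA
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        _check_shape(self.grid, self.codes)
        present = set(np.unique(self.codes[self.codes != self.nodata]).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes without legend entry: {sorted(missing)}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata

    def copy_with(self, codes: np.ndarray, legend: dict[int, str] | None = None):
        return CategoricalRaster(
            self.grid, codes, self.nodata, dict(self.legend if legend is None else legend)
        )


@dataclass
class ContinuousRaster:
    """Real-valued surface on a grid; NaN marks nodata."""

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_shape(self.grid, self.values)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


# District zones are plain categorical rasters whose codes are district ids.
DistrictZones = CategoricalRaster


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_extratags(grid: Grid, nodata) -> list:
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", None, str(nodata)),
    ]


def _read_grid(page, shape) -> Grid:
    scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie = page.tags.get(_TAG_MODEL_TIEPOINT)
    desc = page.tags.get(270)
    meta = {}
    if desc is not None:
        try:
            meta = json.loads(desc.value)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if scale is None or tie is None:
        raise GridError("no grid: file lacks GeoTIFF georeferencing tags")
    sx, sy = float(scale.value[0]), float(scale.value[1])
    if not np.isclose(sx, sy):
        raise GridError("non-square pixels are unsupported")
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    origin_x = x - j * sx
    origin_y = y + i * sy
    return Grid(
        origin_x=origin_x,
        origin_y=origin_y,
        pixel_size=sx,
        n_rows=shape[0],
        n_cols=shape[1],
        crs_id=str(meta.get("crs_id", "local")),
    ), meta


def write_categorical(raster: CategoricalRaster, path) -> str:
    meta = {
        "crs_id": raster.grid.crs_id,
        "legend": {str(k): v for k, v in raster.legend.items()},
        "kind": "categorical",
    }
    tifffile.imwrite(
        str(path),
        raster.codes.astype(np.int32),
        extratags=_geo_extratags(raster.grid, raster.nodata),
        description=json.dumps(meta),
    )
    return str(path)


def read_categorical(path) -> CategoricalRaster:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = tf.asarray().astype(np.int32)
        grid, meta = _read_grid(page, data.shape)
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = int(float(str(nd_tag.value))) if nd_tag is not None else CATEGORICAL_NODATA
    legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return CategoricalRaster(grid, data, nodata, legend)


def write_continuous(raster: ContinuousRaster, path) -> str:
    meta = {"crs_id": raster.grid.crs_id, "units": raster.units, "kind": "continuous"}
    tifffile.imwrite(
        str(path),
        raster.values.astype(np.float32),
        extratags=_geo_extratags(raster.grid, "nan"),
        description=json.dumps(meta),
    )
    return str(path)


def read_continuous(path) -> ContinuousRaster:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = tf.asarray().astype(np.float64)
        grid, meta = _read_grid(page, data.shape)
    return ContinuousRaster(grid, data, units=str(meta.get("units", "")))


# ---------------------------------------------------------------------------
# Alignment helpers


def resample_nearest(src: ContinuousRaster, target: Grid) -> ContinuousRaster:
    """Nearest-neighbor resampling of a continuous surface onto ``target``.

    Each target cell takes the value of the source cell containing the
    target cell's center (which, for cells inside the source extent, is the
    cell with the nearest center).  Target centers outside the source extent
    become nodata; fully disjoint extents yield an all-nodata raster with a
    warning.
    """
    if src.grid == target:
        return ContinuousRaster(target, src.values.copy(), src.units)
    xs, ys = target.cell_centers()
    xg = np.broadcast_to(xs, target.shape)
    yg = np.broadcast_to(ys[:, None], target.shape)
    row, col = src.grid.xy_to_rowcol(xg, yg)
    inside = src.grid.contains_rowcol(row, col)
    out = np.full(target.shape, np.nan)
    if not inside.any():
        warnings.warn("source and target extents are disjoint: all-nodata output")
        return ContinuousRaster(target, out, src.units)
    out[inside] = src.values[row[inside], col[inside]]
    return ContinuousRaster(target, out, src.units)


def extract_at_points(raster: ContinuousRaster, points) -> np.ndarray:
    """Values of the cells containing ``points`` (sequence of (x, y)).

    Points outside the extent or over nodata cells yield NaN.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    row, col = raster.grid.xy_to_rowcol(pts[:, 0], pts[:, 1])
    inside = raster.grid.contains_rowcol(row, col)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("extract_at_points: %d point(s) outside raster extent", n_out)
    vals = np.full(len(pts), np.nan)
    vals[inside] = raster.values[row[inside], col[inside]]
    return vals
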