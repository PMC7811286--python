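"""Grid data model and georeferenced raster I/O.

All layers in the package live on a regular geographic (lon/lat, WGS84)
grid of square cells. Cell (0, 0) is the upper-left cell; cell centers sit
at ``origin + (index + 0.5) * cell_size`` with latitude decreasing down
rows. Every point-in-cell test in the package uses cell centers.

Rasters are read and written as single-band GeoTIFF files carrying the
standard geo tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory for
geographic WGS84, and GDAL_NODATA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "EARTH_RADIUS_KM",
    "RasterGrid",
    "EnvStack",
    "haversine_km",
    "read_raster",
    "write_raster",
    "buffer_mask",
    "count_mask_cells",
]

#: Fixed spherical Earth radius used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0

# TIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKey directory declaring a geographic WGS84 raster
# (ModelType=2 geographic, RasterType=1 pixel-is-area, GCS=EPSG:4326).
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class RasterGrid:
    """A single georeferenced layer of square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    origin_lon, origin_lat
        Coordinates of the grid's upper-left *corner* in degrees.
    cell_size
        Cell edge length in degrees (square cells).
    values
        ``n_rows x n_cols`` array. Cells equal to ``nodata`` are missing.
    nodata
        Sentinel marking missing cells.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({self.n_rows}, {self.n_cols})"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds in degrees."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def cell_center(self, row, col):
        """Center (lon, lat) of cell(s) at the given indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self):
        """(lon, lat) arrays of shape (n_rows, n_cols) for every cell."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell (row, col) containing a point; half-open cell intervals.

        Raises ``ValueError`` for points outside the raster extent.
        """
        west, south, east, north = self.bounds
        if not (west <= lon < east) or not (south < lat <= north):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent {self.bounds}")
        col = int(math.floor((lon - west) / self.cell_size))
        row = int(math.floor((north - lat) / self.cell_size))
        # guard against floating-point landing exactly on the far edge
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return row, col

    # -- values -----------------------------------------------------------
    def nodata_mask(self) -> np.ndarray:
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return ~np.isfinite(vals) | (vals == self.nodata)
        return vals == self.nodata

    def copy_with(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid on the same geometry with different values."""
        return replace(
            self,
            values=np.asarray(values),
            nodata=self.nodata if nodata is None else nodata,
        )


@dataclass
class EnvStack:
    """Named environmental layers sharing one grid geometry."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValueError("all layers must share the same geometry")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def subset(self, names) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})

    def nodata_mask(self) -> np.ndarray:
        """Cells missing in any layer."""
        out = np.zeros(self.template.shape, dtype=bool)
        for g in self.layers.values():
            out |= g.nodata_mask()
        return out

    def to_matrix(self, cells=None) -> np.ndarray:
        """Stack values into an (n_cells, n_vars) matrix.

        ``cells`` may be a boolean mask array or an (rows, cols) index
        tuple; default is all cells in row-major order.
        """
        cols = []
        for g in self.layers.values():
            v = g.values.astype(float)
            if cells is None:
                cols.append(v.ravel())
            elif isinstance(cells, tuple):
                cols.append(v[cells])
            else:
                cols.append(v[np.asarray(cells, dtype=bool)])
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    """Write a grid as a single-band georeferenced TIFF.

    Integer data round-trips bit-exactly; float data is stored at full
    float64 (or the array's own float) precision.
    """
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        out = vals.copy()
        out[~np.isfinite(out)] = grid.nodata
    else:
        out = vals
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
            True,
        ),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS, True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), True),
    ]
    tifffile.imwrite(str(path), out, extratags=extratags, photometric="minisblack")


def read_raster(path) -> RasterGrid:
    """Read a single-band georeferenced TIFF written by :func:`write_raster`
    (or any GeoTIFF with square cells and the standard geo tags)."""
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: expected 1 sample per pixel, found {page.samplesperpixel}")
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); we require the
        # upper-left corner anchor (0, 0).
        if tie[0] != 0 or tie[1] != 0:
            raise ValueError(f"{path}: unsupported tiepoint anchor {tie[:2]}")
        origin_lon, origin_lat = tie[3], tie[4]
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    n_rows, n_cols = values.shape
    return RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=float(sx),
        values=values,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def buffer_mask(lons, lats, radius_km: float, template: RasterGrid) -> RasterGrid:
    """Binary mask of cells whose centers lie within ``radius_km``
    great-circle distance of at least one of the given points.

    This is the accessible-area (M) constructor: the model calibration
    extent is taken as a fixed-radius buffer around known occurrences.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("buffer_mask requires at least one point")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    clon, clat = template.cell_centers()
    within = np.zeros(template.shape, dtype=bool)
    for lon, lat in zip(lons, lats):
        within |= haversine_km(clon, clat, lon, lat) <= radius_km
    return template.copy_with(within.astype(np.uint8), nodata=255)


def count_mask_cells(mask: RasterGrid) -> int:
    """Number of cells flagged 1 in a binary mask."""
    vals = np.asarray(mask.values)
    uniq = np.unique(vals)
    if not np.all(np.isin(uniq, (0, 1, mask.nodata))):
        raise ValueError("mask is not binary")
    return int(np.sum(vals == 1))
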