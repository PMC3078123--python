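"""Georeferenced grid data model.

Everything in the pipeline moves through :class:`Grid`: a 2-D array of
values on a regular geographic (WGS84 lat/lon) lattice with square cells,
cell-center registration and a nodata sentinel.  The grid origin
``(lon_origin, lat_origin)`` is the *outer corner* of the first (north-west)
cell; rows run north to south, columns west to east.  Cell footprints are
half-open, ``[west, east) x [north, south)``, so every in-extent point maps
to exactly one cell and points on shared edges are assigned
deterministically.

Depth is positive-down metres throughout the package; bathymetry grids hold
seafloor depth with land as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "GeoTransform",
    "Grid",
    "Bathymetry",
    "DepthInterval",
    "ZBinnedField",
    "LayerStack",
    "normalize_lon",
    "resample_nearest",
]

#: mean spherical Earth radius, metres
EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
METERS_PER_DEGREE = np.pi * EARTH_RADIUS_M / 180.0

DEFAULT_NODATA = -9999.0


def normalize_lon(lon):
    """Normalize longitudes to [-180, 180); in-range values pass through
    unchanged (no floating-point drift from the modulo)."""
    lon = np.asarray(lon, dtype=float)
    wrapped = (lon + 180.0) % 360.0 - 180.0
    return np.where((lon >= -180.0) & (lon < 180.0), lon, wrapped)


class GeoTransform(NamedTuple):
    """Placement of a grid on the globe: NW outer corner, cell size, shape."""

    lon_origin: float
    lat_origin: float
    cell_size_deg: float
    n_rows: int
    n_cols: int


@dataclass
class Grid:
    """A georeferenced 2-D raster with a nodata sentinel.

    Parameters
    ----------
    values
        2-D array, row 0 is the northernmost row.
    lon_origin, lat_origin
        Outer (NW) corner of the first cell, degrees.
    cell_size_deg
        Cell edge length in degrees (square cells).
    nodata
        Sentinel value excluded from all statistics.
    """

    values: np.ndarray
    lon_origin: float
    lat_origin: float
    cell_size_deg: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if not self.cell_size_deg > 0:
            raise ValueError("cell_size_deg must be positive")
        self.lon_origin = float(normalize_lon(self.lon_origin))
        self.lat_origin = float(self.lat_origin)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def geotransform(self) -> GeoTransform:
        return GeoTransform(
            self.lon_origin, self.lat_origin, self.cell_size_deg, self.n_rows, self.n_cols
        )

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_cols * self.cell_size_deg

    @property
    def lat_min(self) -> float:
        return self.lat_origin - self.n_rows * self.cell_size_deg

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        return Grid(
            self.values.copy() if values is None else np.asarray(values, dtype=float),
            self.lon_origin,
            self.lat_origin,
            self.cell_size_deg,
            self.nodata,
        )

    def same_geotransform(self, other: "Grid", tol: float = 1e-9) -> bool:
        a, b = self.geotransform, other.geotransform
        return (
            a.n_rows == b.n_rows
            and a.n_cols == b.n_cols
            and abs(a.lon_origin - b.lon_origin) <= tol
            and abs(a.lat_origin - b.lat_origin) <= tol
            and abs(a.cell_size_deg - b.cell_size_deg) <= tol
        )

    # -- indexing ----------------------------------------------------------
    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to the (row, col) of the cell containing it.

        Half-open footprints: a point on a shared edge belongs to the cell
        whose west/north edge it lies on.  Returns None when the point falls
        outside the grid extent.
        """
        r, c, ok = self.cell_index_array([lon], [lat])
        return (int(r[0]), int(c[0])) if ok[0] else None

    def cell_index_array(self, lon, lat):
        """Vectorized :meth:`cell_index`; returns (rows, cols, in_extent)."""
        lon = normalize_lon(lon)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_origin) / self.cell_size_deg)
        row = np.floor((self.lat_origin - lat) / self.cell_size_deg)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.clip(col, 0, self.n_cols - 1).astype(int)
        row = np.clip(row, 0, self.n_rows - 1).astype(int)
        return row, col, ok

    def cell_center(self, row, col):
        """(lon, lat) of a cell center; inverse of :meth:`cell_index`."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.lon_origin + (col + 0.5) * self.cell_size_deg
        lat = self.lat_origin - (row + 0.5) * self.cell_size_deg
        return lon, lat

    def cell_centers(self):
        """(lon 1-D of length n_cols, lat 1-D of length n_rows)."""
        lon = self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg
        lat = self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg
        return lon, lat

    def sample(self, lon, lat):
        """Values at points; NaN outside extent or on nodata cells."""
        row, col, ok = self.cell_index_array(lon, lat)
        vals = self.values[row, col]
        vals = np.where(ok & (vals != self.nodata) & np.isfinite(vals), vals, np.nan)
        return vals


@dataclass
class Bathymetry:
    """Seafloor depth grid: positive-down metres, land cells nodata."""

    grid: Grid

    def __post_init__(self):
        valid = self.grid.values[self.grid.mask]
        if valid.size and not np.all(valid > 0):
            raise ValueError("bathymetry depths must be positive-down (> 0 at sea)")

    @classmethod
    def from_elevation(cls, grid: Grid) -> "Bathymetry":
        """Ingest an elevation-convention raster: negate, mask land (>= 0)."""
        depth = -grid.values
        depth[~grid.mask] = grid.nodata
        depth[depth <= 0] = grid.nodata
        return cls(grid.copy(values=depth))

    @property
    def sea_mask(self) -> np.ndarray:
        return self.grid.mask

    @property
    def depth(self) -> np.ndarray:
        return self.grid.values


@dataclass(frozen=True)
class DepthInterval:
    """Half-open depth interval [top, bottom), positive-down metres."""

    top: float
    bottom: float

    def __post_init__(self):
        if not (0 <= self.top < self.bottom):
            raise ValueError(f"require 0 <= top < bottom, got [{self.top}, {self.bottom})")

    def contains(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        return (d >= self.top) & (d < self.bottom)


@dataclass
class ZBinnedField:
    """Ordered, contiguous stack of (DepthInterval, Grid) slices of one variable.

    ``depth_levels`` optionally records the standard depth levels the
    intervals were derived from, so a file round-trip reconstructs the
    identical binning.
    """

    variable_name: str
    slices: list[tuple[DepthInterval, Grid]]
    depth_levels: list[float] | None = None

    def __post_init__(self):
        if not self.slices:
            raise ValueError("ZBinnedField needs at least one slice")
        prev = None
        first = self.slices[0][0].top
        for interval, grid in self.slices:
            if prev is not None:
                if interval.top != prev.bottom:
                    raise ValueError("depth intervals must be contiguous and sorted")
                if not grid.same_geotransform(self.slices[0][1]):
                    raise ValueError("all slice grids must share one geotransform")
            prev = interval
        if first != 0:
            raise ValueError("first depth interval must start at 0 m")

    @property
    def intervals(self) -> list[DepthInterval]:
        return [iv for iv, _ in self.slices]

    @property
    def max_depth(self) -> float:
        return self.slices[-1][0].bottom

    def slice_for_depth(self, depth: float) -> int:
        """Index of the slice covering ``depth``; deeper-than-deepest maps to
        the last slice (deep-stability assumption)."""
        for i, (iv, _) in enumerate(self.slices):
            if iv.contains(depth):
                return i
        if depth >= self.max_depth:
            return len(self.slices) - 1
        raise ValueError(f"depth {depth} not covered")


@dataclass
class LayerStack:
    """Named collection of co-registered grids; one row of covariates per cell.

    A cell is valid only where *every* member layer is valid — this is the
    "analysis area" used for presence filtering and background sampling.
    """

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self):
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geotransform(grids[0]):
                raise ValueError("all stack layers must share one geotransform")

    @property
    def names(self) -> list[str]:
        return list(self.layers.keys())

    @property
    def reference(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack")
        return next(iter(self.layers.values()))

    @property
    def geotransform(self) -> GeoTransform:
        return self.reference.geotransform

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.reference.values.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.mask
        return mask

    def add(self, name: str, grid: Grid) -> None:
        if self.layers and not grid.same_geotransform(self.reference):
            raise ValueError(f"layer {name!r} not on the stack geotransform")
        self.layers[name] = grid

    def covariates_at_cells(self, rows, cols) -> np.ndarray:
        """(n_cells, n_layers) matrix of values at the given cell indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.empty((rows.size, len(self.layers)))
        for j, g in enumerate(self.layers.values()):
            v = g.values[rows, cols]
            out[:, j] = np.where((v != g.nodata) & np.isfinite(v), v, np.nan)
        return out

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of cells valid in every layer, row-major order."""
        return np.nonzero(self.valid_mask)

    def __iter__(self) -> Iterator[tuple[str, Grid]]:
        return iter(self.layers.items())

    def __len__(self) -> int:
        return len(self.layers)


def resample_nearest(source: Grid, target: GeoTransform) -> Grid:
    """Resample onto ``target`` by nearest-neighbour (containing-cell) lookup.

    Each output cell takes the value of the source cell whose half-open
    footprint contains the output cell center; centers outside the source
    extent become nodata.  No values are invented: the output multiset is a
    subset of the source values.
    """
    import warnings

    out = np.full((target.n_rows, target.n_cols), source.nodata, dtype=float)
    lon = target.lon_origin + (np.arange(target.n_cols) + 0.5) * target.cell_size_deg
    lat = target.lat_origin - (np.arange(target.n_rows) + 0.5) * target.cell_size_deg
    lon2, lat2 = np.meshgrid(lon, lat)
    rows, cols, ok = source.cell_index_array(lon2.ravel(), lat2.ravel())
    vals = source.values[rows, cols]
    vals[~ok] = source.nodata
    out[:] = vals.reshape(out.shape)
    if not ok.any():
        warnings.warn("resample_nearest: no overlap between source and target extents")
    return Grid(out, target.lon_origin, target.lat_origin, target.cell_size_deg, source.nodata)
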