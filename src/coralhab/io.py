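"""Raster, NetCDF and stack I/O.

Formats supported:

* ESRI ASCII grid (``.asc``) — plain text, written with 6 significant
  digits so round-trips are bit-exact at that precision.
* GeoTIFF — float64 imagery via :mod:`tifffile` with the standard
  ModelPixelScale / ModelTiepoint / GDAL_NODATA GeoTIFF tags.  Everything
  in the package is geographic WGS84, so no CRS machinery is involved.
* NetCDF (CF-style ``depth``/``lat``/``lon``) for z-binned climatology
  fields, through xarray's scipy backend (NetCDF3 classic).

Z-level to depth-interval conversion follows the midpoint rule: interval
boundaries sit halfway between consecutive standard depths, the first
interval starts at 0 m and the last extends half the final spacing below
the deepest level (the source never states bin edges; midpoints are the
symmetric choice).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .grid import DEFAULT_NODATA, DepthInterval, Grid, LayerStack, ZBinnedField

__all__ = [
    "read_raster",
    "write_raster",
    "read_zbinned",
    "write_zbinned",
    "depth_levels_to_intervals",
    "save_stack",
    "load_stack",
]

ASCII_PRECISION = 6  # significant digits in .asc output

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _detect_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "ascii_grid"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt"):
        return "ascii_grid"
    raise ValueError(f"cannot infer raster format from {path!r}; pass format=")


def read_raster(path, format: str | None = None) -> Grid:
    """Read a georeferenced raster from ESRI ASCII grid or GeoTIFF."""
    fmt = _detect_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    return _read_geotiff(path)


def write_raster(grid: Grid, path, format: str | None = None) -> None:
    """Write a grid; re-readable to an equal Grid (exact for GeoTIFF,
    exact at 6 significant digits for ASCII)."""
    fmt = _detect_format(path, format)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    else:
        _write_geotiff(grid, path)


# -- ESRI ASCII grid -------------------------------------------------------

def _read_ascii(path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "dx", "dy",
            "nodata_value", "xllcenter", "yllcenter",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize" if "cellsize" in header else "dx"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid header in {path}: missing {key}")
    if "dx" in header and "dy" in header and header["dx"] != header["dy"]:
        raise ValueError(f"{path}: rectangular cells (dx != dy) are not supported")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header.get("cellsize", header.get("dx"))
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "\n".join(lines[i:]).split()
    try:
        values = np.array(body, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric data in grid body") from exc
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    if "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    else:
        if "xllcorner" not in header or "yllcorner" not in header:
            raise ValueError(f"malformed ASCII grid header in {path}: missing corner")
        xll, yll = header["xllcorner"], header["yllcorner"]
    lat_origin = yll + n_rows * cell
    return Grid(values, xll, lat_origin, cell, nodata)


def _write_ascii(grid: Grid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon_origin!r}\n")
        fh.write(f"yllcorner {grid.lat_min!r}\n")
        fh.write(f"cellsize {grid.cell_size_deg!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        vals = grid.values.copy()
        vals[~grid.mask] = grid.nodata
        for row in vals:
            fh.write(" ".join(f"{v:.{ASCII_PRECISION}g}" for v in row) + "\n")


# -- GeoTIFF ---------------------------------------------------------------

def _read_geotiff(path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band 2-D raster")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-12:
            raise ValueError(f"{path}: rectangular cells (pixel scale {sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j) = (0, 0) to geographic (lon, lat)
        lon_origin = tie[3] - tie[0] * sx
        lat_origin = tie[4] + tie[1] * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    return Grid(values, lon_origin, lat_origin, sx, nodata)


def _write_geotiff(grid: Grid, path) -> None:
    import tifffile

    vals = grid.values.copy()
    vals[~grid.mask] = grid.nodata
    cs = grid.cell_size_deg
    tifffile.imwrite(
        path,
        vals.astype(np.float64),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_origin, grid.lat_origin, 0.0)),
            (_TAG_GDAL_NODATA, "s", None, repr(grid.nodata)),
        ],
    )


# -- NetCDF z-binned fields ------------------------------------------------

DEPTH_NAMES = ("depth", "z", "lev", "depth_m")
DEFAULT_SINGLE_LEVEL_MAX_DEPTH = 11_000.0


def depth_levels_to_intervals(
    depths: np.ndarray, single_level_max_depth: float = DEFAULT_SINGLE_LEVEL_MAX_DEPTH
) -> list[DepthInterval]:
    """Convert standard depth levels to contiguous half-open intervals.

    Boundaries at midpoints between consecutive levels; the first interval
    starts at 0 and the last ends half the final spacing below the deepest
    level.  A single level covers [0, single_level_max_depth).
    """
    depths = np.asarray(depths, dtype=float)
    if depths.ndim != 1 or depths.size == 0:
        raise ValueError("need a 1-D, nonempty depth axis")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depth levels must be strictly increasing")
    if depths.size == 1:
        return [DepthInterval(0.0, float(single_level_max_depth))]
    mids = (depths[:-1] + depths[1:]) / 2.0
    tops = np.concatenate([[0.0], mids])
    bottoms = np.concatenate([mids, [depths[-1] + (depths[-1] - depths[-2]) / 2.0]])
    return [DepthInterval(float(t), float(b)) for t, b in zip(tops, bottoms)]


def _find_depth_coord(ds) -> str:
    for name in DEPTH_NAMES:
        if name in ds.coords or name in ds.dims:
            return name
    raise ValueError("NetCDF file has no depth coordinate "
                     f"(looked for {', '.join(DEPTH_NAMES)})")


def read_zbinned(
    path,
    variable: str,
    nodata: float = DEFAULT_NODATA,
    single_level_max_depth: float = DEFAULT_SINGLE_LEVEL_MAX_DEPTH,
) -> ZBinnedField:
    """Read a (depth, lat, lon) NetCDF variable into a ZBinnedField."""
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not in {path}")
        da = ds[variable]
        depth_name = _find_depth_coord(ds)
        depths = np.asarray(ds[depth_name].values, dtype=float)
        intervals = depth_levels_to_intervals(depths, single_level_max_depth)
        lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        cell = float(abs(lat[1] - lat[0])) if lat.size > 1 else float(abs(lon[1] - lon[0]))
        data = da.transpose(depth_name, "lat", "lon").values.astype(float)
    north_first = lat.size < 2 or lat[0] > lat[1]
    if not north_first:
        data = data[:, ::-1, :]
        lat = lat[::-1]
    lat_origin = lat[0] + cell / 2
    lon_origin = lon[0] - cell / 2
    slices = []
    for k, interval in enumerate(intervals):
        plane = data[k].copy()
        plane[~np.isfinite(plane)] = nodata
        slices.append((interval, Grid(plane, lon_origin, lat_origin, cell, nodata)))
    return ZBinnedField(variable, slices, depth_levels=[float(d) for d in depths])


def write_zbinned(field: ZBinnedField, path, depths=None) -> None:
    """Write a ZBinnedField to NetCDF3.

    Depth levels come from the field's recorded ``depth_levels`` so that a
    read/write round-trip reproduces the identical intervals; for a field
    without recorded levels they are reconstructed from the interval
    boundaries (level k+1 mirrors level k across the shared boundary).
    """
    import xarray as xr

    ref = field.slices[0][1]
    if depths is None:
        depths = field.depth_levels
    if depths is None:
        bounds = [iv.bottom for iv in field.intervals[:-1]]
        depths = [field.intervals[0].top]
        for b in bounds:
            depths.append(2.0 * b - depths[-1])
    lon, lat = ref.cell_centers()
    data = np.stack([g.masked() for _, g in field.slices])
    ds = xr.Dataset(
        {field.variable_name: (("depth", "lat", "lon"), data)},
        coords={"depth": np.asarray(depths, dtype=float), "lat": lat, "lon": lon},
    )
    ds.to_netcdf(path, engine="scipy")


# -- layer stacks ----------------------------------------------------------

def save_stack(stack: LayerStack, directory, format: str = "ascii_grid") -> list[str]:
    """Write every layer of a stack into a directory; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if format == "ascii_grid" else ".tif"
    paths = []
    for name, grid in stack:
        p = directory / f"{name}{ext}"
        write_raster(grid, p, format)
        paths.append(str(p))
    return paths


def load_stack(directory) -> LayerStack:
    """Load all rasters in a directory into a stack (sorted by file name)."""
    directory = Path(directory)
    stack = LayerStack()
    files = sorted(
        [p for p in directory.iterdir() if p.suffix.lower() in (".asc", ".tif", ".tiff")]
    )
    if not files:
        raise FileNotFoundError(f"no raster layers found in {directory}")
    for p in files:
        stack.add(p.stem, read_raster(p))
    return stack
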