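"""Up-scaling of z-binned and surface climatologies onto bathymetry.

The core idea: a climatology reports one value per standard depth level on
a coarse horizontal grid.  Assuming conditions at a given z-level are
representative of the seafloor wherever the seafloor sits at that depth,
each z-bin can be *draped* over the portion of a high-resolution bathymetry
whose depth falls inside the bin's interval.  The per-bin pipeline is

1. inverse-distance-weighted interpolation of the bin onto an intermediate
   grid (default 0.1°) — this closes the gaps that would otherwise open
   between adjacent bins on steep terrain;
2. nearest-neighbour resampling onto the bathymetry grid (no further
   interpolation);
3. assignment of every sea cell to the bin containing its depth, and a
   merge of all bins into one continuous seafloor layer.

Cells deeper than the deepest bin keep the deepest bin's value (deep-water
conditions are assumed stable below the climatology's reach, and the corals
modelled here are not found at those depths anyway).  Surface-only fields
skip the draping and are simply interpolated and resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import Bathymetry, Grid, ZBinnedField, resample_nearest

__all__ = ["IDWConfig", "idw_interpolate", "drape_zbins", "upscale_surface"]


@dataclass(frozen=True)
class IDWConfig:
    """Inverse-distance-weighting parameters.

    power
        Exponent of inverse distance (conventional default 2).
    max_neighbors
        Number of nearest valid source cells contributing to each output
        point (default 12).
    intermediate_cell_size_deg
        Resolution of the intermediate grid the bins are interpolated to
        before resampling (default 0.1°).
    """

    power: float = 2.0
    max_neighbors: int = 12
    intermediate_cell_size_deg: float = 0.1

    def __post_init__(self):
        if not self.power > 0:
            raise ValueError("power must be positive")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if not self.intermediate_cell_size_deg > 0:
            raise ValueError("intermediate_cell_size_deg must be positive")


def idw_interpolate(source: Grid, config: IDWConfig) -> Grid:
    """Interpolate a grid's valid cell centers onto an intermediate grid.

    Each output value is the inverse-distance-power weighted mean of the
    ``max_neighbors`` nearest valid source cell centers (distances in
    degree space).  An output point coincident with a source center takes
    that center's value exactly, and every output lies within the [min,
    max] of the neighbours used.
    """
    mask = source.mask
    if not mask.any():
        raise ValueError("idw_interpolate: source has no valid cells")
    src_rows, src_cols = np.nonzero(mask)
    src_lon, src_lat = source.cell_center(src_rows, src_cols)
    src_vals = source.values[src_rows, src_cols]

    cs = config.intermediate_cell_size_deg
    n_cols = max(1, int(np.ceil(source.n_cols * source.cell_size_deg / cs - 1e-9)))
    n_rows = max(1, int(np.ceil(source.n_rows * source.cell_size_deg / cs - 1e-9)))
    out = Grid(
        np.zeros((n_rows, n_cols)), source.lon_origin, source.lat_origin, cs, source.nodata
    )
    out_lon, out_lat = out.cell_centers()
    lon2, lat2 = np.meshgrid(out_lon, out_lat)
    pts = np.column_stack([lon2.ravel(), lat2.ravel()])

    tree = cKDTree(np.column_stack([src_lon, src_lat]))
    k = min(config.max_neighbors, src_vals.size)
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / dist ** config.power
    w[~np.isfinite(w)] = 0.0
    # avoid 0/0 where the nearest point is coincident
    wsum = w.sum(axis=1)
    wsum[exact] = 1.0
    vals = (w * src_vals[idx]).sum(axis=1) / wsum
    vals[exact] = src_vals[idx[exact, 0]]
    out.values[:] = vals.reshape(n_rows, n_cols)
    return out


def drape_zbins(field: ZBinnedField, bathy: Bathymetry, config: IDWConfig) -> Grid:
    """Convert a z-binned field into a continuous seafloor layer.

    Every sea cell receives the value of exactly one bin — the one whose
    half-open depth interval [top, bottom) contains the cell's depth; cells
    below the deepest bin take the deepest bin's value.  Land cells are
    nodata.
    """
    target = bathy.grid.geotransform
    nodata = bathy.grid.nodata
    resampled = [
        resample_nearest(idw_interpolate(g, config), target) for _, g in field.slices
    ]
    depth = bathy.depth
    sea = bathy.sea_mask
    out = np.full(depth.shape, nodata, dtype=float)
    assigned = np.zeros(depth.shape, dtype=bool)
    for (interval, _), grid_k in zip(field.slices, resampled):
        sel = sea & interval.contains(depth)
        vals = grid_k.values[sel]
        # a resampled slice is nodata where the bathymetry extends beyond
        # the climatology's horizontal extent; keep those cells nodata
        vals[vals == grid_k.nodata] = nodata
        out[sel] = vals
        assigned |= sel
    deepest = sea & ~assigned & (depth >= field.max_depth)
    vals = resampled[-1].values[deepest]
    vals[vals == resampled[-1].nodata] = nodata
    out[deepest] = vals
    assigned |= deepest
    if (sea & ~assigned).any():
        # depths above the first interval's top cannot occur (bins start at 0)
        raise AssertionError("unassigned sea cells after draping")
    return Grid(out, target.lon_origin, target.lat_origin, target.cell_size_deg, nodata)


def upscale_surface(source: Grid, bathy: Bathymetry, config: IDWConfig) -> Grid:
    """Surface-only path: interpolate, resample onto bathymetry, mask land."""
    inter = idw_interpolate(source, config)
    res = resample_nearest(inter, bathy.grid.geotransform)
    out = res.values.copy()
    out[~bathy.sea_mask] = bathy.grid.nodata
    g = bathy.grid
    return Grid(out, g.lon_origin, g.lat_origin, g.cell_size_deg, g.nodata)
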