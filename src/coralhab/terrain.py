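"""Benthic terrain metrics derived from bathymetry.

Slope uses Horn's 3x3 finite-difference stencil with a per-row conversion
of degree spacing to metres (spherical Earth, radius 6371 km), so east-west
cell widths shrink with latitude.  Windowed variants (moving-average slope,
rugosity, bathymetric position index) take a window radius in kilometres;
the radius is converted to whole cells per row, minimum one cell, and the
window for a cell uses its own row's east-west width.

Sign conventions: depth is positive-down, so BPI is defined as
``mean(window depth) - cell depth`` — positive on crests (cell shallower
than its surroundings), negative in depressions.  Rugosity is the ratio of
triangulated 3-D surface area to planar area inside the window, exactly 1
on flat terrain and >= 1 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import METERS_PER_DEGREE, Bathymetry, Grid

__all__ = ["TerrainWindow", "slope", "windowed_slope", "rugosity", "bpi"]

#: window radii used for the multi-scale terrain layers, kilometres
STANDARD_WINDOWS_KM = (5.0, 20.0, 30.0, 100.0)


@dataclass(frozen=True)
class TerrainWindow:
    """Moving-window radius in kilometres."""

    radius_km: float

    def __post_init__(self):
        if not self.radius_km > 0:
            raise ValueError("radius_km must be positive")


def _meters_per_cell(grid: Grid):
    """(dy_m scalar, dx_m per-row array) for one cell step."""
    _, lat = grid.cell_centers()
    dy = METERS_PER_DEGREE * grid.cell_size_deg
    dx = METERS_PER_DEGREE * np.cos(np.radians(lat)) * grid.cell_size_deg
    return dy, dx


def _half_widths(grid: Grid, radius_km: float):
    """Window half-widths in cells: (hy scalar, hx per-row array)."""
    dy, dx = _meters_per_cell(grid)
    hy = max(1, int(round(radius_km * 1000.0 / dy)))
    with np.errstate(divide="ignore"):
        hx = np.round(radius_km * 1000.0 / dx).astype(int)
    hx = np.clip(hx, 1, grid.n_cols)
    return hy, hx


def slope(bathy: Bathymetry) -> Grid:
    """Seafloor slope in radians (Horn's method).

    Nodata wherever the 3x3 neighbourhood is incomplete (edges, and cells
    adjacent to land).
    """
    g = bathy.grid
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("slope needs a grid of at least 3x3 cells")
    z = g.values
    valid = g.mask
    dy_m, dx_m = _meters_per_cell(g)

    out = np.full(z.shape, g.nodata, dtype=float)
    c = z[1:-1, 1:-1]
    nw, n, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w, e = z[1:-1, :-2], z[1:-1, 2:]
    sw, s, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    ok = np.ones(c.shape, dtype=bool)
    for r0 in range(3):
        for c0 in range(3):
            ok &= valid[r0 : r0 + valid.shape[0] - 2, c0 : c0 + valid.shape[1] - 2]
    gx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8.0 * dx_m[1:-1, None])
    gy = ((sw + 2 * s + se) - (nw + 2 * n + ne)) / (8.0 * dy_m)
    sl = np.arctan(np.hypot(gx, gy))
    inner = out[1:-1, 1:-1]
    inner[ok] = sl[ok]
    out[1:-1, 1:-1] = inner
    return g.copy(values=out)


def _window_mean(values: np.ndarray, valid: np.ndarray, hy: int, hx: np.ndarray):
    """Masked moving-window mean; returns (mean, full) where ``full`` marks
    cells whose entire window is inside the grid and free of nodata."""
    n_rows, n_cols = values.shape
    v = np.where(valid, values, 0.0)
    cnt = valid.astype(float)
    # vertical band sums via cumulative sums (window rows r-hy .. r+hy)
    cv = np.vstack([np.zeros((1, n_cols)), np.cumsum(v, axis=0)])
    cc = np.vstack([np.zeros((1, n_cols)), np.cumsum(cnt, axis=0)])
    r = np.arange(n_rows)
    top = np.clip(r - hy, 0, n_rows)
    bot = np.clip(r + hy + 1, 0, n_rows)
    band_v = cv[bot] - cv[top]
    band_c = cc[bot] - cc[top]
    full_rows = (r - hy >= 0) & (r + hy < n_rows)

    mean = np.full(values.shape, np.nan)
    full = np.zeros(values.shape, dtype=bool)
    hv = np.hstack([np.zeros((n_rows, 1)), np.cumsum(band_v, axis=1)])
    hc = np.hstack([np.zeros((n_rows, 1)), np.cumsum(band_c, axis=1)])
    cidx = np.arange(n_cols)
    for row in range(n_rows):
        h = hx[row]
        left = np.clip(cidx - h, 0, n_cols)
        right = np.clip(cidx + h + 1, 0, n_cols)
        wsum = hv[row, right] - hv[row, left]
        wcnt = hc[row, right] - hc[row, left]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean[row] = np.where(wcnt > 0, wsum / wcnt, np.nan)
        expected = (2 * hy + 1) * (2 * h + 1)
        full[row] = full_rows[row] & (cidx - h >= 0) & (cidx + h < n_cols) & (wcnt == expected)
    return mean, full


def windowed_slope(bathy: Bathymetry, window: TerrainWindow) -> Grid:
    """Slope of the depth surface smoothed by a moving average of the
    window radius; captures broad-scale gradients (e.g. continental slopes)
    rather than local roughness."""
    g = bathy.grid
    dy_m, _ = _meters_per_cell(g)
    if window.radius_km * 1000.0 < dy_m / 2.0:
        warnings.warn("window radius smaller than one cell; falling back to plain slope")
        return slope(bathy)
    hy, hx = _half_widths(g, window.radius_km)
    mean, full = _window_mean(g.values, g.mask, hy, hx)
    smoothed = np.where(full & (mean > 0), mean, g.nodata)
    return slope(Bathymetry(g.copy(values=smoothed)))


def bpi(bathy: Bathymetry, window: TerrainWindow) -> Grid:
    """Bathymetric position index: mean window depth minus cell depth.

    Positive on crests (seamount summits), negative in depressions, zero on
    flat or uniformly sloping terrain ... nodata where the window is
    incomplete.
    """
    g = bathy.grid
    hy, hx = _half_widths(g, window.radius_km)
    mean, full = _window_mean(g.values, g.mask, hy, hx)
    out = np.full(g.values.shape, g.nodata, dtype=float)
    sel = full & g.mask
    out[sel] = mean[sel] - g.values[sel]
    return g.copy(values=out)


def _facet_areas(grid: Grid):
    """Triangulated facet areas between cell centers.

    Each quad of four adjacent cell centers is split along the NW-SE
    diagonal into two 3-D triangles.  Returns (area3d, area2d, quad_valid),
    each of shape (n_rows-1, n_cols-1); area2d is the horizontal projection.
    """
    dy_m, dx_m = _meters_per_cell(grid)
    n_rows, n_cols = grid.values.shape
    # physical cell-center positions: x shrinks with latitude per row
    x = (np.arange(n_cols) + 0.5) * dx_m[:, None]
    y = np.broadcast_to((np.arange(n_rows) * dy_m)[:, None], (n_rows, n_cols)).copy()
    z = grid.values

    def tri_area(p0, p1, p2):
        u = np.stack([a1 - a0 for a0, a1 in zip(p0, p1)], axis=-1)
        v = np.stack([a2 - a0 for a0, a2 in zip(p0, p2)], axis=-1)
        cr = np.cross(u, v)
        return 0.5 * np.linalg.norm(cr, axis=-1)

    def corner(arrs, r0, c0):
        return tuple(a[r0 : r0 + n_rows - 1, c0 : c0 + n_cols - 1] for a in arrs)

    coords3 = (x, y, z)
    coords2 = (x, y, np.zeros_like(z))
    areas3 = np.zeros((n_rows - 1, n_cols - 1))
    areas2 = np.zeros((n_rows - 1, n_cols - 1))
    for coords, acc in ((coords3, areas3), (coords2, areas2)):
        nw = corner(coords, 0, 0)
        ne = corner(coords, 0, 1)
        sw = corner(coords, 1, 0)
        se = corner(coords, 1, 1)
        acc += tri_area(nw, ne, se) + tri_area(nw, se, sw)
    m = grid.mask
    quad_valid = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
    return areas3, areas2, quad_valid


def rugosity(bathy: Bathymetry, window: TerrainWindow) -> Grid:
    """Surface-area to planar-area ratio within the window (>= 1).

    The seafloor inside the window is triangulated over cell centers; the
    ratio of summed 3-D facet area to summed horizontal projection measures
    terrain complexity independent of overall depth.
    """
    g = bathy.grid
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("rugosity needs a grid of at least 3x3 cells")
    hy, hx = _half_widths(g, window.radius_km)
    a3, a2, qvalid = _facet_areas(g)
    # quads indexed by their NW cell; the window of cell (r, c) covers quads
    # (r-hy .. r+hy-1) x (c-hx .. c+hx-1)
    n_rows, n_cols = g.values.shape
    out = np.full(g.values.shape, g.nodata, dtype=float)
    c3 = np.pad(np.cumsum(np.cumsum(np.where(qvalid, a3, 0.0), 0), 1), ((1, 0), (1, 0)))
    c2 = np.pad(np.cumsum(np.cumsum(np.where(qvalid, a2, 0.0), 0), 1), ((1, 0), (1, 0)))
    cq = np.pad(np.cumsum(np.cumsum(qvalid.astype(float), 0), 1), ((1, 0), (1, 0)))

    def box(c, r0, r1, col0, col1):
        return c[r1, col1] - c[r0, col1] - c[r1, col0] + c[r0, col0]

    cidx = np.arange(n_cols)
    for row in range(n_rows):
        h = hx[row]
        r0, r1 = row - hy, row + hy  # quad rows r0 .. r1-1
        if r0 < 0 or r1 > n_rows - 1:
            continue
        col0 = cidx - h
        col1 = cidx + h
        ok = (col0 >= 0) & (col1 <= n_cols - 1)
        col0c = np.clip(col0, 0, n_cols - 1)
        col1c = np.clip(col1, 0, n_cols - 1)
        s3 = box(c3, r0, r1, col0c, col1c)
        s2 = box(c2, r0, r1, col0c, col1c)
        nq = box(cq, r0, r1, col0c, col1c)
        expected = (r1 - r0) * (col1c - col0c)
        complete = ok & (nq == expected) & (expected > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(complete & (s2 > 0), s3 / s2, g.nodata)
        out[row] = ratio
    return g.copy(values=out)
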