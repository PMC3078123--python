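"""Validation of up-scaled seafloor layers against bottle-station data.

Quality-controlled water-bottle measurements (GLODAP-style records of
lon/lat/depth/value) are intersected with a seafloor layer: each station
is paired with the value of the grid cell containing it (horizontal match;
the layer already represents the seafloor).  Stations shallower than 50 m
are discarded first — near-surface bottles do not describe seafloor
conditions on any shelf.  Agreement is summarised by Pearson correlation,
by binned mean profiles along depth (50 m bins), latitude (5°) and
longitude (10°), and by a coarse 5° grid of the mean difference
(layer − station) to show where in the ocean the up-scaling is least
reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid

__all__ = [
    "BottleStation",
    "ValidationResult",
    "filter_stations",
    "intersect_layer",
    "binned_profile",
    "error_grid",
    "stations_from_frame",
]

DEFAULT_MIN_DEPTH_M = 50.0


@dataclass(frozen=True)
class BottleStation:
    lon: float
    lat: float
    depth: float  # metres, positive-down
    value: float

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("station depth must be >= 0 (positive-down)")


@dataclass
class ValidationResult:
    """Paired station/layer values and their correlation."""

    n: int
    pearson_r: float
    r_squared: float
    p_value: float
    pairs: pd.DataFrame  # columns: lon, lat, depth, station, layer
    n_dropped: int = 0


def stations_from_frame(df: pd.DataFrame) -> list[BottleStation]:
    """Build stations from a lon/lat/depth/value DataFrame (CSV layout)."""
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("lon", "lat", "depth", "value") if c not in cols]
    if missing:
        raise ValueError(f"station table missing columns {missing}")
    return [
        BottleStation(
            float(r[cols["lon"]]), float(r[cols["lat"]]),
            float(r[cols["depth"]]), float(r[cols["value"]]),
        )
        for _, r in df.iterrows()
    ]


def filter_stations(
    stations: list[BottleStation], min_depth: float = DEFAULT_MIN_DEPTH_M
) -> list[BottleStation]:
    """Retain stations strictly deeper than ``min_depth`` metres."""
    return [s for s in stations if s.depth > min_depth]


def intersect_layer(stations: list[BottleStation], layer: Grid) -> ValidationResult:
    """Pair each station with the layer value of its containing cell.

    Stations outside the extent or on nodata (land) cells are dropped and
    counted.  Needs at least 3 surviving pairs for the correlation to be
    defined.
    """
    if not stations:
        raise ValueError("no stations supplied")
    lon = np.array([s.lon for s in stations])
    lat = np.array([s.lat for s in stations])
    vals = layer.sample(lon, lat)
    keep = np.isfinite(vals)
    n_dropped = int((~keep).sum())
    pairs = pd.DataFrame(
        {
            "lon": lon[keep],
            "lat": lat[keep],
            "depth": np.array([s.depth for s in stations])[keep],
            "station": np.array([s.value for s in stations])[keep],
            "layer": vals[keep],
        }
    )
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} stations intersect valid cells; correlation undefined"
        )
    if pairs["station"].std() == 0 or pairs["layer"].std() == 0:
        r, p = (1.0, 0.0) if np.allclose(pairs["station"], pairs["layer"]) else (np.nan, np.nan)
    else:
        r, p = stats.pearsonr(pairs["station"], pairs["layer"])
    return ValidationResult(
        n=len(pairs),
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        p_value=float(p),
        pairs=pairs,
        n_dropped=n_dropped,
    )


def binned_profile(
    pairs: pd.DataFrame, axis: str, bin_width: float
) -> pd.DataFrame:
    """Mean station and layer values in half-open bins along an axis.

    ``axis`` is one of depth / latitude / longitude; conventional widths
    are 50 m, 5° and 10° respectively.  Bins start at the axis minimum;
    empty bins are omitted.  Columns: bin_start, bin_center, n,
    mean_station, mean_layer.
    """
    col = {"depth": "depth", "latitude": "lat", "longitude": "lon"}.get(axis)
    if col is None:
        raise ValueError("axis must be one of depth, latitude, longitude")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    if pairs.empty:
        raise ValueError("no pairs to bin")
    x = pairs[col].to_numpy(dtype=float)
    start = x.min()
    idx = np.floor((x - start) / bin_width).astype(int)
    out = []
    for b in np.unique(idx):
        sel = idx == b
        out.append(
            {
                "bin_start": start + b * bin_width,
                "bin_center": start + (b + 0.5) * bin_width,
                "n": int(sel.sum()),
                "mean_station": float(pairs.loc[sel, "station"].mean()),
                "mean_layer": float(pairs.loc[sel, "layer"].mean()),
            }
        )
    return pd.DataFrame(out)


def error_grid(pairs: pd.DataFrame, cell_deg: float = 5.0) -> Grid:
    """Coarse grid of the mean difference (layer − station) per cell.

    Cells containing no stations are nodata.  The grid is snapped to
    multiples of ``cell_deg`` covering the stations' extent.
    """
    if pairs.empty:
        raise ValueError("no pairs")
    lon = pairs["lon"].to_numpy(dtype=float)
    lat = pairs["lat"].to_numpy(dtype=float)
    diff = (pairs["layer"] - pairs["station"]).to_numpy(dtype=float)
    lon0 = np.floor(lon.min() / cell_deg) * cell_deg
    lat1 = np.ceil(lat.max() / cell_deg) * cell_deg
    # +1 so stations exactly on the far edge still fall inside a cell
    n_cols = int((lon.max() - lon0) // cell_deg) + 1
    n_rows = int((lat1 - lat.min()) // cell_deg) + 1
    grid = Grid(np.zeros((n_rows, n_cols)), lon0, lat1, cell_deg)
    rows, cols, ok = grid.cell_index_array(lon, lat)
    sums = np.zeros((n_rows, n_cols))
    cnts = np.zeros((n_rows, n_cols))
    np.add.at(sums, (rows[ok], cols[ok]), diff[ok])
    np.add.at(cnts, (rows[ok], cols[ok]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnts > 0, sums / cnts, grid.nodata)
    grid.values[:] = mean
    return grid
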