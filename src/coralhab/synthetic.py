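"""Synthetic ocean worlds with planted ground truth.

Generates every input the pipeline consumes — bathymetry with
shelf/slope/abyssal-plain structure and seamounts, coarse z-binned
climatology fields with latitudinal and depth gradients, presence records
drawn from a known (Gaussian-product) niche, and noisy bottle stations —
so that the full analysis can be exercised end-to-end with no downloads
and checked against the truth it was generated from.

Default world: a 60 x 80 cell region at 0.05° resolution (~4° x 3° of a
mid-latitude ocean margin), a 150 m shelf dropping to a 4800 m abyssal
plain, four seamounts, and three z-binned variables (temperature, salinity,
dissolved oxygen) on a 4x coarser horizontal grid with ten standard depth
levels reaching 4000 m — so the deepest cells exercise the
deeper-than-deepest draping rule.  The planted niche is driven by
temperature (optimum 8 °C, tolerance 1.5 °C), emulating the restricted
thermal envelopes observed for framework-forming cold-water corals.

All generators are bit-reproducible per seed; sub-seeds for the individual
generators are derived deterministically from the world seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Bathymetry, Grid, LayerStack, ZBinnedField
from .io import depth_levels_to_intervals
from .presences import PresenceRecord, PresenceSet
from .upscale import IDWConfig, drape_zbins
from .validation import BottleStation

__all__ = [
    "SyntheticWorldConfig",
    "GradientSpec",
    "NicheTruth",
    "SyntheticWorld",
    "make_bathymetry",
    "make_zbinned_field",
    "make_presences",
    "make_stations",
    "make_world",
    "true_suitability",
    "DEFAULT_DEPTH_LEVELS",
    "DEFAULT_FIELD_SPECS",
    "DEFAULT_TRUTH",
]

DEFAULT_DEPTH_LEVELS = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Geometry and relief of the synthetic ocean region."""

    n_rows: int = 60
    n_cols: int = 80
    cell_size_deg: float = 0.05
    lon_origin: float = -30.0
    lat_origin: float = 45.0
    shelf_depth: float = 150.0
    abyssal_depth: float = 4800.0
    n_seamounts: int = 4
    seamount_height: float = 3000.0
    noise_sd: float = 25.0
    land_margin_frac: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.shelf_depth < self.abyssal_depth:
            raise ValueError("require 0 < shelf_depth < abyssal_depth")
        if self.n_seamounts < 0:
            raise ValueError("n_seamounts must be >= 0")
        if self.n_rows < 4 or self.n_cols < 8:
            raise ValueError("grid too small for a shelf/slope/abyssal profile")


@dataclass(frozen=True)
class GradientSpec:
    """Analytic structure of a z-binned variable.

    value(lat, z) = deep_value + (surface_value + lat_slope·(lat − lat_ref)
    − deep_value) · exp(−z / depth_scale): a latitudinal linear gradient at
    the surface decaying towards a uniform deep value.
    """

    surface_value: float
    deep_value: float
    depth_scale: float  # e-folding depth, m
    lat_slope: float = 0.0  # units per degree latitude
    lat_ref: float = 42.0

    def evaluate(self, lat, depth):
        lat = np.asarray(lat, dtype=float)
        depth = np.asarray(depth, dtype=float)
        surf = self.surface_value + self.lat_slope * (lat - self.lat_ref)
        return self.deep_value + (surf - self.deep_value) * np.exp(-depth / self.depth_scale)


#: temperature / salinity / dissolved-oxygen structure of the default world
DEFAULT_FIELD_SPECS: dict[str, GradientSpec] = {
    "temperature": GradientSpec(
        surface_value=19.0, deep_value=1.0, depth_scale=2000.0, lat_slope=-0.9
    ),
    "salinity": GradientSpec(
        surface_value=36.0, deep_value=34.7, depth_scale=1500.0, lat_slope=-0.05
    ),
    "oxygen": GradientSpec(
        surface_value=6.0, deep_value=4.5, depth_scale=600.0, lat_slope=0.08
    ),
}

#: per-variable field noise, in the variable's units
DEFAULT_FIELD_NOISE = {"temperature": 0.15, "salinity": 0.03, "oxygen": 0.05}


@dataclass(frozen=True)
class NicheTruth:
    """Planted Gaussian-product niche: independent bell-shaped responses.

    suitability(x) = prevalence · Π_v exp(−(x_v − optimum_v)² / (2 tol_v²))
    over the variables with a response; variables absent from ``responses``
    do not influence the species.
    """

    responses: dict[str, tuple[float, float]]
    prevalence: float = 1.0

    def __post_init__(self):
        for var, (_, tol) in self.responses.items():
            if not tol > 0:
                raise ValueError(f"tolerance for {var} must be positive")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")

    def suitability(self, covariates: dict[str, np.ndarray]) -> np.ndarray:
        names = list(covariates)
        s = np.full_like(np.asarray(covariates[names[0]], dtype=float), self.prevalence)
        for var, (opt, tol) in self.responses.items():
            if var not in covariates:
                raise KeyError(f"truth variable {var!r} missing from covariates")
            x = np.asarray(covariates[var], dtype=float)
            s = s * np.exp(-((x - opt) ** 2) / (2.0 * tol ** 2))
        return s


#: temperature-driven default truth (thermal optimum 8 °C, tolerance 1.5 °C)
DEFAULT_TRUTH = NicheTruth(responses={"temperature": (8.0, 1.5)})


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def make_bathymetry(config: SyntheticWorldConfig) -> Bathymetry:
    """West-to-east shelf → slope → abyssal profile with seamounts.

    The westernmost ``land_margin_frac`` of columns is land (nodata);
    seamounts are Gaussian bumps rising from the abyssal plain at seeded
    random positions; seeded Gaussian noise is added everywhere at sea.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.n_rows, config.n_cols
    col = np.arange(n_cols, dtype=float)
    land_end = int(round(config.land_margin_frac * n_cols))
    shelf_end = max(land_end + 1, int(round(0.25 * n_cols)))
    slope_end = max(shelf_end + 1, int(round(0.55 * n_cols)))

    profile = np.empty(n_cols)
    profile[:shelf_end] = config.shelf_depth
    ramp = (col[shelf_end:slope_end] - shelf_end) / max(1, slope_end - shelf_end)
    profile[shelf_end:slope_end] = (
        config.shelf_depth + (config.abyssal_depth - config.shelf_depth) * ramp
    )
    profile[slope_end:] = config.abyssal_depth

    depth = np.tile(profile, (n_rows, 1))
    # seamounts on the abyssal plain
    for _ in range(config.n_seamounts):
        r0 = rng.uniform(0.1 * n_rows, 0.9 * n_rows)
        c0 = rng.uniform(slope_end + 2, n_cols - 2)
        sigma = rng.uniform(1.5, 3.5)
        rr, cc = np.mgrid[0:n_rows, 0:n_cols]
        bump = config.seamount_height * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2)
        )
        depth -= bump
    if config.noise_sd > 0:
        depth += rng.normal(0.0, config.noise_sd, size=depth.shape)
    depth = np.clip(depth, 5.0, None)

    grid = Grid(
        depth, config.lon_origin, config.lat_origin, config.cell_size_deg
    )
    if land_end > 0:
        grid.values[:, :land_end] = grid.nodata
    return Bathymetry(grid)


def make_zbinned_field(
    name: str,
    depth_levels,
    gradient: GradientSpec,
    bathy: Bathymetry,
    noise_sd: float = 0.0,
    seed: int = 0,
    coarsen: int = 4,
) -> ZBinnedField:
    """Coarse-grid z-binned field over the bathymetry's extent.

    Each slice holds the analytic gradient evaluated at the slice's depth
    level plus seeded cell noise, on a horizontal grid ``coarsen`` times
    coarser than the bathymetry (so draping exercises real resampling).
    """
    depth_levels = np.asarray(depth_levels, dtype=float)
    if depth_levels.size < 1:
        raise ValueError("need at least one depth level")
    intervals = depth_levels_to_intervals(depth_levels)
    rng = np.random.default_rng(seed)
    ref = bathy.grid
    cs = ref.cell_size_deg * coarsen
    n_cols = int(np.ceil(ref.n_cols / coarsen))
    n_rows = int(np.ceil(ref.n_rows / coarsen))
    proto = Grid(np.zeros((n_rows, n_cols)), ref.lon_origin, ref.lat_origin, cs)
    _, lat = proto.cell_centers()
    slices = []
    for level, interval in zip(depth_levels, intervals):
        base = gradient.evaluate(lat, level)[:, None]
        vals = np.broadcast_to(base, (n_rows, n_cols)).copy()
        if noise_sd > 0:
            vals += rng.normal(0.0, noise_sd, size=vals.shape)
        slices.append((interval, proto.copy(values=vals)))
    return ZBinnedField(name, slices, depth_levels=[float(d) for d in depth_levels])


def true_suitability(stack: LayerStack, truth: NicheTruth) -> Grid:
    """Grid of the planted suitability over the stack's valid cells."""
    rows, cols = stack.valid_cells()
    X = stack.covariates_at_cells(rows, cols)
    cov = {name: X[:, j] for j, name in enumerate(stack.names)}
    s = truth.suitability(cov)
    ref = stack.reference
    out = np.full(ref.values.shape, ref.nodata, dtype=float)
    out[rows, cols] = s
    return ref.copy(values=out)


def make_presences(
    stack: LayerStack,
    truth: NicheTruth,
    n: int,
    seed: int = 0,
    species: str = "synthetic_coral",
) -> PresenceSet:
    """Sample presence cells with probability proportional to the planted
    suitability, without replacement (one presence per cell by
    construction); records sit at cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = stack.valid_cells()
    if rows.size < n:
        raise ValueError(f"only {rows.size} valid cells but {n} presences requested")
    X = stack.covariates_at_cells(rows, cols)
    cov = {name: X[:, j] for j, name in enumerate(stack.names)}
    w = truth.suitability(cov)
    w = np.maximum(w, 1e-300)
    rng = np.random.default_rng(seed)
    # Gumbel-top-k = successive weighted sampling without replacement
    keys = np.log(w) + rng.gumbel(size=w.size)
    sel = np.argsort(keys)[::-1][:n]
    ref = stack.reference
    lon, lat = ref.cell_center(rows[sel], cols[sel])
    records = [
        PresenceRecord(species, float(lo), float(la)) for lo, la in zip(lon, lat)
    ]
    return PresenceSet(species, records, ref.geotransform)


def make_stations(
    field: ZBinnedField,
    bathy: Bathymetry,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BottleStation]:
    """Seeded bottle stations at random sea cells.

    A station sits at its cell's center, its depth is the cell's seafloor
    depth, and its value is the field's slice value for that depth at the
    station position, plus Gaussian measurement noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(bathy.sea_mask)
    sel = rng.choice(rows.size, size=min(n, rows.size), replace=False)
    r, c = rows[sel], cols[sel]
    lon, lat = bathy.grid.cell_center(r, c)
    depths = bathy.depth[r, c]
    noise = rng.normal(0.0, noise_sd, size=r.size) if noise_sd > 0 else np.zeros(r.size)
    stations = []
    for lo, la, d, eps in zip(lon, lat, depths, noise):
        k = field.slice_for_depth(float(d))
        val = field.slices[k][1].sample([lo], [la])[0]
        if not np.isfinite(val):
            continue  # station over a gap in the climatology
        stations.append(BottleStation(float(lo), float(la), float(d), float(val + eps)))
    return stations


@dataclass
class SyntheticWorld:
    """A complete generated study region with its planted truth."""

    config: SyntheticWorldConfig
    bathy: Bathymetry
    fields: dict[str, ZBinnedField]
    stack: LayerStack
    truth: NicheTruth
    idw: IDWConfig


def make_world(
    config: SyntheticWorldConfig | None = None,
    truth: NicheTruth | None = None,
    field_specs: dict[str, GradientSpec] | None = None,
    field_noise: dict[str, float] | None = None,
    depth_levels=DEFAULT_DEPTH_LEVELS,
    idw: IDWConfig | None = None,
    coarsen: int = 4,
) -> SyntheticWorld:
    """Generate bathymetry + z-binned fields and drape them into the
    analysis stack (layers: depth, then each field).

    The default IDW intermediate resolution equals the coarse fields' own
    cell size, so interpolation is exact at the climatology grid points.
    """
    config = config or SyntheticWorldConfig()
    truth = truth or DEFAULT_TRUTH
    field_specs = field_specs if field_specs is not None else DEFAULT_FIELD_SPECS
    field_noise = field_noise if field_noise is not None else DEFAULT_FIELD_NOISE
    seeds = _subseeds(config.seed, 1 + len(field_specs))
    bathy_cfg = SyntheticWorldConfig(
        **{**config.__dict__, "seed": seeds[0]}
    )
    bathy = make_bathymetry(bathy_cfg)
    if idw is None:
        idw = IDWConfig(
            intermediate_cell_size_deg=config.cell_size_deg * coarsen
        )
    stack = LayerStack()
    stack.add("depth", bathy.grid)
    fields = {}
    for k, (name, spec) in enumerate(field_specs.items()):
        f = make_zbinned_field(
            name,
            depth_levels,
            spec,
            bathy,
            noise_sd=field_noise.get(name, 0.0),
            seed=seeds[1 + k],
            coarsen=coarsen,
        )
        fields[name] = f
        stack.add(name, drape_zbins(f, bathy, idw))
    return SyntheticWorld(config, bathy, fields, stack, truth, idw)
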