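"""Build continuous seafloor layers from a z-binned climatology.

Generates a synthetic ocean region (shelf, slope, abyssal plain,
seamounts), a coarse depth-binned temperature climatology, and drapes the
climatology onto the bathymetry: every sea cell receives the temperature
of the depth bin containing its own seafloor depth.  Also derives terrain
metrics.  The printed numbers show the draped layer spanning warm shelf
water to cold abyssal water, and rugosity >= 1 with the roughest terrain
on the seamounts.
"""

import numpy as np

from coralhab import (
    IDWConfig,
    TerrainWindow,
    bpi,
    drape_zbins,
    rugosity,
    slope,
)
from coralhab.synthetic import (
    DEFAULT_DEPTH_LEVELS,
    DEFAULT_FIELD_SPECS,
    SyntheticWorldConfig,
    make_bathymetry,
    make_zbinned_field,
)

config = SyntheticWorldConfig(seed=42)
bathy = make_bathymetry(config)
print(f"bathymetry: {bathy.grid.n_rows} x {bathy.grid.n_cols} cells, "
      f"depths {bathy.depth[bathy.sea_mask].min():.0f}-"
      f"{bathy.depth[bathy.sea_mask].max():.0f} m, "
      f"{(~bathy.sea_mask).sum()} land cells")

field = make_zbinned_field(
    "temperature", DEFAULT_DEPTH_LEVELS, DEFAULT_FIELD_SPECS["temperature"],
    bathy, noise_sd=0.15, seed=1, coarsen=4,
)
print(f"climatology: {len(field.slices)} depth bins on a 4x coarser grid, "
      f"0-{field.max_depth:.0f} m")

idw = IDWConfig(power=2, max_neighbors=12,
                intermediate_cell_size_deg=config.cell_size_deg * 4)
layer = drape_zbins(field, bathy, idw)
sea = bathy.sea_mask
print(f"draped seafloor temperature: {layer.values[sea].min():.2f} to "
      f"{layer.values[sea].max():.2f} degC "
      f"(shelf is warm, abyssal plain is cold)")

sl = slope(bathy)
rug = rugosity(bathy, TerrainWindow(20.0))
pos = bpi(bathy, TerrainWindow(30.0))
print(f"slope: median {np.degrees(np.median(sl.values[sl.mask])):.2f} deg, "
      f"max {np.degrees(sl.values[sl.mask].max()):.1f} deg")
print(f"rugosity: min {rug.values[rug.mask].min():.4f} (flat plain ~1), "
      f"max {rug.values[rug.mask].max():.3f} (seamount flanks)")
print(f"BPI: {pos.values[pos.mask].min():.0f} m (depressions) to "
      f"{pos.values[pos.mask].max():.0f} m (seamount crests)")
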