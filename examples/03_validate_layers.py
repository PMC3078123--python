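"""Validate an up-scaled seafloor layer against bottle stations.

Synthetic bottle stations sample the "true" climatology at their position
and seafloor depth, with optional measurement noise.  Intersecting them
with the draped layer measures how faithfully the up-scaling reproduces
seafloor conditions: noise-free stations agree exactly (r^2 = 1), noisy
ones degrade gracefully.  Binned profiles and the coarse error grid show
where along depth/latitude/longitude any disagreement concentrates.
"""

from coralhab import (
    binned_profile,
    error_grid,
    filter_stations,
    intersect_layer,
    make_stations,
)
from coralhab.synthetic import make_world

world = make_world()
layer = world.stack.layers["temperature"]
field = world.fields["temperature"]

for noise in (0.0, 0.5):
    stations = make_stations(field, world.bathy, 400, noise_sd=noise, seed=3)
    retained = filter_stations(stations, min_depth=50.0)
    result = intersect_layer(retained, layer)
    print(f"noise sd {noise:>3}: retained {result.n} stations deeper than 50 m, "
          f"r^2 = {result.r_squared:.4f}")

# profiles and error grid for the noisy case
profile = binned_profile(result.pairs, "depth", 50.0)
print(f"\ndepth profile: {len(profile)} occupied 50 m bins; first three:")
for _, row in profile.head(3).iterrows():
    print(f"  {row['bin_start']:6.0f} m  n={row['n']:3.0f}  "
          f"station {row['mean_station']:6.2f}  layer {row['mean_layer']:6.2f}")

grid = error_grid(result.pairs, cell_deg=1.0)
errs = grid.values[grid.mask]
print(f"\nerror grid ({grid.n_rows} x {grid.n_cols} cells of 1 deg): "
      f"mean layer-station difference {errs.mean():+.3f}, "
      f"largest cell bias {abs(errs).max():.3f}")
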