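"""Generate a seeded synthetic world and inspect its climate.

The world is a rectangle of monthly climate (12x tmax, tmin, prec), a
soil layer, and the six derived predictors; temperature falls with
latitude, rainfall rises with longitude, and smoothed noise adds
spatial texture.
"""

import numpy as np

from invasion_hotspots import SyntheticWorldSpec, generate_climate

spec = SyntheticWorldSpec(grid_rows=40, grid_cols=40, seed=7)
world = generate_climate(spec)
bc = world.bioclim

print(f"grid: {spec.grid_rows}x{spec.grid_cols} cells of {spec.cell_size_deg} deg")
for name in ("MAT", "MTWM", "MTCM", "AP", "PS", "TCF"):
    layer = bc[name]
    print(f"{name:>4}: min {layer.min():8.1f}  mean {layer.mean():8.1f}  max {layer.max():8.1f}")

# MAT spans the latitudinal gradient: the northern edge is coldest.
north, south = bc["MAT"][0].mean(), bc["MAT"][-1].mean()
print(f"MAT north edge {north:.1f} C vs south edge {south:.1f} C "
      f"(gradient {spec.temp_gradient} C/deg lat)")
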