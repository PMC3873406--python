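"""Project a fitted model onto a warmed climate and measure range change.

A 3-model anomaly ensemble is downscaled by cubic spline onto the
baseline grid, applied to the monthly climate, and the per-model
surfaces averaged into a consensus; the species' current-climate
90%-sensitivity threshold then cuts both periods into binary habitat.
"""

import numpy as np

from invasion_hotspots import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    apply_anomaly,
    binarize,
    build_features,
    consensus_surface,
    derive_bioclim,
    dispersal_scenarios,
    downscale_anomaly,
    fit,
    generate_anomalies,
    generate_climate,
    generate_regions,
    generate_species,
    predict,
)
from invasion_hotspots.background import eligible_cells, presence_cells, sample_background

world = generate_climate(SyntheticWorldSpec(grid_rows=40, grid_cols=40, seed=7))
_, zones = generate_regions(world, 5, seed=7)
occ, _ = generate_species(world, SyntheticSpeciesSpec("demo", n_presences=250), seed=3)

grid = world.grid
pres = presence_cells(occ, grid)
bg = sample_background(eligible_cells(occ, zones), 2000, 3, grid, "demo", zones)
pr, pc = np.divmod(pres, grid.cols)
br, bc = np.divmod(bg.points["cell_index"].to_numpy(), grid.cols)
fs, F_pres, F_bg = build_features(world.bioclim.matrix(pr, pc), world.bioclim.matrix(br, bc))
model = fit(fs, F_pres, F_bg, training_meta={"species_id": "demo"})

surf_now = predict(model, world.bioclim, scenario="current")
cur = binarize(surf_now, model.logistic(F_pres), 0.90, scenario="current")

per_gcm = []
for st in generate_anomalies(world, 3, warming_mean=2.5, warming_sd=0.3, seed=7):
    fine = downscale_anomaly(st, grid)
    future_bc = derive_bioclim(apply_anomaly(world.climate, fine), world.tcf)
    per_gcm.append(predict(model, future_bc, scenario=st.gcm_id))
consensus = consensus_surface(per_gcm)
fut = binarize(consensus, None, threshold=cur.threshold, scenario="2065")
full, none = dispersal_scenarios(cur, fut)

print(f"threshold (from current climate): {cur.threshold:.3f}")
print(f"current habitat:        {cur.area_cells:4d} cells, {cur.area_km2:12.0f} km2")
print(f"future, full dispersal: {full.area_cells:4d} cells, {full.area_km2:12.0f} km2")
print(f"future, no dispersal:   {none.area_cells:4d} cells, {none.area_km2:12.0f} km2")
pct = 100 * (full.area_km2 - cur.area_km2) / cur.area_km2
print(f"full-dispersal change: {pct:+.1f}% (negative = contraction under warming)")
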