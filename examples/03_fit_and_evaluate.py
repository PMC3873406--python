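"""Fit a maximum-entropy model for one species and evaluate it.

Background points are restricted to the climate zones holding the
species' records (one point per cell, never a presence cell); features
are the 27 linear/quadratic/product transforms of the six predictors;
the accuracy report gives AUC, the 90%-sensitivity threshold, the
omission rate and the exact binomial omission p-value.
"""

import numpy as np

from invasion_hotspots import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    build_features,
    evaluate,
    fit,
    generate_climate,
    generate_regions,
    generate_species,
)
from invasion_hotspots.background import eligible_cells, presence_cells, sample_background

world = generate_climate(SyntheticWorldSpec(grid_rows=40, grid_cols=40, seed=7))
_, zones = generate_regions(world, 5, seed=7)
occ, true_suit = generate_species(
    world, SyntheticSpeciesSpec("demo", n_presences=250), seed=3
)

grid = world.grid
pres = presence_cells(occ, grid)
bg = sample_background(eligible_cells(occ, zones), 2000, 3, grid, "demo", zones)

pr, pc = np.divmod(pres, grid.cols)
br, bc = np.divmod(bg.points["cell_index"].to_numpy(), grid.cols)
fs, F_pres, F_bg = build_features(world.bioclim.matrix(pr, pc), world.bioclim.matrix(br, bc))
model = fit(fs, F_pres, F_bg, training_meta={"species_id": "demo"})

report = evaluate(model, model.logistic(F_pres), model.logistic(F_bg))
print(f"features: {fs.n_features}, active weights: {np.count_nonzero(model.lambdas)}")
print(f"AUC {report.auc:.3f}  (gate: > {report.auc_gate})")
print(f"90%-sensitivity threshold {report.threshold:.3f}")
print(f"omission rate {report.omission_rate:.3f}, binomial p {report.binomial_p:.2e}")
print(f"predicted area fraction {report.predicted_area_fraction:.3f}")
print("gates passed" if report.passed else "gates FAILED")
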