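"""Clean a contaminated occurrence table step by step.

A synthetic species is sampled with known contamination — cultivated
records, exact duplicates, and an over-collected bias region — then
pushed through the standard cleaning order: drop cultivated records,
deduplicate on the 8 km equal-area grid, cap the per-cell density
inside the bias rectangle.
"""

from invasion_hotspots import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    generate_climate,
    generate_species,
)
from invasion_hotspots.occurrences import dedupe_equal_area, remove_cultivated, thin_bias

world = generate_climate(SyntheticWorldSpec(grid_rows=40, grid_cols=40, seed=7))
box = (115.0, 35.0, 122.0, 42.0)
spec = SyntheticSpeciesSpec(
    "demo_species",
    n_presences=300,
    cultivated_fraction=0.1,
    duplicate_fraction=0.15,
    bias_region=box,
    bias_multiplier=2.0,
)
occ, _ = generate_species(world, spec, seed=1)
print(f"raw records: {len(occ)}")

occ = remove_cultivated(occ)
occ = dedupe_equal_area(occ, cell_km=8.0)
# thin at a coarser cell than the dedup grid, otherwise the density cap
# of 1 record per cell is already satisfied everywhere
occ = thin_bias(occ, [box], target_density=1, cell_km=50.0, seed=1)

for step, removed in occ.cleaning_log:
    print(f"  {step:>20}: removed {removed}")
removed = sum(n for _, n in occ.cleaning_log)
print(f"clean records: {len(occ)} (raw {len(occ) + removed} = clean + {removed} removed)")
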