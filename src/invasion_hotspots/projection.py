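"""Ensemble consensus, fixed-sensitivity binarization, dispersal scenarios.

Per-species continuous surfaces from each climate model are averaged
cell-wise into a consensus forecast, then cut at the species' own
threshold — the value at which 90% of its current-climate presence
scores are retained.  That single threshold, derived once from current
conditions, is applied unchanged to every future consensus surface.
The full-dispersal scenario takes the future mask as-is; the
no-dispersal scenario intersects it with the current mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import fixed_sensitivity_threshold
from .grid import GridSpec, require_aligned
from .maxent import SuitabilitySurface


@dataclass
class BinarySuitability:
    """A thresholded habitat map plus the threshold that produced it."""

    grid: GridSpec
    mask: np.ndarray  # boolean; False on nodata cells too
    valid: np.ndarray  # where the surface was defined
    threshold: float
    species_id: str = ""
    scenario: str = ""

    @property
    def area_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_km2(self) -> float:
        return float(self.grid.cell_areas_km2()[self.mask].sum())


def consensus_surface(surfaces: list[SuitabilitySurface]) -> SuitabilitySurface:
    """Cell-wise mean of aligned per-model surfaces (nodata propagates)."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    require_aligned(*surfaces, names=[s.scenario or f"surface {i}" for i, s in enumerate(surfaces)])
    species = {s.species_id for s in surfaces}
    if len(species) > 1:
        raise ValueError(f"surfaces belong to different species: {sorted(species)}")
    raw = np.mean([s.raw for s in surfaces], axis=0)
    logistic = np.mean([s.logistic for s in surfaces], axis=0)
    return SuitabilitySurface(
        surfaces[0].grid,
        raw,
        logistic,
        species_id=surfaces[0].species_id,
        scenario="consensus",
        n_clamped_cells=max(s.n_clamped_cells for s in surfaces),
    )


def binarize(
    surface: SuitabilitySurface,
    presence_scores_current,
    sensitivity: float = 0.90,
    threshold: float | None = None,
    scenario: str = "",
) -> BinarySuitability:
    """Threshold a surface at the species' fixed-sensitivity cutoff.

    The threshold comes from the species' current-climate logistic
    scores at its presence cells (or is passed explicitly when reusing a
    current threshold on a future surface); suitable = score >=
    threshold, inclusive, so ties stay inside.
    """
    if threshold is None:
        threshold = fixed_sensitivity_threshold(presence_scores_current, sensitivity)
    valid = surface.valid
    mask = np.zeros(surface.grid.shape, dtype=bool)
    mask[valid] = surface.logistic[valid] >= threshold
    return BinarySuitability(
        surface.grid, mask, valid, float(threshold), surface.species_id, scenario
    )


def vote_binarize(
    surfaces: list[SuitabilitySurface],
    threshold: float,
    min_agreement: float = 0.5,
    scenario: str = "",
) -> BinarySuitability:
    """Threshold each ensemble member first, then vote (non-default route).

    A cell is suitable when at least ``min_agreement`` of the per-model
    surfaces reach the threshold.  The default route is
    average-then-threshold (:func:`consensus_surface` + :func:`binarize`);
    this alternative exists for sensitivity analysis of that ordering.
    """
    if not surfaces:
        raise ValueError("no surfaces to vote over")
    require_aligned(*surfaces, names=[s.scenario or f"surface {i}" for i, s in enumerate(surfaces)])
    votes = np.mean([s.logistic >= threshold for s in surfaces], axis=0)
    valid = np.logical_and.reduce([s.valid for s in surfaces])
    mask = valid & (votes >= min_agreement)
    return BinarySuitability(
        surfaces[0].grid, mask, valid, float(threshold), surfaces[0].species_id, scenario
    )


def dispersal_scenarios(
    current: BinarySuitability, future: BinarySuitability
) -> tuple[BinarySuitability, BinarySuitability]:
    """(full-dispersal, no-dispersal) future maps.

    Full dispersal keeps the future mask; no dispersal intersects it
    with the current mask, so a species keeps only habitat that is
    suitable both now and later.
    """
    if not current.grid.compatible(future.grid):
        raise ValueError("current and future masks are on different grids")
    full = BinarySuitability(
        future.grid,
        future.mask.copy(),
        future.valid,
        future.threshold,
        future.species_id,
        f"{future.scenario}/full-dispersal",
    )
    none = BinarySuitability(
        future.grid,
        current.mask & future.mask,
        future.valid & current.valid,
        future.threshold,
        future.species_id,
        f"{future.scenario}/no-dispersal",
    )
    return full, none


def area_stats(mask: np.ndarray, grid: GridSpec) -> tuple[int, float]:
    """(cell count, geodesic km2) of a boolean mask on a grid."""
    mask = np.asarray(mask, dtype=bool)
    return int(mask.sum()), float(grid.cell_areas_km2()[mask].sum())
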