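"""Stacked-richness hotspots and areal-change summaries.

Per-species binary habitat maps are summed into a richness surface (how
many species find suitable habitat in each cell).  A hotspot is the set
of cells at or above the top-25th-percentile richness cutoff for a
scope — the whole domain or one region of a partition.  Future change
is measured by freezing each scope's *current* cutoff and applying it
to the future richness surface, so expansion and contraction are
expressed against a fixed bar.

Percentile convention: linear interpolation between order statistics by
default, with a nearest-rank option; ties at the cutoff are always
included (>=), so a tied surface can put more than 25% of a scope in
the hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, require_aligned
from .projection import BinarySuitability

DEFAULT_BANDS = (5, 10, 15, 20, 25)


@dataclass
class RichnessSurface:
    grid: GridSpec
    counts: np.ndarray  # float with NaN off-domain; integer-valued on valid cells
    n_species: int
    scenario: str = ""

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.counts)


@dataclass
class HotspotResult:
    cutoff_value: float
    mask: np.ndarray
    mean_richness: float  # over hotspot cells; NaN when empty
    sd_richness: float  # sample SD; NaN when < 2 cells
    area_cells: int
    area_km2: float
    scope: str = "domain"


@dataclass
class RegionChangeRow:
    region_id: str
    scenario: str
    current_area_km2: float
    future_area_km2: float
    pct_change: float  # NaN (flagged) when current area is zero
    mean_richness: float
    sd_richness: float


def stack_richness(masks: list[BinarySuitability], scenario: str = "") -> RichnessSurface:
    """Cell-wise sum of per-species binary maps; nodata propagates."""
    if not masks:
        raise ValueError("no species masks to stack")
    require_aligned(*masks, names=[m.species_id or f"mask {i}" for i, m in enumerate(masks)])
    counts = np.sum([m.mask.astype(float) for m in masks], axis=0)
    valid = np.logical_and.reduce([m.valid for m in masks])
    counts = np.where(valid, counts, np.nan)
    return RichnessSurface(masks[0].grid, counts, len(masks), scenario)


def hotspot_cutoff(
    surface: RichnessSurface,
    scope_cells: np.ndarray | None = None,
    percentile: float = 75.0,
    method: str = "linear",
) -> float:
    """The percentile cutoff of richness over a scope's valid cells."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be inside (0, 100)")
    scope = surface.valid if scope_cells is None else (np.asarray(scope_cells, bool) & surface.valid)
    vals = surface.counts[scope]
    if vals.size == 0:
        raise ValueError("hotspot scope contains no valid cells")
    if method == "nearest-rank":
        return float(np.percentile(vals, percentile, method="inverted_cdf"))
    return float(np.percentile(vals, percentile))


def hotspot_mask(
    surface: RichnessSurface,
    cutoff: float,
    scope_cells: np.ndarray | None = None,
    scope: str = "domain",
) -> HotspotResult:
    """Cells of the scope at or above the cutoff, with richness stats.

    Mean and SD (sample, n-1) are computed over hotspot cells only;
    both are NaN-flagged when the mask is empty (SD also for a single
    cell).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    in_scope = surface.valid if scope_cells is None else (
        np.asarray(scope_cells, bool) & surface.valid
    )
    mask = in_scope & (surface.counts >= cutoff)
    vals = surface.counts[mask]
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    cells = int(mask.sum())
    km2 = float(surface.grid.cell_areas_km2()[mask].sum())
    return HotspotResult(float(cutoff), mask, mean, sd, cells, km2, scope)


def future_change(
    current: HotspotResult,
    future_surface: RichnessSurface,
    scope_cells: np.ndarray | None = None,
    region_id: str = "domain",
) -> RegionChangeRow:
    """Apply the current cutoff to a future surface and measure the change.

    ``pct_change = 100 * (future - current) / current`` in km²; NaN
    (undefined, flagged by the caller) when the current hotspot is
    empty.
    """
    fut = hotspot_mask(future_surface, current.cutoff_value, scope_cells, current.scope)
    if current.area_km2 > 0:
        pct = 100.0 * (fut.area_km2 - current.area_km2) / current.area_km2
    else:
        pct = float("nan")
    return RegionChangeRow(
        region_id,
        future_surface.scenario,
        current.area_km2,
        fut.area_km2,
        pct,
        fut.mean_richness,
        fut.sd_richness,
    )


def percentile_bands(
    surface: RichnessSurface,
    scope_cells: np.ndarray | None = None,
    bands=DEFAULT_BANDS,
    method: str = "linear",
) -> np.ndarray:
    """Label each scope cell with the tightest top-percentile band it meets.

    ``bands=(5, 10, 15, 20, 25)`` labels a cell 5 if it reaches the
    top-5% cutoff, else 10 if it reaches the top-10% cutoff, and so on;
    cells below the loosest cutoff are labelled 0 (background).
    """
    bands = tuple(bands)
    if list(bands) != sorted(bands) or len(set(bands)) != len(bands):
        raise ValueError("bands must be strictly increasing")
    scope = surface.valid if scope_cells is None else (np.asarray(scope_cells, bool) & surface.valid)
    out = np.zeros(surface.grid.shape, dtype=int)
    out[~scope] = -1  # off-scope marker
    # assign from loosest to tightest so tighter bands overwrite
    for b in sorted(bands, reverse=True):
        cut = hotspot_cutoff(surface, scope, 100.0 - b, method)
        out[scope & (surface.counts >= cut)] = b
    return out


def species_in_region(
    masks: list[BinarySuitability], region_mask: np.ndarray
) -> tuple[int, pd.DataFrame]:
    """How many species have suitable habitat intersecting a region.

    Returns the count of species with at least one suitable cell inside
    the region and a per-species table of suitable cell counts there.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    rows = []
    for m in masks:
        cells = int((m.mask & region_mask).sum())
        rows.append({"species": m.species_id, "suitable_cells": cells})
    table = pd.DataFrame(rows, columns=["species", "suitable_cells"])
    return int((table["suitable_cells"] > 0).sum()), table


def region_summary_table(
    current_masks: list[BinarySuitability],
    future_masks_by_scenario: dict[str, list[BinarySuitability]],
    region_raster,
    percentile: float = 75.0,
    include_domain: bool = True,
) -> pd.DataFrame:
    """Current and per-scenario hotspot summary rows for every scope.

    One row per (scope, scenario) pair: mean and SD of richness inside
    the hotspot, its area, and the percent change of the future hotspot
    at the frozen current cutoff.  Scopes are the whole domain plus each
    region of the partition raster.
    """
    current_surface = stack_richness(current_masks, "current")
    future_surfaces = {
        sc: stack_richness(ms, sc) for sc, ms in future_masks_by_scenario.items()
    }
    labels = region_raster.values
    region_ids = sorted(set(labels[np.isfinite(labels)].astype(int).tolist()))
    scopes: list[tuple[str, np.ndarray | None]] = []
    if include_domain:
        scopes.append(("domain", None))
    scopes += [(str(rid), labels == rid) for rid in region_ids]

    rows = []
    for scope_name, scope_cells in scopes:
        cut = hotspot_cutoff(current_surface, scope_cells, percentile)
        cur = hotspot_mask(current_surface, cut, scope_cells, scope_name)
        rows.append(
            {
                "region": scope_name,
                "scenario": "current",
                "mean": cur.mean_richness,
                "sd": cur.sd_richness,
                "area_km2": cur.area_km2,
                "area_cells": cur.area_cells,
                "pct_change": 0.0,
            }
        )
        for sc, fsurf in future_surfaces.items():
            row = future_change(cur, fsurf, scope_cells, scope_name)
            fut_cells = hotspot_mask(fsurf, cut, scope_cells, scope_name).area_cells
            rows.append(
                {
                    "region": scope_name,
                    "scenario": sc,
                    "mean": row.mean_richness,
                    "sd": row.sd_richness,
                    "area_km2": row.future_area_km2,
                    "area_cells": fut_cells,
                    "pct_change": row.pct_change,
                }
            )
    return pd.DataFrame(rows)
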