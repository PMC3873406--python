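"""Background-point sampling under climate-zone restriction.

Presence-background models contrast the environments at known presences
with a sample of the available landscape.  Here "available" means: cells
belonging to a climate zone in which the species has at least one
record, excluding the presence cells themselves and nodata cells.  Each
cell holds at most one background point, placed at the cell centre so
predictor extraction is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, Raster
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class BackgroundSet:
    species_id: str
    points: pd.DataFrame  # columns: lon, lat, cell_index
    zone_ids_used: set
    seed: int
    shortfall: int = 0

    def __len__(self) -> int:
        return len(self.points)


def presence_cells(occ: OccurrenceSet, grid: GridSpec) -> np.ndarray:
    """Sorted unique flat cell indices holding at least one record.

    Records outside the grid are ignored (they cannot collide with
    landscape cells).
    """
    lon = occ.records["lon"].to_numpy(float)
    lat = occ.records["lat"].to_numpy(float)
    inside = grid.contains(lon, lat)
    row, col = grid.cell_of(lon[inside], lat[inside])
    return np.unique(grid.flat_index(row, col))


def eligible_cells(presences: OccurrenceSet, zones: Raster) -> np.ndarray:
    """Flat indices of cells available for background sampling.

    Cells whose zone label appears among the presence cells, minus the
    presence cells themselves, minus nodata cells.
    """
    grid = zones.grid
    pres = presence_cells(presences, grid)
    zflat = zones.values.ravel()
    pres_zones = zflat[pres]
    pres_zones = np.unique(pres_zones[np.isfinite(pres_zones)])
    if pres_zones.size == 0:
        raise ValueError(
            f"{presences.species_id}: all presence records fall on nodata cells"
        )
    in_zone = np.isin(zflat, pres_zones) & np.isfinite(zflat)
    in_zone[pres] = False
    return np.flatnonzero(in_zone)


def sample_background(
    eligible: np.ndarray,
    n: int,
    seed: int,
    grid: GridSpec,
    species_id: str = "",
    zones: Raster | None = None,
) -> BackgroundSet:
    """Draw min(n, |eligible|) cells uniformly without replacement.

    Points sit at cell centres; any shortfall against the requested n is
    logged and recorded on the returned set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = np.asarray(eligible)
    if eligible.size == 0:
        raise ValueError("no eligible background cells")
    rng = np.random.default_rng(seed)
    take = min(n, eligible.size)
    shortfall = n - take
    if shortfall:
        logger.warning(
            "%s: only %d eligible cells for %d requested background points",
            species_id,
            eligible.size,
            n,
        )
    cells = rng.choice(eligible, size=take, replace=False)
    rows, cols = np.divmod(cells, grid.cols)
    lon = grid.origin_lon + (cols + 0.5) * grid.cell_size_deg
    lat = grid.origin_lat - (rows + 0.5) * grid.cell_size_deg
    points = pd.DataFrame({"lon": lon, "lat": lat, "cell_index": cells})
    zone_ids: set = set()
    if zones is not None:
        zone_ids = set(np.unique(zones.values.ravel()[cells]).tolist())
    return BackgroundSet(species_id, points, zone_ids, seed, shortfall)
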