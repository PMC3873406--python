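"""Occurrence-record cleaning for presence-only niche modelling.

Herbarium and aggregator downloads need four standard repairs before
they can calibrate a model: cultivated specimens are dropped, exact and
near-duplicate records are collapsed onto an equal-area grid (8 km by
default), regions with much denser collection effort than the rest of
the range are thinned to a density cap, and species with too few records
are set aside.  Every step appends a ``(step, removed_count)`` entry to
the set's cleaning log, so raw count = final count + sum of removals
always holds.

The dedup grid uses the Lambert cylindrical equal-area projection on the
authalic sphere (x = R*lon_rad, y = R*sin(lat_rad)); any equal-area
projection serves, since only cell membership matters.  Cell assignment
is by floor, so boundary records land deterministically in the cell to
their south-west in projected coordinates.  All steps keep the first
record in input order among duplicates and preserve input order among
survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["species", "lon", "lat", "cultivated", "source"]


@dataclass
class OccurrenceSet:
    """Cleaned or raw presence records for one species, with provenance."""

    species_id: str
    records: pd.DataFrame
    cleaning_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        for col in ("lon", "lat"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite {col} in records for {self.species_id}")
        if np.any(np.abs(df["lon"].to_numpy(float)) > 180) or np.any(
            np.abs(df["lat"].to_numpy(float)) > 90
        ):
            raise ValueError(f"coordinates out of range for {self.species_id}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def _evolve(self, survivors: pd.DataFrame, step: str, removed: int) -> "OccurrenceSet":
        return OccurrenceSet(
            self.species_id,
            survivors.reset_index(drop=True),
            self.cleaning_log + [(step, removed)],
        )


def from_frame(df: pd.DataFrame) -> dict[str, OccurrenceSet]:
    """Split a multi-species occurrence table into per-species sets."""
    out = {}
    for sp, sub in df.groupby("species", sort=True):
        out[str(sp)] = OccurrenceSet(str(sp), sub.reset_index(drop=True))
    return out


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    return from_frame(pd.read_csv(path))


def write_occurrences(path, sets) -> None:
    frames = [s.records.assign(species=s.species_id) for s in sets]
    pd.concat(frames, ignore_index=True)[OCC_COLUMNS].to_csv(path, index=False)


def equal_area_cell(lon, lat, cell_km: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer (ix, iy) cell indices on the equal-area dedup grid."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.deg2rad(lon)
    y = EARTH_RADIUS_KM * np.sin(np.deg2rad(lat))
    return np.floor(x / cell_km).astype(int), np.floor(y / cell_km).astype(int)


def remove_cultivated(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop records flagged as cultivated (garden/trial specimens)."""
    flag = occ.records["cultivated"].astype(bool).to_numpy()
    return occ._evolve(occ.records[~flag], "cultivated", int(flag.sum()))


def dedupe_equal_area(occ: OccurrenceSet, cell_km: float = 8.0) -> OccurrenceSet:
    """Keep at most one record per equal-area ``cell_km`` grid cell.

    The first record in input order wins.  Records whose projection is
    degenerate (non-finite coordinates — cannot occur for in-range
    inputs, guarded anyway) are dropped and counted separately.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    df = occ.records
    ix, iy = equal_area_cell(df["lon"], df["lat"], cell_km)
    bad = ~(np.isfinite(ix.astype(float)) & np.isfinite(iy.astype(float)))
    out = occ
    if bad.any():
        logger.warning("%d records dropped: projection failure", int(bad.sum()))
        out = out._evolve(df[~bad], "projection_failure", int(bad.sum()))
        df = out.records
        ix, iy = equal_area_cell(df["lon"], df["lat"], cell_km)
    keys = pd.DataFrame({"ix": ix, "iy": iy})
    dup = keys.duplicated(keep="first").to_numpy()
    return out._evolve(df[~dup], "duplicate_cell", int(dup.sum()))


def thin_bias(
    occ: OccurrenceSet,
    bias_regions,
    target_density: int,
    cell_km: float = 8.0,
    seed: int = 0,
) -> OccurrenceSet:
    """Cap the per-cell record count inside over-collected regions.

    ``bias_regions`` is a list of (lon_min, lat_min, lon_max, lat_max)
    rectangles.  Within each, cells holding more than ``target_density``
    records are subsampled to the cap by a seeded random choice; records
    outside every rectangle are untouched.  An empty list is the identity
    (with a zero-count log entry).
    """
    if target_density < 1:
        raise ValueError("target_density must be >= 1")
    df = occ.records
    if not bias_regions or df.empty:
        return occ._evolve(df, "bias_thinning", 0)
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    in_region = np.zeros(len(df), dtype=bool)
    for lon0, lat0, lon1, lat1 in bias_regions:
        in_region |= (lon >= min(lon0, lon1)) & (lon <= max(lon0, lon1)) & (
            lat >= min(lat0, lat1)
        ) & (lat <= max(lat0, lat1))
    ix, iy = equal_area_cell(lon, lat, cell_km)
    rng = np.random.default_rng(seed)
    keep = np.ones(len(df), dtype=bool)
    cells = pd.DataFrame({"ix": ix, "iy": iy, "pos": np.arange(len(df))})[in_region]
    for _, grp in cells.groupby(["ix", "iy"], sort=True):
        if len(grp) > target_density:
            drop = rng.choice(grp["pos"].to_numpy(), size=len(grp) - target_density, replace=False)
            keep[drop] = False
    return occ._evolve(df[keep], "bias_thinning", int((~keep).sum()))


def min_records_filter(sets, min_n: int = 100):
    """Partition species by the strict more-than-``min_n`` record rule.

    Returns ``(passed, failed)`` lists; nothing is mutated.  The rule is
    applied to whatever state the sets are in — typically before
    cleaning, so species can legitimately end up with fewer records
    after deduplication.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    passed = [s for s in sets if len(s) > min_n]
    failed = [s for s in sets if len(s) <= min_n]
    return passed, failed


def clean_pipeline(
    occ: OccurrenceSet,
    cell_km: float = 8.0,
    bias_regions=(),
    target_density: int = 1,
    seed: int = 0,
) -> OccurrenceSet:
    """The standard cleaning order: cultivated -> dedupe -> bias thinning."""
    out = remove_cultivated(occ)
    out = dedupe_equal_area(out, cell_km)
    out = thin_bias(out, list(bias_regions), target_density, cell_km, seed)
    return out


def cleaning_report(sets) -> pd.DataFrame:
    """Tidy (species, step, removed) table across a collection of sets."""
    rows = [
        {"species": s.species_id, "step": step, "removed": n}
        for s in sets
        for step, n in s.cleaning_log
    ]
    return pd.DataFrame(rows, columns=["species", "step", "removed"])
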