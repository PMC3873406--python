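"""Synthetic worlds: climate grids, species, climate-model anomalies, regions.

Every input the pipeline needs can be generated here from a seed, so the
whole analysis is testable without external downloads.  The generated
world is a northern-hemisphere-style rectangle whose temperature falls
with latitude and whose rainfall rises with longitude; species are given
known Gaussian niches in MAT and AP so that model output can be checked
against the truth that produced the data.

Generator equations (cell centre at longitude ``lon``, latitude ``lat``,
month ``m`` in 0..11; ``eps_*`` are unit-variance smoothed-noise fields,
identically zero when ``noise_scale == 0``):

    tmax[m] = TMAX_BASE + SEASONAL_AMP*cos(2*pi*(m - 6)/12)
              + temp_gradient*lat + TEMP_NOISE_AMP*eps_T
    tmin[m] = tmax[m] - DIURNAL_RANGE
    prec[m] = max(0, (AP_BASE + AP_LON_GRADIENT*(lon - origin_lon)) / 12
                     * (1 + PREC_SEASONAL*cos(2*pi*m/12))
                     * exp(PREC_NOISE_AMP*eps_P))
    tcf     = clip(TCF_BASE + TCF_NOISE_AMP*eps_C, 0, 100)

The noise fields are standard-normal white noise smoothed with a
Gaussian kernel of width ``noise_scale`` cells and rescaled to unit
marginal variance — cheap, seedable, and spatially autocorrelated.  The
three fields are drawn in the fixed order T, P, C from one generator
seeded with the world seed, so identical specs reproduce bit-identical
worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import ndimage

from .climate import AnomalyStack, BioclimStack, MonthlyClimateStack, derive_bioclim
from .grid import GridSpec, Raster
from .occurrences import OccurrenceSet

TMAX_BASE = 30.0  # °C, warmest-month tmax at latitude 0
SEASONAL_AMP = 8.0  # °C, annual tmax cycle half-amplitude
DIURNAL_RANGE = 8.0  # °C, tmax - tmin
TEMP_NOISE_AMP = 2.0  # °C
AP_BASE = 400.0  # mm/yr at the western edge
AP_LON_GRADIENT = 30.0  # mm/yr per degree longitude
PREC_SEASONAL = 0.6  # fractional summer-wet amplitude
PREC_NOISE_AMP = 0.3  # log-scale
TCF_BASE = 45.0  # % weight
TCF_NOISE_AMP = 20.0


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Size, placement and texture of a synthetic world."""

    grid_rows: int = 60
    grid_cols: int = 60
    cell_size_deg: float = 0.5
    origin_lon: float = 110.0
    origin_lat: float = 50.0
    temp_gradient: float = -0.5  # °C per degree latitude
    noise_scale: float = 3.0  # Gaussian kernel width, cells; 0 = noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("degenerate grid: need at least 4x4 cells")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.grid_rows, self.grid_cols, self.origin_lon, self.origin_lat, self.cell_size_deg
        )


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """A species with a known product-Gaussian niche in MAT and AP."""

    species_id: str
    niche_optimum: tuple[float, float] = (12.0, 900.0)  # (MAT °C, AP mm)
    niche_breadth: tuple[float, float] = (3.0, 250.0)  # Gaussian SDs
    n_presences: int = 300
    cultivated_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    bias_region: tuple[float, float, float, float] | None = None
    bias_multiplier: float = 1.0

    def __post_init__(self) -> None:
        # normalize sequences (e.g. YAML lists) to tuples
        object.__setattr__(self, "niche_optimum", tuple(self.niche_optimum))
        object.__setattr__(self, "niche_breadth", tuple(self.niche_breadth))
        if self.bias_region is not None:
            object.__setattr__(self, "bias_region", tuple(self.bias_region))
        if self.n_presences < 5:
            raise ValueError("n_presences must be >= 5")
        for frac in (self.cultivated_fraction, self.duplicate_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contamination fractions must lie in [0, 1]")
        if self.bias_multiplier < 1.0:
            raise ValueError("bias_multiplier must be >= 1")


def noise_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field; zeros when scale == 0.

    White N(0,1) noise smoothed with a Gaussian kernel (reflect
    boundaries) and rescaled to unit sample variance.
    """
    if scale == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


@dataclass
class SyntheticWorld:
    """A generated world: monthly climate, soil, land mask, and its spec."""

    spec: SyntheticWorldSpec
    climate: MonthlyClimateStack
    tcf: Raster
    land_mask: np.ndarray

    @property
    def grid(self) -> GridSpec:
        return self.spec.grid

    @cached_property
    def bioclim(self) -> BioclimStack:
        return derive_bioclim(self.climate, self.tcf)


def generate_climate(
    spec: SyntheticWorldSpec, land_mask: np.ndarray | None = None
) -> SyntheticWorld:
    """Generate the 37-layer climate+soil stack for a world spec.

    Returns a :class:`SyntheticWorld`; cells outside ``land_mask`` (all
    land by default) are NaN in every layer.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    eps_t = noise_field(rng, grid.shape, spec.noise_scale)
    eps_p = noise_field(rng, grid.shape, spec.noise_scale)
    eps_c = noise_field(rng, grid.shape, spec.noise_scale)

    lon, lat = grid.center_mesh()
    months = np.arange(12)
    tmax = (
        TMAX_BASE
        + SEASONAL_AMP * np.cos(2 * np.pi * (months[:, None, None] - 6) / 12)
        + spec.temp_gradient * lat[None]
        + TEMP_NOISE_AMP * eps_t[None]
    )
    tmin = tmax - DIURNAL_RANGE
    monthly_base = (AP_BASE + AP_LON_GRADIENT * (lon - spec.origin_lon)) / 12.0
    season = 1 + PREC_SEASONAL * np.cos(2 * np.pi * months / 12)
    prec = np.maximum(
        0.0, monthly_base[None] * season[:, None, None] * np.exp(PREC_NOISE_AMP * eps_p)[None]
    )
    tcf = np.clip(TCF_BASE + TCF_NOISE_AMP * eps_c, 0.0, 100.0)

    if land_mask is None:
        land_mask = np.ones(grid.shape, dtype=bool)
    else:
        land_mask = np.asarray(land_mask, dtype=bool)
        if land_mask.shape != grid.shape:
            raise ValueError("land mask does not match the grid")
    sea = ~land_mask
    for arr in (tmax, tmin, prec):
        arr[:, sea] = np.nan
    tcf = np.where(land_mask, tcf, np.nan)

    stack = MonthlyClimateStack(grid, tmax, tmin, prec)
    return SyntheticWorld(spec, stack, Raster(grid, tcf, "TCF"), land_mask)


def true_suitability(world: SyntheticWorld, sspec: SyntheticSpeciesSpec) -> Raster:
    """The species' true niche response evaluated on the world.

    Product of Gaussian responses in MAT and AP, maximal (=1) at the
    niche optimum; NaN off land.
    """
    mat = world.bioclim["MAT"]
    ap = world.bioclim["AP"]
    (mu_t, mu_p), (sd_t, sd_p) = sspec.niche_optimum, sspec.niche_breadth
    s = np.exp(-0.5 * ((mat - mu_t) / sd_t) ** 2) * np.exp(-0.5 * ((ap - mu_p) / sd_p) ** 2)
    return Raster(world.grid, s, f"true_suitability_{sspec.species_id}")


def _sample_cells(rng, grid, probs_flat, n):
    idx = rng.choice(grid.n_cells, size=n, p=probs_flat, replace=True)
    rows, cols = np.unravel_index(idx, grid.shape)
    # uniform jitter within the sampled cell
    lon = grid.origin_lon + (cols + rng.uniform(0, 1, n)) * grid.cell_size_deg
    lat = grid.origin_lat - (rows + rng.uniform(0, 1, n)) * grid.cell_size_deg
    return lon, lat


def generate_species(
    world: SyntheticWorld, sspec: SyntheticSpeciesSpec, seed: int = 0
) -> tuple[OccurrenceSet, Raster]:
    """Sample contaminated occurrence records from a known niche.

    Clean presences are drawn cell-wise proportionally to true
    suitability (with replacement — records cluster in good habitat, as
    herbarium data do) and jittered uniformly within their cell.
    Contamination is then appended in order: exact duplicates of clean
    records (``duplicate_fraction`` x n), cultivated-flagged records at
    uniform random land locations (``cultivated_fraction`` x n), and
    bias-region oversampling ((bias_multiplier - 1) x the clean count
    inside the rectangle, drawn from the niche restricted to it).
    Returns the record set and the true suitability raster.
    """
    suit = true_suitability(world, sspec)
    s = np.nan_to_num(suit.values, nan=0.0).ravel()
    n_avail = int(np.count_nonzero(s))
    if sspec.n_presences > n_avail:
        raise ValueError(
            f"{sspec.species_id}: requested {sspec.n_presences} presences but only "
            f"{n_avail} cells have nonzero suitability (short by {sspec.n_presences - n_avail})"
        )
    rng = np.random.default_rng(seed)
    grid = world.grid
    probs = s / s.sum()
    lon, lat = _sample_cells(rng, grid, probs, sspec.n_presences)
    frames = [
        pd.DataFrame(
            {"lon": lon, "lat": lat, "cultivated": 0, "source": "synthetic"}
        )
    ]

    n_dup = round(sspec.duplicate_fraction * sspec.n_presences)
    if n_dup:
        pick = rng.integers(0, sspec.n_presences, n_dup)
        dup = frames[0].iloc[pick].copy()
        dup["source"] = "synthetic_duplicate"
        frames.append(dup)

    n_cult = round(sspec.cultivated_fraction * sspec.n_presences)
    if n_cult:
        land_flat = world.land_mask.ravel().astype(float)
        lon_c, lat_c = _sample_cells(rng, grid, land_flat / land_flat.sum(), n_cult)
        frames.append(
            pd.DataFrame(
                {"lon": lon_c, "lat": lat_c, "cultivated": 1, "source": "synthetic_cultivated"}
            )
        )

    if sspec.bias_region is not None and sspec.bias_multiplier > 1:
        lon0, lat0, lon1, lat1 = sspec.bias_region
        clean = frames[0]
        in_box = (
            (clean["lon"] >= min(lon0, lon1))
            & (clean["lon"] <= max(lon0, lon1))
            & (clean["lat"] >= min(lat0, lat1))
            & (clean["lat"] <= max(lat0, lat1))
        )
        n_bias = round((sspec.bias_multiplier - 1) * int(in_box.sum()))
        if n_bias:
            glon, glat = grid.center_mesh()
            box = (
                (glon >= min(lon0, lon1))
                & (glon <= max(lon0, lon1))
                & (glat >= min(lat0, lat1))
                & (glat <= max(lat0, lat1))
            )
            sb = s * box.ravel()
            if sb.sum() > 0:
                lon_b, lat_b = _sample_cells(rng, grid, sb / sb.sum(), n_bias)
                frames.append(
                    pd.DataFrame(
                        {"lon": lon_b, "lat": lat_b, "cultivated": 0, "source": "synthetic_bias"}
                    )
                )

    records = pd.concat(frames, ignore_index=True)
    records.insert(0, "species", sspec.species_id)
    return OccurrenceSet(sspec.species_id, records), suit


def generate_anomalies(
    world: SyntheticWorld,
    n_gcms: int,
    warming_mean: float = 2.0,
    warming_sd: float = 0.5,
    precip_factor: float = 0.9,
    coarsen_factor: int = 4,
    seed: int = 0,
    rcp_id: str = "RCP8.5",
    period: str = "2065",
) -> list[AnomalyStack]:
    """Coarse warming/drying anomaly stacks for an ensemble of climate models.

    Each model's temperature delta is ``warming_mean + warming_sd * eps``
    (one smoothed field per model, applied to all 12 months) and its
    precipitation change is a multiplicative factor
    ``precip_factor * exp(0.05 * warming_sd * eps')``, so with
    ``warming_sd == 0`` all models are identical and ``precip_factor == 1``
    means exactly no change.
    """
    if n_gcms < 1:
        raise ValueError("n_gcms must be >= 1")
    coarse = world.grid.coarsen(coarsen_factor)
    rng = np.random.default_rng(seed)
    stacks = []
    for g in range(n_gcms):
        eps_t = noise_field(rng, coarse.shape, 1.0) if warming_sd > 0 else np.zeros(coarse.shape)
        eps_p = noise_field(rng, coarse.shape, 1.0) if warming_sd > 0 else np.zeros(coarse.shape)
        dtemp = np.broadcast_to(warming_mean + warming_sd * eps_t, (12, *coarse.shape)).copy()
        pfac = np.broadcast_to(
            precip_factor * np.exp(0.05 * warming_sd * eps_p), (12, *coarse.shape)
        ).copy()
        stacks.append(
            AnomalyStack(
                coarse,
                dtemp,
                pfac,
                gcm_id=f"GCM{g + 1}",
                rcp_id=rcp_id,
                period=period,
                prec_mode="multiplicative",
            )
        )
    return stacks


def generate_regions(
    world: SyntheticWorld, n_regions: int, seed: int = 0, mat_bins: int = 3, ap_bins: int = 2
) -> tuple[Raster, Raster]:
    """Partition the land into contiguous regions and derive climate zones.

    Regions grow by multi-source breadth-first search from ``n_regions``
    seed cells drawn uniformly from land, so every region is contiguous
    by construction and the labels tile the land exactly.  The zone
    raster bins MAT into ``mat_bins`` and AP into ``ap_bins`` land-cell
    quantiles (zone id = mat_bin * ap_bins + ap_bin), standing in for a
    discrete climate classification.
    """
    grid = world.grid
    land = world.land_mask
    n_land = int(land.sum())
    if not 1 <= n_regions <= n_land:
        raise ValueError("n_regions must be between 1 and the number of land cells")
    rng = np.random.default_rng(seed)
    land_idx = np.flatnonzero(land.ravel())
    seeds = rng.choice(land_idx, size=n_regions, replace=False)

    labels = np.full(grid.shape, -1, dtype=int)
    from collections import deque

    queue: deque[tuple[int, int]] = deque()
    for lab, flat in enumerate(seeds):
        r, c = divmod(int(flat), grid.cols)
        labels[r, c] = lab
        queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.rows and 0 <= cc < grid.cols and land[rr, cc] and labels[rr, cc] < 0:
                labels[rr, cc] = labels[r, c]
                queue.append((rr, cc))
    # land cells unreachable by 4-connectivity (isolated islands): nearest seed
    orphan = land & (labels < 0)
    if orphan.any():
        srows, scols = np.divmod(seeds, grid.cols)
        orows, ocols = np.nonzero(orphan)
        d2 = (orows[:, None] - srows[None]) ** 2 + (ocols[:, None] - scols[None]) ** 2
        labels[orows, ocols] = np.argmin(d2, axis=1)

    region = np.where(land, labels, np.nan).astype(float)

    mat, ap = world.bioclim["MAT"], world.bioclim["AP"]
    zone = np.full(grid.shape, np.nan)
    mat_land, ap_land = mat[land], ap[land]
    mat_edges = np.quantile(mat_land, np.linspace(0, 1, mat_bins + 1)[1:-1])
    ap_edges = np.quantile(ap_land, np.linspace(0, 1, ap_bins + 1)[1:-1])
    mat_bin = np.digitize(mat, mat_edges)
    ap_bin = np.digitize(ap, ap_edges)
    zone[land] = (mat_bin * ap_bins + ap_bin)[land]

    return Raster(grid, region, "regions"), Raster(grid, zone, "zones")
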