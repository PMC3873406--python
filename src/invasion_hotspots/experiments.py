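"""Self-contained synthetic study designs built on the pipeline stages.

Two experiments double as the package's scientific self-checks:

- :func:`recovery_experiment` asks whether the model recovers a known
  Gaussian niche from sampled presences — the basic validity check for
  any presence-background method — and contrasts it with a
  label-shuffled control whose discrimination should collapse to
  chance.
- :func:`warming_shift_experiment` runs a miniature end-to-end study:
  several species, a warming anomaly ensemble, fixed-sensitivity
  binarization, richness stacking and frozen-cutoff hotspot change.  In
  a world whose temperature falls with latitude, warming should push
  stacked richness poleward, pull the hotspot's equatorward edge
  poleward, and expand the hotspot inside a cold high-latitude region —
  the classic poleward-shift signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .background import eligible_cells, presence_cells, sample_background
from .climate import apply_anomaly, derive_bioclim, downscale_anomaly
from .evaluation import auc as auc_score
from .hotspots import hotspot_cutoff, hotspot_mask, stack_richness
from .maxent import build_features, cross_validate, fit, predict
from .projection import binarize
from .synth import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    generate_anomalies,
    generate_climate,
    generate_regions,
    generate_species,
)


@dataclass
class RecoveryResult:
    spearman_rho: float
    cv_auc: float
    train_auc: float
    shuffled_aucs: np.ndarray
    n_presence_cells: int
    n_background: int


def recovery_experiment(
    seed: int = 42,
    rows: int = 100,
    cols: int = 100,
    n_presences: int = 500,
    n_background: int = 10_000,
    n_shuffles: int = 20,
    folds: int = 5,
) -> RecoveryResult:
    """Fit a known Gaussian-niche species and score niche recovery.

    Returns the Spearman correlation between true and predicted
    suitability over all cells, the cross-validated AUC, and the
    cross-validated AUCs of ``n_shuffles`` label-shuffled controls
    (presence labels reassigned at random over the pooled landscape
    cells).
    """
    world = generate_climate(SyntheticWorldSpec(grid_rows=rows, grid_cols=cols, seed=seed))
    _, zones = generate_regions(world, 6, seed=seed)
    sspec = SyntheticSpeciesSpec("recovery", n_presences=n_presences)
    occ, true_suit = generate_species(world, sspec, seed=seed)

    grid = world.grid
    bioclim = world.bioclim
    pres = presence_cells(occ, grid)
    elig = eligible_cells(occ, zones)
    bg = sample_background(elig, n_background, seed, grid, "recovery", zones)
    bg_cells = bg.points["cell_index"].to_numpy()

    pr, pc = np.divmod(pres, grid.cols)
    br, bc = np.divmod(bg_cells, grid.cols)
    fs, F_pres, F_bg = build_features(bioclim.matrix(pr, pc), bioclim.matrix(br, bc))
    model = fit(fs, F_pres, F_bg, training_meta={"species_id": "recovery"})

    surf = predict(model, bioclim)
    rho = stats.spearmanr(
        true_suit.values.ravel(), surf.logistic.ravel(), nan_policy="omit"
    ).statistic

    cv_aucs = [
        auc_score(m.scores(F_pres[idx]), m.scores(F_bg))
        for m, idx in cross_validate(fs, F_pres, F_bg, k=folds, seed=seed)
    ]
    train_auc = auc_score(model.scores(F_pres), model.scores(F_bg))

    # label-shuffled control: same landscape, presence labels at random
    pool = np.concatenate([pres, bg_cells])
    rng = np.random.default_rng(seed)
    shuffled = []
    for _ in range(n_shuffles):
        fake_pres = rng.choice(pool, size=pres.size, replace=False)
        fake_bg = np.setdiff1d(pool, fake_pres)
        fr, fc = np.divmod(fake_pres, grid.cols)
        gr, gc = np.divmod(fake_bg, grid.cols)
        sfs, sF_pres, sF_bg = build_features(
            bioclim.matrix(fr, fc), bioclim.matrix(gr, gc)
        )
        fold_aucs = [
            auc_score(m.scores(sF_pres[idx]), m.scores(sF_bg))
            for m, idx in cross_validate(sfs, sF_pres, sF_bg, k=2, seed=seed)
        ]
        shuffled.append(float(np.mean(fold_aucs)))

    return RecoveryResult(
        spearman_rho=float(rho),
        cv_auc=float(np.mean(cv_aucs)),
        train_auc=float(train_auc),
        shuffled_aucs=np.array(shuffled),
        n_presence_cells=int(pres.size),
        n_background=int(bg_cells.size),
    )


@dataclass
class WarmingShiftResult:
    centroid_lat_current: float
    centroid_lat_future: float
    edge_lat_current: float
    edge_lat_future: float
    domain_pct_change: float
    alpine_current_km2: float
    alpine_future_km2: float

    @property
    def centroid_moved_poleward(self) -> bool:
        return self.centroid_lat_future > self.centroid_lat_current

    @property
    def equatorward_edge_contracted(self) -> bool:
        return self.edge_lat_future > self.edge_lat_current

    @property
    def alpine_expanded(self) -> bool:
        return self.alpine_future_km2 > self.alpine_current_km2


def _richness_centroid_lat(surface) -> float:
    lat = surface.grid.center_mesh()[1]
    w = np.nan_to_num(surface.counts)
    return float((lat * w).sum() / w.sum())


def warming_shift_experiment(
    seed: int = 0,
    rows: int = 48,
    cols: int = 48,
    n_species: int = 8,
    n_background: int = 1500,
    warming_mean: float = 2.5,
    warming_sd: float = 0.3,
    n_gcms: int = 3,
    sensitivity: float = 0.90,
    percentile: float = 75.0,
    alpine_rows: int = 8,
) -> WarmingShiftResult:
    """Miniature end-to-end warming study on one seeded synthetic world.

    The world's temperature falls with latitude (northern-hemisphere
    style), species' thermal optima span the middle of the gradient, and
    the future climate is the ensemble consensus under a mean warming of
    ``warming_mean`` °C.  The "alpine analogue" is the coldest
    ``alpine_rows`` rows of the grid, treated as a region scope with its
    own current cutoff.
    """
    rng = np.random.default_rng(seed)
    world = generate_climate(SyntheticWorldSpec(grid_rows=rows, grid_cols=cols, seed=seed))
    _, zones = generate_regions(world, 5, seed=seed)
    bioclim_now = world.bioclim

    stacks = generate_anomalies(
        world, n_gcms, warming_mean=warming_mean, warming_sd=warming_sd,
        precip_factor=1.0, coarsen_factor=4, seed=seed,
    )
    future_stacks = []
    for st in stacks:
        fine = downscale_anomaly(st, world.grid)
        future_stacks.append(derive_bioclim(apply_anomaly(world.climate, fine), world.tcf))

    current_masks, future_masks = [], []
    for i in range(n_species):
        sspec = SyntheticSpeciesSpec(
            species_id=f"w{i}",
            niche_optimum=(float(rng.uniform(4, 11)), float(rng.uniform(600, 1100))),
            niche_breadth=(float(rng.uniform(2.0, 3.0)), float(rng.uniform(180, 280))),
            n_presences=200,
        )
        occ, _ = generate_species(world, sspec, seed=seed * 100 + i)
        pres = presence_cells(occ, world.grid)
        elig = eligible_cells(occ, zones)
        bg = sample_background(elig, n_background, seed + i, world.grid, sspec.species_id, zones)
        pr, pc = np.divmod(pres, world.grid.cols)
        br, bc = np.divmod(bg.points["cell_index"].to_numpy(), world.grid.cols)
        fs, F_pres, F_bg = build_features(
            bioclim_now.matrix(pr, pc), bioclim_now.matrix(br, bc)
        )
        model = fit(fs, F_pres, F_bg, training_meta={"species_id": sspec.species_id})
        pres_scores = model.logistic(F_pres)
        surf_now = predict(model, bioclim_now, scenario="current")
        cur_mask = binarize(surf_now, pres_scores, sensitivity, scenario="current")
        from .projection import consensus_surface

        per_gcm = [predict(model, bc_f, scenario="future") for bc_f in future_stacks]
        consensus = consensus_surface(per_gcm)
        fut_mask = binarize(consensus, None, threshold=cur_mask.threshold, scenario="future")
        current_masks.append(cur_mask)
        future_masks.append(fut_mask)

    rich_now = stack_richness(current_masks, "current")
    rich_fut = stack_richness(future_masks, "future")

    cut = hotspot_cutoff(rich_now, percentile=percentile)
    hot_now = hotspot_mask(rich_now, cut)
    hot_fut = hotspot_mask(rich_fut, cut)
    lat = world.grid.center_mesh()[1]

    def edge_lat(mask):
        # the equatorward (low-latitude) edge of the hotspot, measured as
        # the 5th percentile of hotspot-cell latitudes so a few straggler
        # cells on the domain boundary do not pin the edge there
        return float(np.percentile(lat[mask], 5)) if mask.any() else float("nan")

    pct = (
        100.0 * (hot_fut.area_km2 - hot_now.area_km2) / hot_now.area_km2
        if hot_now.area_km2 > 0
        else float("nan")
    )

    alpine_scope = np.zeros(world.grid.shape, dtype=bool)
    alpine_scope[:alpine_rows] = True
    alp_cut = hotspot_cutoff(rich_now, alpine_scope, percentile)
    alp_now = hotspot_mask(rich_now, alp_cut, alpine_scope, "alpine")
    alp_fut = hotspot_mask(rich_fut, alp_cut, alpine_scope, "alpine")

    return WarmingShiftResult(
        centroid_lat_current=_richness_centroid_lat(rich_now),
        centroid_lat_future=_richness_centroid_lat(rich_fut),
        edge_lat_current=edge_lat(hot_now.mask),
        edge_lat_future=edge_lat(hot_fut.mask),
        domain_pct_change=float(pct),
        alpine_current_km2=alp_now.area_km2,
        alpine_future_km2=alp_fut.area_km2,
    )
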