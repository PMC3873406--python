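"""End-to-end orchestration: clean -> predictors -> fit -> project -> hotspots.

A single :class:`PipelineConfig` drives the whole analysis.  The demo
mode generates every input synthetically (world, species, climate-model
anomalies, regions) from one seed; file mode consumes occurrence CSVs
and raster TIFFs produced elsewhere.  Species that fail the accuracy
gates (AUC, omission) are excluded from the richness stack and listed
in the run manifest, which also records checksums of every written
output so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import eligible_cells, presence_cells, sample_background
from .climate import BioclimStack, apply_anomaly, derive_bioclim, downscale_anomaly
from .evaluation import auc as auc_score
from .evaluation import evaluate, fixed_sensitivity_threshold
from .grid import Raster
from .hotspots import region_summary_table
from .maxent import build_features, cross_validate, fit, predict
from .occurrences import clean_pipeline, cleaning_report, min_records_filter
from .projection import binarize, consensus_surface, dispersal_scenarios
from .synth import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    generate_anomalies,
    generate_climate,
    generate_regions,
    generate_species,
)

logger = logging.getLogger(__name__)


@dataclass
class ScenarioSpec:
    rcp_id: str = "RCP8.5"
    period: str = "2065"
    warming_mean: float = 2.0
    warming_sd: float = 0.5
    precip_factor: float = 0.9

    @property
    def tag(self) -> str:
        return f"{self.rcp_id}_{self.period}"


@dataclass
class PipelineConfig:
    """Everything one run needs; all modelling constants are defaults here."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # synthetic-world inputs (file mode not listed here supplies rasters instead)
    world: SyntheticWorldSpec = field(default_factory=SyntheticWorldSpec)
    species: list[SyntheticSpeciesSpec] = field(default_factory=list)
    n_gcms: int = 7
    coarsen_factor: int = 4
    scenarios: list[ScenarioSpec] = field(default_factory=lambda: [ScenarioSpec()])
    n_regions: int = 8
    # cleaning
    dedupe_cell_km: float = 8.0
    min_records: int = 20
    # modelling
    n_background: int = 10_000
    beta_multiplier: float = 1.0
    folds: int = 5
    sensitivity: float = 0.90
    auc_gate: float = 0.75
    omission_gate: float = 0.5
    # hotspots
    percentile: float = 75.0
    bands: tuple = (5, 10, 15, 20, 25)
    # outputs
    write_rasters: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["world"] = SyntheticWorldSpec(**raw.get("world", {}))
        raw["species"] = [SyntheticSpeciesSpec(**s) for s in raw.get("species", [])]
        raw["scenarios"] = [ScenarioSpec(**s) for s in raw.get("scenarios", [{}])]
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every problem in a config; an empty list means runnable."""
    problems: list[str] = []
    if not 0.0 < config.sensitivity <= 1.0:
        problems.append(f"sensitivity must be in (0, 1], got {config.sensitivity}")
    if not 0.0 < config.percentile < 100.0:
        problems.append(f"percentile must be inside (0, 100), got {config.percentile}")
    if config.n_gcms < 1:
        problems.append("n_gcms must be >= 1")
    if config.n_background < 1:
        problems.append("n_background must be >= 1")
    if config.beta_multiplier < 0:
        problems.append("beta_multiplier must be >= 0")
    if config.folds < 2:
        problems.append("folds must be >= 2")
    if not config.species:
        problems.append("no species configured")
    if list(config.bands) != sorted(set(config.bands)):
        problems.append("bands must be strictly increasing")
    if config.n_regions < 1 or config.n_regions > config.world.grid.n_cells:
        problems.append("n_regions must be between 1 and the cell count")
    for sc in config.scenarios:
        if sc.precip_factor < 0:
            problems.append(f"{sc.tag}: precip_factor must be >= 0")
    return problems


def demo_config(
    seed: int = 0,
    outdir: str = "demo_out",
    n_species: int = 10,
    n_gcms: int = 2,
    rows: int = 40,
    cols: int = 40,
) -> PipelineConfig:
    """A small synthetic configuration that runs in minutes on one CPU."""
    rng = np.random.default_rng(seed)
    world = SyntheticWorldSpec(grid_rows=rows, grid_cols=cols, seed=seed)
    species = []
    for i in range(n_species):
        species.append(
            SyntheticSpeciesSpec(
                species_id=f"sp{i:02d}",
                niche_optimum=(float(rng.uniform(6, 18)), float(rng.uniform(550, 1150))),
                niche_breadth=(float(rng.uniform(2.5, 4.0)), float(rng.uniform(180, 300))),
                n_presences=int(rng.integers(150, 300)),
                cultivated_fraction=0.05,
                duplicate_fraction=0.05,
            )
        )
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        world=world,
        species=species,
        n_gcms=n_gcms,
        n_background=2000,
        scenarios=[ScenarioSpec()],
        n_regions=6,
        min_records=20,
    )


def fit_species_sdm(
    bioclim: BioclimStack,
    occ,
    zones: Raster,
    n_background: int,
    beta_multiplier: float,
    folds: int,
    seed: int,
):
    """Fit and cross-validate one species' model on a predictor stack.

    Presence records are collapsed to one per grid cell; the background
    is zone-restricted and disjoint from presence cells.  Returns the
    fitted model, the feature matrices, and the mean cross-validated
    AUC.
    """
    grid = bioclim.grid
    pres_cells = presence_cells(occ, grid)
    valid_flat = bioclim.valid.ravel()
    pres_cells = pres_cells[valid_flat[pres_cells]]
    if pres_cells.size < max(2, folds):
        raise ValueError(f"{occ.species_id}: too few presence cells on valid predictors")
    elig = eligible_cells(occ, zones)
    elig = elig[valid_flat[elig]]
    bg = sample_background(elig, n_background, seed, grid, occ.species_id, zones)

    pr, pc = np.divmod(pres_cells, grid.cols)
    br, bc = np.divmod(bg.points["cell_index"].to_numpy(), grid.cols)
    X_pres = bioclim.matrix(pr, pc)
    X_bg = bioclim.matrix(br, bc)
    fs, F_pres, F_bg = build_features(X_pres, X_bg)
    model = fit(
        fs,
        F_pres,
        F_bg,
        beta_multiplier=beta_multiplier,
        training_meta={"species_id": occ.species_id, "seed": seed},
    )
    cv_aucs = []
    for fold_model, test_idx in cross_validate(
        fs, F_pres, F_bg, k=folds, seed=seed, beta_multiplier=beta_multiplier
    ):
        cv_aucs.append(
            auc_score(fold_model.scores(F_pres[test_idx]), fold_model.scores(F_bg))
        )
    return model, fs, F_pres, F_bg, float(np.mean(cv_aucs)), bg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    species_gates: dict
    excluded_species: list
    warnings: list
    checksums: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all stage outputs to outdir."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # stage 1: world + inputs
    world = generate_climate(config.world)
    bioclim_now = world.bioclim
    regions, zones = generate_regions(world, config.n_regions, seed=config.seed)

    # stage 2: occurrences (generate, contaminate, clean, filter)
    raw_sets = {}
    for i, sspec in enumerate(config.species):
        occ, _ = generate_species(world, sspec, seed=config.seed + 1000 + i)
        raw_sets[sspec.species_id] = occ
    cleaned = {
        sid: clean_pipeline(occ, cell_km=config.dedupe_cell_km, seed=config.seed)
        for sid, occ in raw_sets.items()
    }
    passed_sets, failed_sets = min_records_filter(list(cleaned.values()), config.min_records)
    excluded = [s.species_id for s in failed_sets]
    for s in failed_sets:
        warnings.append(f"{s.species_id}: below the {config.min_records}-record minimum")
    cleaning_report(list(cleaned.values())).to_csv(
        outdir / "cleaning_report.tsv", sep="\t", index=False
    )

    # stage 3: future predictor stacks per scenario x GCM (consensus later)
    future_bioclim: dict[str, list[BioclimStack]] = {}
    for s_i, sc in enumerate(config.scenarios):
        stacks = generate_anomalies(
            world,
            config.n_gcms,
            warming_mean=sc.warming_mean,
            warming_sd=sc.warming_sd,
            precip_factor=sc.precip_factor,
            coarsen_factor=config.coarsen_factor,
            seed=config.seed + 5000 + s_i,
            rcp_id=sc.rcp_id,
            period=sc.period,
        )
        per_gcm = []
        for st in stacks:
            fine = downscale_anomaly(st, world.grid)
            future_monthly = apply_anomaly(world.climate, fine)
            per_gcm.append(derive_bioclim(future_monthly, world.tcf))
        future_bioclim[sc.tag] = per_gcm

    # stage 4: per-species models, gates, projections
    gates = {}
    current_masks = []
    future_masks: dict[str, list] = {sc.tag: [] for sc in config.scenarios}
    eval_rows = []
    for i, occ in enumerate(passed_sets):
        sp_seed = config.seed + 2000 + i
        model, fs, F_pres, F_bg, cv_auc, bg = fit_species_sdm(
            bioclim_now,
            occ,
            zones,
            config.n_background,
            config.beta_multiplier,
            config.folds,
            sp_seed,
        )
        surf_now = predict(model, bioclim_now, scenario="current")
        pres_scores = model.logistic(F_pres)
        bg_scores = model.logistic(F_bg)
        report = evaluate(
            model,
            pres_scores,
            bg_scores,
            sensitivity=config.sensitivity,
            auc_gate=config.auc_gate,
            omission_gate=config.omission_gate,
            presence_raw_scores=model.scores(F_pres)
            / model.scores(np.vstack([F_pres, F_bg])).sum(),
        )
        gate_ok = cv_auc > config.auc_gate and report.omission_rate < config.omission_gate
        gates[occ.species_id] = {
            "auc_train": report.auc,
            "auc_cv": cv_auc,
            "omission_rate": report.omission_rate,
            "binomial_p": report.binomial_p,
            "threshold": report.threshold,
            "passed": bool(gate_ok),
        }
        eval_rows.append({"species": occ.species_id, **gates[occ.species_id]})
        if not gate_ok:
            excluded.append(occ.species_id)
            warnings.append(f"{occ.species_id}: failed accuracy gates")
            continue
        cur_mask = binarize(surf_now, pres_scores, config.sensitivity, scenario="current")
        current_masks.append(cur_mask)
        for sc in config.scenarios:
            per_gcm_surfaces = [
                predict(model, bc, scenario=f"{sc.tag}/{k}")
                for k, bc in enumerate(future_bioclim[sc.tag])
            ]
            consensus = consensus_surface(per_gcm_surfaces)
            consensus.scenario = sc.tag
            fut_mask = binarize(
                consensus, pres_scores, threshold=cur_mask.threshold, scenario=sc.tag
            )
            full, _none = dispersal_scenarios(cur_mask, fut_mask)
            future_masks[sc.tag].append(full)

    pd.DataFrame(eval_rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    # stage 5: hotspot stacking and summaries
    if not current_masks:
        raise RuntimeError("no species passed the accuracy gates; nothing to stack")
    summary = region_summary_table(
        current_masks,
        {tag: ms for tag, ms in future_masks.items() if ms},
        regions,
        percentile=config.percentile,
    )
    summary.to_csv(outdir / "hotspot_summary.tsv", sep="\t", index=False, float_format="%.6g")

    if config.write_rasters:
        from .grid import Raster, write_raster
        from .hotspots import hotspot_cutoff, hotspot_mask, percentile_bands, stack_richness

        rich_now = stack_richness(current_masks, "current")
        cut = hotspot_cutoff(rich_now, percentile=config.percentile)
        layers = {
            "richness_current": rich_now.counts,
            "hotspot_current": hotspot_mask(rich_now, cut).mask.astype(float),
            "bands_current": percentile_bands(rich_now, bands=config.bands).astype(float),
            "regions": regions.values,
            "zones": zones.values,
        }
        for tag, ms in future_masks.items():
            if ms:
                layers[f"richness_{tag}"] = stack_richness(ms, tag).counts
        write_raster(outdir / "surfaces.tif", layers, grid=world.grid)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.tsv"))
    }
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_json.encode()).hexdigest(),
        version=__version__,
        species_gates=gates,
        excluded_species=sorted(set(excluded)),
        warnings=warnings,
        checksums=checksums,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
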