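import numpy as np
import pytest
from scipy import ndimage, stats

from invasion_hotspots.climate import derive_bioclim
from invasion_hotspots.synth import (
    AP_BASE,
    AP_LON_GRADIENT,
    DIURNAL_RANGE,
    PREC_NOISE_AMP,
    PREC_SEASONAL,
    SEASONAL_AMP,
    TCF_BASE,
    TCF_NOISE_AMP,
    TEMP_NOISE_AMP,
    TMAX_BASE,
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    generate_anomalies,
    generate_climate,
    generate_regions,
    generate_species,
    true_suitability,
)


class TestGenerateClimate:
    def test_noise_free_temperature_is_exact(self):
        spec = SyntheticWorldSpec(grid_rows=10, grid_cols=10, noise_scale=0.0, seed=5)
        world = generate_climate(spec)
        _, lat = spec.grid.center_mesh()
        for m in range(12):
            base_m = TMAX_BASE + SEASONAL_AMP * np.cos(2 * np.pi * (m - 6) / 12)
            np.testing.assert_allclose(
                world.climate.tmax[m], base_m + spec.temp_gradient * lat, atol=1e-12
            )

    def test_same_seed_bit_identical(self):
        spec = SyntheticWorldSpec(grid_rows=12, grid_cols=15, seed=42)
        a, b = generate_climate(spec), generate_climate(spec)
        for name in ("tmax", "tmin", "prec"):
            np.testing.assert_array_equal(
                getattr(a.climate, name), getattr(b.climate, name)
            )
        np.testing.assert_array_equal(a.tcf.values, b.tcf.values)

    def test_layer_count_and_physical_bounds(self, world):
        c = world.climate
        assert c.tmax.shape[0] == c.tmin.shape[0] == c.prec.shape[0] == 12
        assert np.all(c.tmax >= c.tmin)
        assert np.all(c.prec >= 0)
        assert np.all((world.tcf.values >= 0) & (world.tcf.values <= 100))

    def test_mean_temperature_follows_latitude_gradient(self, world):
        # regression of zonal-mean MAT on latitude recovers temp_gradient
        mat = world.bioclim["MAT"].mean(axis=1)
        lat = world.grid.lat_centers()
        slope = np.polyfit(lat, mat, 1)[0]
        # the autocorrelated noise field (amp 2 °C over a 20° span) tilts
        # any single seed's regression; the trend itself must dominate
        assert slope == pytest.approx(world.spec.temp_gradient, abs=0.25)

    def test_generator_formula_oracle(self):
        """Cell-by-cell re-evaluation of the documented generator equations."""
        spec = SyntheticWorldSpec(grid_rows=20, grid_cols=20, noise_scale=2.0, seed=1)
        world = generate_climate(spec)
        # independently regenerate the three noise fields the same way
        rng = np.random.default_rng(spec.seed)
        fields = []
        for _ in range(3):
            w = rng.standard_normal(spec.grid.shape)
            sm = ndimage.gaussian_filter(w, sigma=spec.noise_scale, mode="reflect")
            fields.append(sm / sm.std())
        eps_t, eps_p, eps_c = fields
        grid = spec.grid
        for m in (0, 4, 11):
            for r in range(0, 20, 7):
                for c in range(0, 20, 7):
                    lat = grid.origin_lat - (r + 0.5) * grid.cell_size_deg
                    lon = grid.origin_lon + (c + 0.5) * grid.cell_size_deg
                    tmax = (
                        TMAX_BASE
                        + SEASONAL_AMP * np.cos(2 * np.pi * (m - 6) / 12)
                        + spec.temp_gradient * lat
                        + TEMP_NOISE_AMP * eps_t[r, c]
                    )
                    prec = max(
                        0.0,
                        (AP_BASE + AP_LON_GRADIENT * (lon - spec.origin_lon))
                        / 12.0
                        * (1 + PREC_SEASONAL * np.cos(2 * np.pi * m / 12))
                        * np.exp(PREC_NOISE_AMP * eps_p[r, c]),
                    )
                    assert world.climate.tmax[m, r, c] == pytest.approx(tmax, abs=1e-10)
                    assert world.climate.tmin[m, r, c] == pytest.approx(
                        tmax - DIURNAL_RANGE, abs=1e-10
                    )
                    assert world.climate.prec[m, r, c] == pytest.approx(prec, abs=1e-10)
        tcf = np.clip(TCF_BASE + TCF_NOISE_AMP * eps_c, 0, 100)
        np.testing.assert_allclose(world.tcf.values, tcf, atol=1e-10)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="4x4"):
            SyntheticWorldSpec(grid_rows=3, grid_cols=10)

    def test_land_mask_holes_propagate(self):
        spec = SyntheticWorldSpec(grid_rows=8, grid_cols=8, seed=0)
        mask = np.ones((8, 8), dtype=bool)
        mask[0, :3] = False
        world = generate_climate(spec, land_mask=mask)
        assert np.isnan(world.climate.tmax[:, 0, :3]).all()
        assert np.isfinite(world.climate.tmax[:, 4, 4]).all()


class TestGenerateSpecies:
    def test_clean_record_count_matches_request(self, world):
        spec = SyntheticSpeciesSpec("s", n_presences=50)
        occ, _ = generate_species(world, spec, seed=0)
        assert len(occ) == 50
        assert (occ.records["cultivated"] == 0).all()

    def test_contamination_counts(self, world):
        spec = SyntheticSpeciesSpec(
            "s", n_presences=100, cultivated_fraction=0.1, duplicate_fraction=0.2
        )
        occ, _ = generate_species(world, spec, seed=0)
        assert len(occ) == 100 + 20 + 10
        assert int(occ.records["cultivated"].sum()) == 10
        assert (occ.records["source"] == "synthetic_duplicate").sum() == 20

    def test_clean_presences_in_positive_suitability_cells(self, species_data, world):
        occ, suit = species_data
        clean = occ.records[occ.records["source"] == "synthetic"]
        row, col = world.grid.cell_of(clean["lon"].to_numpy(), clean["lat"].to_numpy())
        assert np.all(suit.values[row, col] > 0)

    def test_presence_density_tracks_suitability(self):
        world = generate_climate(SyntheticWorldSpec(grid_rows=80, grid_cols=80, seed=9))
        # a concentrated niche keeps per-cell expected counts well above the
        # Poisson noise floor, so density can actually converge at n=5000
        spec = SyntheticSpeciesSpec("s", n_presences=5000, niche_breadth=(1.5, 120.0))
        occ, suit = generate_species(world, spec, seed=42)
        row, col = world.grid.cell_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy()
        )
        counts = np.zeros(world.grid.shape)
        np.add.at(counts, (row, col), 1)
        s = np.nan_to_num(suit.values)
        r = np.corrcoef(counts.ravel(), s.ravel() / s.sum())[0, 1]
        assert r >= 0.95

    def test_infinite_breadth_is_uniform(self):
        # enormous niche breadth -> suitability ~ constant -> uniform sampling
        world = generate_climate(SyntheticWorldSpec(grid_rows=60, grid_cols=60, seed=9))
        spec = SyntheticSpeciesSpec(
            "s", n_presences=2000, niche_breadth=(1e9, 1e12)
        )
        occ, _ = generate_species(world, spec, seed=42)
        row, col = world.grid.cell_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy()
        )
        counts = np.zeros(world.grid.n_cells)
        np.add.at(counts, world.grid.flat_index(row, col), 1)
        # chi-square against the uniform expectation, binned to keep cells > 5
        binned = counts.reshape(-1, 8).sum(axis=1)
        p = stats.chisquare(binned).pvalue
        assert p > 0.01

    def test_oversubscribed_world_errors_with_shortfall(self, small_world):
        spec = SyntheticSpeciesSpec("s", n_presences=100_000)
        with pytest.raises(ValueError, match="short by"):
            generate_species(small_world, spec, seed=0)

    def test_bias_region_oversamples(self, world):
        box = (118.0, 30.0, 124.0, 40.0)
        spec = SyntheticSpeciesSpec(
            "s", n_presences=400, bias_region=box, bias_multiplier=3.0
        )
        occ, _ = generate_species(world, spec, seed=5)
        extra = occ.records["source"] == "synthetic_bias"
        assert extra.sum() > 0
        assert occ.records.loc[extra, "lon"].between(box[0], box[2]).all()
        assert occ.records.loc[extra, "lat"].between(box[1], box[3]).all()


class TestGenerateAnomalies:
    def test_deterministic_ensemble_when_sd_zero(self, small_world):
        stacks = generate_anomalies(
            small_world, 3, warming_mean=2.0, warming_sd=0.0, precip_factor=1.0, seed=0
        )
        for st in stacks:
            np.testing.assert_array_equal(st.dtemp, np.full_like(st.dtemp, 2.0))
            np.testing.assert_array_equal(st.dprec, np.ones_like(st.dprec))

    def test_seven_model_ensemble(self, small_world):
        stacks = generate_anomalies(small_world, 7, seed=1)
        assert len(stacks) == 7
        assert len({s.gcm_id for s in stacks}) == 7

    def test_ensemble_mean_near_warming_mean(self, small_world):
        warming_sd = 0.5
        stacks = generate_anomalies(
            small_world, 7, warming_mean=2.0, warming_sd=warming_sd, coarsen_factor=2, seed=0
        )
        vals = np.concatenate([s.dtemp[0].ravel() for s in stacks])
        # smoothing with a sigma=1 Gaussian kernel leaves ~4*pi correlated
        # cells per sample; SE of the mean scales accordingly
        se = warming_sd * np.sqrt(4 * np.pi / vals.size)
        assert abs(vals.mean() - 2.0) <= 3 * se

    def test_invalid_ensemble_size_rejected(self, small_world):
        with pytest.raises(ValueError):
            generate_anomalies(small_world, 0, seed=0)


class TestGenerateRegions:
    def test_single_region_covers_land(self, small_world):
        region, _ = generate_regions(small_world, 1, seed=0)
        land = small_world.land_mask
        assert np.all(region.values[land] == 0)

    def test_partition_tiles_the_land(self, world):
        region, _ = generate_regions(world, 9, seed=2)
        land = world.land_mask
        labels = region.values[land]
        assert np.all(np.isfinite(labels))
        assert set(np.unique(labels).astype(int)) == set(range(9))
        assert np.isnan(region.values[~land]).all()

    def test_thirty_seven_regions(self, world):
        region, _ = generate_regions(world, 37, seed=0)
        assert len(np.unique(region.values[world.land_mask])) == 37

    def test_regions_contiguous(self, world):
        region, _ = generate_regions(world, 6, seed=4)
        for lab in range(6):
            mask = region.values == lab
            n_comp = ndimage.label(mask)[1]
            assert n_comp == 1

    def test_zone_raster_has_discrete_classes(self, world):
        _, zone = generate_regions(world, 4, seed=0, mat_bins=3, ap_bins=2)
        vals = zone.values[world.land_mask]
        assert set(np.unique(vals)).issubset(set(range(6)))
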