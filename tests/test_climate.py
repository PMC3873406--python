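import numpy as np
import pytest

from invasion_hotspots.climate import (
    AnomalyStack,
    MonthlyClimateStack,
    apply_anomaly,
    derive_bioclim,
    downscale_anomaly,
    downscale_field,
)
from invasion_hotspots.grid import GridSpec, Raster


def constant_stack(grid, tmax=25.0, tmin=15.0, prec=50.0):
    shape = (12, *grid.shape)
    return MonthlyClimateStack(
        grid, np.full(shape, tmax), np.full(shape, tmin), np.full(shape, prec)
    )


@pytest.fixture
def grid():
    return GridSpec(8, 8, 0.0, 4.0, 0.5)


class TestDeriveBioclim:
    def test_constant_climate(self, grid):
        bc = derive_bioclim(constant_stack(grid), Raster(grid, np.full(grid.shape, 30.0)))
        assert np.all(bc["MAT"] == 20.0)
        assert np.all(bc["MTWM"] == 25.0)
        assert np.all(bc["MTCM"] == 15.0)
        assert np.all(bc["AP"] == 600.0)
        assert np.all(bc["PS"] == 0.0)
        assert np.all(bc["TCF"] == 30.0)

    def test_single_wet_month_seasonality(self, grid):
        stack = constant_stack(grid, prec=0.0)
        stack.prec[11] = 120.0
        bc = derive_bioclim(stack, Raster(grid, np.zeros(grid.shape)))
        # hand arithmetic: monthly [0]*11+[120]; mean 10; pop SD = sqrt(
        # (11*100 + 110^2)/12 ) = sqrt(1100/12*...) computed explicitly:
        months = np.array([0.0] * 11 + [120.0])
        expected_ps = 100 * months.std() / (1 + months.mean())
        assert np.all(bc["AP"] == 120.0)
        np.testing.assert_allclose(bc["PS"], expected_ps)

    def test_matches_per_cell_loop_oracle(self, small_world):
        bc = small_world.bioclim
        c = small_world.climate
        rng = np.random.default_rng(0)
        for r, col in zip(rng.integers(0, 20, 15), rng.integers(0, 20, 15)):
            tmax = [c.tmax[m, r, col] for m in range(12)]
            tmin = [c.tmin[m, r, col] for m in range(12)]
            prec = [c.prec[m, r, col] for m in range(12)]
            tmean = [(a + b) / 2 for a, b in zip(tmax, tmin)]
            assert bc["MAT"][r, col] == pytest.approx(sum(tmean) / 12, abs=1e-10)
            assert bc["MTWM"][r, col] == pytest.approx(max(tmax), abs=1e-10)
            assert bc["MTCM"][r, col] == pytest.approx(min(tmin), abs=1e-10)
            assert bc["AP"][r, col] == pytest.approx(sum(prec), abs=1e-9)
            mean_p = sum(prec) / 12
            sd_p = (sum((p - mean_p) ** 2 for p in prec) / 12) ** 0.5
            assert bc["PS"][r, col] == pytest.approx(100 * sd_p / (1 + mean_p), abs=1e-9)

    def test_ordering_invariant(self, world):
        bc = world.bioclim
        valid = bc.valid
        assert np.all(bc["MTCM"][valid] <= bc["MAT"][valid])
        assert np.all(bc["MAT"][valid] <= bc["MTWM"][valid])

    def test_nodata_propagates(self, grid):
        stack = constant_stack(grid)
        stack.tmax[3, 2, 2] = np.nan
        bc = derive_bioclim(stack, Raster(grid, np.zeros(grid.shape)))
        assert np.isnan(bc["MAT"][2, 2]) and np.isnan(bc["MTWM"][2, 2])

    def test_misaligned_tcf_rejected(self, grid):
        other = GridSpec(8, 8, 1.0, 4.0, 0.5)
        with pytest.raises(ValueError, match="TCF"):
            derive_bioclim(constant_stack(grid), Raster(other, np.zeros(other.shape)))


class TestDownscale:
    def setup_method(self):
        self.fine = GridSpec(16, 16, 0.0, 8.0, 0.5)
        self.coarse = self.fine.coarsen(4)

    def test_constant_field_reproduced(self):
        out = downscale_field(self.coarse, np.full(self.coarse.shape, 2.5), self.fine)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_linear_ramp_on_plane(self):
        lon, lat = self.coarse.center_mesh()
        plane = 0.3 * lon - 0.7 * lat + 1.0
        out = downscale_field(self.coarse, plane, self.fine)
        flon, flat = self.fine.center_mesh()
        np.testing.assert_allclose(out, 0.3 * flon - 0.7 * flat + 1.0, atol=1e-6)

    def test_exact_at_coarse_centers(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=self.coarse.shape)
        out = downscale_field(self.coarse, vals, self.coarse)
        np.testing.assert_allclose(out, vals, atol=1e-9)

    def test_matches_dense_spline_oracle(self):
        # independent tensor-product construction: 1-D not-a-knot cubic
        # splines along latitude for every coarse column, then along
        # longitude for every fine row
        from scipy.interpolate import CubicSpline

        rng = np.random.default_rng(2)
        vals = rng.normal(size=self.coarse.shape)
        out = downscale_field(self.coarse, vals, self.fine)
        clats = self.coarse.lat_centers()[::-1]
        clons = self.coarse.lon_centers()
        flats = self.fine.lat_centers()
        flons = self.fine.lon_centers()
        stage1 = np.empty((len(flats), len(clons)))
        for j in range(len(clons)):
            stage1[:, j] = CubicSpline(clats, vals[::-1, j], extrapolate=True)(flats)
        expected = np.empty((len(flats), len(flons)))
        for i in range(len(flats)):
            expected[i, :] = CubicSpline(clons, stage1[i, :], extrapolate=True)(flons)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_small_grid_falls_back_to_bilinear(self, caplog):
        tiny = GridSpec(3, 3, 0.0, 3.0, 1.0)
        fine = GridSpec(6, 6, 0.0, 3.0, 0.5)
        lon, lat = tiny.center_mesh()
        with caplog.at_level("WARNING"):
            out = downscale_field(tiny, lon + lat, fine)
        assert "bilinear" in caplog.text
        flon, flat = fine.center_mesh()
        np.testing.assert_allclose(out, flon + flat, atol=1e-9)


class TestApplyAnomaly:
    def test_zero_anomaly_is_identity(self, grid):
        base = constant_stack(grid)
        anom = AnomalyStack(
            grid, np.zeros((12, *grid.shape)), np.zeros((12, *grid.shape))
        )
        fut = apply_anomaly(base, anom)
        np.testing.assert_array_equal(fut.tmax, base.tmax)
        np.testing.assert_array_equal(fut.prec, base.prec)
        bc0 = derive_bioclim(base, Raster(grid, np.zeros(grid.shape)))
        bc1 = derive_bioclim(fut, Raster(grid, np.zeros(grid.shape)))
        for name in ("MAT", "MTWM", "MTCM", "AP", "PS"):
            np.testing.assert_array_equal(bc0[name], bc1[name])

    def test_uniform_warming_shifts_mat(self, small_world):
        grid = small_world.grid
        anom = AnomalyStack(
            grid, np.full((12, *grid.shape), 2.0), np.zeros((12, *grid.shape))
        )
        fut = apply_anomaly(small_world.climate, anom)
        bc0 = small_world.bioclim
        bc1 = derive_bioclim(fut, small_world.tcf)
        np.testing.assert_allclose(bc1["MAT"] - bc0["MAT"], 2.0, atol=1e-9)

    def test_negative_precip_clamped_and_logged(self, grid):
        base = constant_stack(grid, prec=10.0)
        dprec = np.zeros((12, *grid.shape))
        dprec[0, 0, 0] = -50.0  # drives one cell-month negative
        fut = apply_anomaly(base, AnomalyStack(grid, np.zeros_like(dprec), dprec))
        assert fut.prec[0, 0, 0] == 0.0
        assert fut.clamp_log["prec_cells_clamped"] == 1

    def test_multiplicative_mode(self, grid):
        base = constant_stack(grid, prec=10.0)
        fac = np.full((12, *grid.shape), 0.8)
        fut = apply_anomaly(
            base, AnomalyStack(grid, np.zeros_like(fac), fac, prec_mode="multiplicative")
        )
        np.testing.assert_allclose(fut.prec, 8.0)

    def test_downscale_anomaly_stack_roundtrip(self, small_world):
        from invasion_hotspots.synth import generate_anomalies

        st = generate_anomalies(small_world, 1, warming_mean=1.5, warming_sd=0.0, seed=0)[0]
        fine = downscale_anomaly(st, small_world.grid)
        np.testing.assert_allclose(fine.dtemp, 1.5, atol=1e-9)
        assert fine.prec_mode == "multiplicative"
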