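"""Bioclimatic predictors and climate-anomaly downscaling.

Six predictor layers drive the niche models:

======  ==============================================  =====
name    definition                                      units
======  ==============================================  =====
MAT     annual mean of monthly mean temperature,        °C
        monthly mean = (tmax + tmin) / 2
MTWM    max over months of monthly tmax                 °C
MTCM    min over months of monthly tmin                 °C
AP      sum of monthly precipitation                    mm
PS      precipitation seasonality,                      —
        100 * SD(monthly prec) / (1 + mean(monthly prec))
        (population SD; the +1 guards arid cells)
TCF     topsoil clay fraction, passed through           % wt
======  ==============================================  =====

Future predictor stacks are built by the anomaly method: coarse-grid
(future − baseline) deltas from each climate model are interpolated onto
the fine baseline grid with a bivariate cubic spline through coarse cell
centres, then added to (temperature) or multiplied into (precipitation)
the fine-scale baseline.  The spline interpolates exactly, so a constant
or linear anomaly field is reproduced without distortion; the soil layer
is held fixed across scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid import GridSpec, Raster, require_aligned

logger = logging.getLogger(__name__)

BIOCLIM_NAMES = ("MAT", "MTWM", "MTCM", "AP", "PS", "TCF")


@dataclass
class MonthlyClimateStack:
    """12 x tmax, 12 x tmin, 12 x prec on a common grid (°C, °C, mm)."""

    grid: GridSpec
    tmax: np.ndarray  # (12, rows, cols)
    tmin: np.ndarray
    prec: np.ndarray
    clamp_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.grid.shape):
                raise ValueError(f"{name} must have shape (12, rows, cols)")
            setattr(self, name, arr)
        both = np.isfinite(self.tmax) & np.isfinite(self.tmin)
        if np.any(self.tmax[both] < self.tmin[both] - 1e-9):
            raise ValueError("tmax < tmin on some valid cells")


@dataclass
class BioclimStack:
    """The six aligned predictor layers."""

    grid: GridSpec
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in BIOCLIM_NAMES if n not in self.layers]
        if missing:
            raise ValueError(f"missing predictor layer(s): {', '.join(missing)}")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name} is not aligned with the grid")
            self.layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def valid(self) -> np.ndarray:
        v = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            v &= np.isfinite(arr)
        return v

    def matrix(self, rows, cols) -> np.ndarray:
        """(n, 6) predictor matrix at the given cells, column order BIOCLIM_NAMES."""
        return np.column_stack([self.layers[n][rows, cols] for n in BIOCLIM_NAMES])


@dataclass
class AnomalyStack:
    """Coarse-grid monthly anomalies for one climate model and scenario.

    ``dtemp`` is additive (°C).  ``dprec`` is either additive (mm) or a
    multiplicative factor (1.0 = no change) according to ``prec_mode``.
    """

    grid: GridSpec
    dtemp: np.ndarray  # (12, rows, cols)
    dprec: np.ndarray
    gcm_id: str = ""
    rcp_id: str = ""
    period: str = ""
    prec_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.prec_mode not in ("additive", "multiplicative"):
            raise ValueError("prec_mode must be 'additive' or 'multiplicative'")
        for name in ("dtemp", "dprec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.grid.shape):
                raise ValueError(f"{name} must have shape (12, rows, cols)")
            setattr(self, name, arr)


def derive_bioclim(monthly: MonthlyClimateStack, tcf: Raster) -> BioclimStack:
    """Collapse a monthly stack + soil layer into the six predictors.

    NaN in any month propagates to the derived cell; grids must match.
    """
    if not monthly.grid.compatible(tcf.grid):
        raise ValueError("grid mismatch: TCF is not aligned with the monthly climate")
    tmean = (monthly.tmax + monthly.tmin) / 2.0
    prec = monthly.prec
    mean_prec = prec.mean(axis=0)
    ps = 100.0 * prec.std(axis=0, ddof=0) / (1.0 + mean_prec)
    layers = {
        "MAT": tmean.mean(axis=0),
        "MTWM": monthly.tmax.max(axis=0),
        "MTCM": monthly.tmin.min(axis=0),
        "AP": prec.sum(axis=0),
        "PS": ps,
        "TCF": tcf.values.copy(),
    }
    return BioclimStack(monthly.grid, layers)


def downscale_field(coarse_grid: GridSpec, coarse_values: np.ndarray, fine_grid: GridSpec) -> np.ndarray:
    """Interpolate one coarse field onto fine cell centres.

    Tensor-product (not-a-knot) bicubic spline through the coarse
    cell-centre values — exact at those centres, exact on constant and
    linear fields; fine centres outside the coarse centre envelope take
    the spline's natural extrapolation.  Grids with fewer than 4 coarse
    cells on an axis fall back to bilinear with a logged warning.
    """
    coarse_values = np.asarray(coarse_values, dtype=float)
    if coarse_values.shape != coarse_grid.shape:
        raise ValueError("coarse values do not match the coarse grid")
    method = "cubic"
    if coarse_grid.rows < 4 or coarse_grid.cols < 4:
        logger.warning(
            "coarse grid %s too small for cubic spline; using bilinear", coarse_grid.shape
        )
        method = "linear"
        if coarse_grid.rows < 2 or coarse_grid.cols < 2:
            # single row/col: the field is constant along the missing axis
            return np.full(fine_grid.shape, float(np.nanmean(coarse_values)))
    # latitude axis descends with row index; the interpolator wants it ascending
    lats = coarse_grid.lat_centers()[::-1]
    lons = coarse_grid.lon_centers()
    interp = RegularGridInterpolator(
        (lats, lons), coarse_values[::-1, :], method=method, bounds_error=False, fill_value=None
    )
    flon, flat = fine_grid.center_mesh()
    fine = interp(np.stack([flat.ravel(), flon.ravel()], axis=1)).reshape(fine_grid.shape)
    return fine


def downscale_anomaly(coarse: AnomalyStack, fine_grid: GridSpec) -> AnomalyStack:
    """Downscale all 24 monthly anomaly layers onto the fine grid."""
    dtemp = np.stack(
        [downscale_field(coarse.grid, coarse.dtemp[m], fine_grid) for m in range(12)]
    )
    dprec = np.stack(
        [downscale_field(coarse.grid, coarse.dprec[m], fine_grid) for m in range(12)]
    )
    return AnomalyStack(
        fine_grid,
        dtemp,
        dprec,
        gcm_id=coarse.gcm_id,
        rcp_id=coarse.rcp_id,
        period=coarse.period,
        prec_mode=coarse.prec_mode,
    )


def apply_anomaly(baseline: MonthlyClimateStack, anomaly: AnomalyStack) -> MonthlyClimateStack:
    """Perturb a baseline monthly stack into a future one.

    Temperatures shift additively.  Precipitation is offset (additive
    mode, clamped at zero with the clamped-cell count logged) or scaled
    (multiplicative mode, negative factors clamped to zero).
    """
    if not baseline.grid.compatible(anomaly.grid):
        raise ValueError("grid mismatch: anomaly stack is not aligned with the baseline")
    tmax = baseline.tmax + anomaly.dtemp
    tmin = baseline.tmin + anomaly.dtemp
    if anomaly.prec_mode == "multiplicative":
        prec = baseline.prec * np.maximum(anomaly.dprec, 0.0)
        n_clamped = int(np.sum((anomaly.dprec < 0) & np.isfinite(baseline.prec)))
    else:
        raw = baseline.prec + anomaly.dprec
        n_clamped = int(np.sum((raw < 0) & np.isfinite(raw)))
        prec = np.maximum(raw, 0.0)
    future = MonthlyClimateStack(baseline.grid, tmax, tmin, prec)
    future.clamp_log["prec_cells_clamped"] = n_clamped
    if n_clamped:
        logger.info("precipitation clamped at zero in %d cell-months", n_clamped)
    return future
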