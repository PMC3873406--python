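"""Regular lon/lat grids and raster containers.

All rasters in this package live on a :class:`GridSpec` — a regular
geographic grid indexed from the top-left corner, rows increasing
southwards (half-open row/col indexing, cell-centre coordinate
convention).  Missing data is NaN in memory and the ``nodata`` sentinel
(-9999 by default) on disk.

Raster I/O uses plain float32 TIFF (one band per layer) written with
:mod:`tifffile`; the georeferencing (origin, cell size, nodata, band
names) travels in a JSON document stored in the TIFF ImageDescription
tag, so a raster round-trips from a single file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Authalic (equal-area) sphere radius in km.
EARTH_RADIUS_KM = 6371.0072

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon``/``origin_lat`` are the coordinates of the *top-left
    corner* of the top-left cell; latitude decreases with row index.
    """

    rows: int
    cols: int
    origin_lon: float
    origin_lat: float
    cell_size_deg: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    # -- coordinate transforms -------------------------------------------------

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.cols) + 0.5) * self.cell_size_deg

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.rows) + 0.5) * self.cell_size_deg

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of cell-centre coordinates."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (floor rule).

        Points outside the grid get indices outside ``[0, rows) x [0, cols)``;
        callers decide whether that is an error.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size_deg).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size_deg).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)

    def flat_index(self, row, col) -> np.ndarray:
        return np.asarray(row) * self.cols + np.asarray(col)

    # -- geometry --------------------------------------------------------------

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row geodesic cell areas, broadcast to the full grid.

        Spherical-strip formula on the authalic sphere:
        ``A = R^2 * dlon * (sin(lat_top) - sin(lat_bottom))``.
        Cells shrink towards the poles.
        """
        lat_top = np.deg2rad(self.origin_lat - np.arange(self.rows) * self.cell_size_deg)
        lat_bot = np.deg2rad(
            self.origin_lat - (np.arange(self.rows) + 1) * self.cell_size_deg
        )
        dlon = math.radians(self.cell_size_deg)
        strip = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
        return np.repeat(strip[:, None], self.cols, axis=1)

    def compatible(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
            and math.isclose(self.cell_size_deg, other.cell_size_deg, rel_tol=1e-12)
        )

    def coarsen(self, factor: int) -> "GridSpec":
        """Coarse grid whose cells aggregate ``factor`` x ``factor`` fine cells.

        Edge cells are padded: the coarse grid always covers the fine extent.
        """
        if factor < 1:
            raise ValueError("coarsen factor must be >= 1")
        rows = -(-self.rows // factor)
        cols = -(-self.cols // factor)
        return replace(
            self, rows=rows, cols=cols, cell_size_deg=self.cell_size_deg * factor
        )


@dataclass
class Raster:
    """A single 2-D layer on a :class:`GridSpec`; missing cells are NaN."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster {self.name!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.name)


def require_aligned(*layers, names: list[str] | None = None) -> None:
    """Raise with the offending layer named when grids disagree."""
    ref = layers[0].grid
    for i, layer in enumerate(layers[1:], start=1):
        if not ref.compatible(layer.grid):
            label = names[i] if names else getattr(layer, "name", "") or f"layer {i}"
            raise ValueError(f"grid mismatch: {label} is not aligned with {names[0] if names else 'the first layer'}")


# -- TIFF I/O ------------------------------------------------------------------


def _grid_meta(grid: GridSpec, band_names: list[str]) -> str:
    return json.dumps(
        {
            "origin_lon": grid.origin_lon,
            "origin_lat": grid.origin_lat,
            "cell_size_deg": grid.cell_size_deg,
            "nodata": grid.nodata,
            "bands": band_names,
        }
    )


def write_raster(path, layers, grid: GridSpec | None = None) -> None:
    """Write one or more layers to a float32 multi-band TIFF.

    ``layers`` may be a Raster, a list of Rasters, or a dict name -> 2-D array
    (``grid`` required in the dict case).  NaN becomes the grid nodata value.
    """
    if isinstance(layers, Raster):
        layers = [layers]
    if isinstance(layers, dict):
        if grid is None:
            raise ValueError("grid required when passing arrays")
        names = list(layers)
        arrays = [np.asarray(layers[n], dtype=float) for n in names]
    else:
        grid = layers[0].grid
        names = [r.name for r in layers]
        arrays = [r.values for r in layers]
    stack = np.stack(arrays).astype(np.float32)
    stack = np.where(np.isfinite(stack), stack, np.float32(grid.nodata))
    tifffile.imwrite(path, stack, description=_grid_meta(grid, names))


def read_raster(path) -> dict[str, Raster]:
    """Read a TIFF written by :func:`write_raster`; returns name -> Raster."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if stack.ndim == 2:
        stack = stack[None]
    grid = GridSpec(
        rows=stack.shape[1],
        cols=stack.shape[2],
        origin_lon=meta["origin_lon"],
        origin_lat=meta["origin_lat"],
        cell_size_deg=meta["cell_size_deg"],
        nodata=meta["nodata"],
    )
    out: dict[str, Raster] = {}
    for name, band in zip(meta["bands"], stack):
        vals = band.astype(float)
        vals[vals == grid.nodata] = np.nan
        out[name] = Raster(grid, vals, name)
    return out
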