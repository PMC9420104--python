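"""Geographic grid geometry, spherical pixel areas and block aggregation.

All layers in the pipeline live on a shared corner-registered, north-up
lat/lon grid.  Pixel areas are computed on a sphere of mean radius
``EARTH_RADIUS_KM`` and are constant along a row, so a full area raster is
stored as one value per latitude band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: IUGG mean Earth radius in km.  The spherical model is exact for the area
#: formula used here; switching to an authalic radius shifts global totals
#: by well under 0.1%.
EARTH_RADIUS_KM = 6371.0088

#: Sentinel for missing values in integer layers (suitability, land cover,
#: zones).  Fraction layers use NaN.
NODATA_INT = -1


@dataclass(frozen=True)
class GridSpec:
    """Corner-registered, north-up geographic grid.

    Parameters
    ----------
    lon_min, lat_max : float
        Degrees of the north-west corner of the grid (cell edges, not
        centres).
    n_rows, n_cols : int
        Raster shape; row 0 is the northernmost band.
    resolution : float
        Pixel edge length in arc-seconds (square pixels).
    """

    lon_min: float
    lat_max: float
    n_rows: int
    n_cols: int
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.lat_max > 90.0 + 1e-9:
            raise ValueError("grid extends beyond the north pole")
        if self.lat_min < -90.0 - 1e-9:
            raise ValueError("grid extends beyond the south pole")
        if self.n_cols * self.res_deg > 360.0 + 1e-9:
            raise ValueError("longitude span exceeds 360 degrees")

    @property
    def res_deg(self) -> float:
        """Pixel edge length in degrees."""
        return self.resolution / 3600.0

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.n_rows * self.res_deg

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.res_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_edges(self) -> np.ndarray:
        """Northern edge of each row plus the final southern edge
        (``n_rows + 1`` values, decreasing)."""
        return self.lat_max - np.arange(self.n_rows + 1) * self.res_deg

    def cell_center_lats(self) -> np.ndarray:
        edges = self.lat_edges()
        return 0.5 * (edges[:-1] + edges[1:])

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid of the same extent with ``factor`` x ``factor`` pixel blocks
        merged into one."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"factor {factor} does not divide grid shape {self.shape}"
            )
        return GridSpec(
            lon_min=self.lon_min,
            lat_max=self.lat_max,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            resolution=self.resolution * factor,
        )

    @staticmethod
    def global_grid(resolution: float) -> "GridSpec":
        """Whole-sphere grid at ``resolution`` arc-seconds."""
        res_deg = resolution / 3600.0
        n_rows = round(180.0 / res_deg)
        n_cols = round(360.0 / res_deg)
        return GridSpec(-180.0, 90.0, n_rows, n_cols, resolution)


def check_same_grid(a: GridSpec, b: GridSpec) -> None:
    """Layers are combinable only on identical grids."""
    if a != b:
        raise ValueError(f"grid mismatch: {a} vs {b}")


def pixel_area(
    lat_north: float,
    lat_south: float,
    dlon: float,
    radius: float = EARTH_RADIUS_KM,
) -> float:
    """Area in km^2 of the spherical quadrangle bounded by two parallels and
    a longitude span.

    Exact on the sphere: ``R^2 * dlon_rad * (sin(lat_N) - sin(lat_S))``.
    """
    if not (-90.0 - 1e-12 <= lat_south <= lat_north <= 90.0 + 1e-12):
        raise ValueError(
            f"latitudes must satisfy -90 <= south <= north <= 90, "
            f"got south={lat_south}, north={lat_north}"
        )
    if dlon <= 0:
        raise ValueError("dlon must be positive")
    return (
        radius * radius
        * math.radians(dlon)
        * (math.sin(math.radians(lat_north)) - math.sin(math.radians(lat_south)))
    )


@dataclass
class AreaRaster:
    """Per-pixel true spherical areas (km^2), stored per latitude row."""

    grid: GridSpec
    row_areas: np.ndarray  # shape (n_rows,)
    radius: float = EARTH_RADIUS_KM

    def expand(self) -> np.ndarray:
        """Full (n_rows, n_cols) array of pixel areas."""
        return np.broadcast_to(
            self.row_areas[:, None], self.grid.shape
        ).copy()

    @property
    def total(self) -> float:
        return float(self.row_areas.sum() * self.grid.n_cols)


def build_area_raster(
    grid: GridSpec, radius: float = EARTH_RADIUS_KM
) -> AreaRaster:
    """Compute the per-row pixel area for every latitude band of ``grid``."""
    edges = grid.lat_edges()
    if edges[0] > 90.0 + 1e-9 or edges[-1] < -90.0 - 1e-9:
        raise ValueError("grid extends beyond the poles")
    north = np.radians(edges[:-1])
    south = np.radians(edges[1:])
    dlon = math.radians(grid.res_deg)
    areas = radius * radius * dlon * (np.sin(north) - np.sin(south))
    return AreaRaster(grid=grid, row_areas=areas, radius=radius)


def _block_view(values: np.ndarray, factor: int) -> np.ndarray:
    """Reshape (R, C) into (R/f, f, C/f, f) blocks."""
    r, c = values.shape
    if r % factor or c % factor:
        raise ValueError(
            f"factor {factor} does not divide layer shape {values.shape}"
        )
    return values.reshape(r // factor, factor, c // factor, factor)


def aggregate_fraction(
    values: np.ndarray,
    grid: GridSpec,
    factor: int,
) -> tuple[np.ndarray, GridSpec]:
    """Aggregate a fraction layer (values in [0, 1], NaN = nodata) by the
    area-weighted mean of non-nodata subcells.

    Conserves fraction-weighted area: sum(fine * fine_area) over non-nodata
    subcells equals sum(coarse * coarse_nonnodata_area).  An all-nodata block
    yields NaN.
    """
    coarse_grid = grid.coarsen(factor)
    if factor == 1:
        return values.astype(float, copy=True), coarse_grid
    vals = values.astype(float)
    finite = np.isfinite(vals)
    if np.any((vals[finite] < 0) | (vals[finite] > 1)):
        raise ValueError("fraction values must lie in [0, 1]")
    area = build_area_raster(grid).expand()
    w = np.where(finite, area, 0.0)
    num = _block_view(np.where(finite, vals, 0.0) * area, factor).sum(axis=(1, 3))
    den = _block_view(w, factor).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        coarse = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return coarse, coarse_grid


def aggregate_categorical(
    values: np.ndarray,
    grid: GridSpec,
    factor: int,
    nodata: int = NODATA_INT,
) -> tuple[np.ndarray, GridSpec]:
    """Aggregate a categorical layer by the modal class weighted by subcell
    area; ties break to the lowest class code.  All-nodata blocks stay
    nodata; the mode never invents a class absent from the block.
    """
    coarse_grid = grid.coarsen(factor)
    if factor == 1:
        return values.copy(), coarse_grid
    area = build_area_raster(grid).expand()
    codes = np.unique(values[values != nodata])
    out = np.full(coarse_grid.shape, nodata, dtype=values.dtype)
    if codes.size == 0:
        return out, coarse_grid
    # accumulate per-block area of each code; argmax over ascending codes
    # implements the lowest-code tie-break
    best_area = np.zeros(coarse_grid.shape)
    for code in codes:
        w = _block_view(np.where(values == code, area, 0.0), factor).sum(
            axis=(1, 3)
        )
        take = w > best_area + 1e-12 * np.maximum(best_area, 1.0)
        # strictly-greater comparison keeps the earlier (lower) code on ties
        take &= w > 0
        out[take] = code
        best_area = np.where(take, w, best_area)
    return out, coarse_grid


def aggregate_area_sum(
    values: np.ndarray, grid: GridSpec, factor: int
) -> tuple[np.ndarray, GridSpec]:
    """Aggregate an additive km^2 layer by summing blocks (NaN treated as 0)."""
    coarse_grid = grid.coarsen(factor)
    if factor == 1:
        return values.astype(float, copy=True), coarse_grid
    vals = np.where(np.isfinite(values), values, 0.0)
    return _block_view(vals, factor).sum(axis=(1, 3)), coarse_grid
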