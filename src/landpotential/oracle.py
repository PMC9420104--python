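"""Independent per-pixel reference implementation.

Recomputes every pipeline product with literal Python loops over pixels —
regime selection, crop maximum, the exclusion hierarchy and zonal sums —
sharing no array code with the main modules, so it serves as an exact
oracle for them.  Pixel areas are rederived here from the spherical
closed form with :mod:`math` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import WorldBundle

_NODATA = -1
_WATER = 210
_SNOW = 220
_WETLAND = 180


@dataclass
class OracleParams:
    """Pipeline parameters the oracle re-reads independently."""

    earth_radius_km: float = 6371.0088
    protected_threshold: float = 0.5
    water_snow_codes: tuple[int, ...] = (_WATER, _SNOW)
    wetland_code: int = _WETLAND
    marginal_min: int = 1
    moderate_min: int = 33
    high_min: int = 75


_COMPONENTS = (
    "suitable_area",
    "excluded_water_snow",
    "excluded_impervious",
    "cultivable_area",
    "excluded_protected",
    "excluded_forest",
    "excluded_wetland",
    "available_area",
)


@dataclass
class TruthSlice:
    """Oracle outputs for one (period, scenario, crop_set)."""

    combined: np.ndarray  # int16 combined suitability
    ledger: dict[str, np.ndarray]  # component name -> km^2 raster
    country_totals: dict[int, dict[str, float]]
    global_totals: dict[str, float]
    class_area: dict[str, dict[str, float]]  # inventory -> class -> km^2
    already_cultivated: dict[str, float]  # inventory -> km^2


@dataclass
class TruthBundle:
    slices: dict[tuple[str, str, str], TruthSlice] = field(
        default_factory=dict
    )


def _row_areas_km2(grid, radius: float) -> list[float]:
    res = grid.resolution / 3600.0
    dlon = math.radians(res)
    areas = []
    for r in range(grid.n_rows):
        lat_n = grid.lat_max - r * res
        lat_s = lat_n - res
        areas.append(
            radius * radius * dlon
            * (math.sin(math.radians(lat_n)) - math.sin(math.radians(lat_s)))
        )
    return areas


def reference_oracle(
    world: WorldBundle, params: OracleParams | None = None
) -> TruthBundle:
    """Recompute combined suitability, ledgers and zonal totals for every
    scenario key and crop set of ``world`` with plain loops."""
    if params is None:
        params = OracleParams()
    grid = world.grid
    n_rows, n_cols = grid.shape
    row_area = _row_areas_km2(grid, params.earth_radius_km)

    landcover = world.surfaces.landcover.tolist()
    imperv = world.surfaces.impervious_frac.tolist()
    forest = world.surfaces.forest.tolist()
    cropflag = world.surfaces.cropland.tolist()
    protected = world.surfaces.protected_frac.tolist()
    irrigated = world.surfaces.irrigation.tolist()
    zones = world.zonemap.zones.tolist()

    names = world.config.crop_names()
    n_secondgen = world.config.n_secondgen
    n_food = len(names) - n_secondgen

    truth = TruthBundle()
    for period, scenario in world.config.scenario_keys():
        rain = [
            world.suitability[(crop, "rainfed", period, scenario)].tolist()
            for crop in names
        ]
        irr = [
            world.suitability[(crop, "irrigated", period, scenario)].tolist()
            for crop in names
        ]
        comb_all = [[_NODATA] * n_cols for _ in range(n_rows)]
        comb_food = [[_NODATA] * n_cols for _ in range(n_rows)]
        for r in range(n_rows):
            irrow = irrigated[r]
            for c in range(n_cols):
                use_irr = irrow[c]
                best_all = _NODATA
                best_food = _NODATA
                for k in range(len(names)):
                    v = irr[k][r][c] if use_irr else rain[k][r][c]
                    if v == _NODATA:
                        continue
                    if v > best_all:
                        best_all = v
                    if k < n_food and v > best_food:
                        best_food = v
                comb_all[r][c] = best_all
                comb_food[r][c] = best_food
        for crop_set, comb in (("all23", comb_all), ("food17", comb_food)):
            truth.slices[(period, scenario, crop_set)] = _ledger_and_sums(
                comb, landcover, imperv, forest, cropflag, protected, zones,
                row_area, n_rows, n_cols, params,
            )
    return truth


def _classify(v: int, params: OracleParams) -> str | None:
    if v >= params.high_min:
        return "high"
    if v >= params.moderate_min:
        return "moderate"
    if v >= params.marginal_min:
        return "marginal"
    return None


def _ledger_and_sums(
    comb, landcover, imperv, forest, cropflag, protected, zones,
    row_area, n_rows, n_cols, params: OracleParams,
) -> TruthSlice:
    ledger = {
        name: [[0.0] * n_cols for _ in range(n_rows)]
        for name in _COMPONENTS
    }
    country: dict[int, dict[str, float]] = {}
    glob = {name: 0.0 for name in _COMPONENTS}
    glob["total_land_km2"] = 0.0
    class_area = {
        inv: {"marginal": 0.0, "moderate": 0.0, "high": 0.0}
        for inv in ("suitable_area", "cultivable_area", "available_area")
    }
    cultivated = {
        inv: 0.0
        for inv in ("suitable_area", "cultivable_area", "available_area")
    }

    for r in range(n_rows):
        pix = row_area[r]
        for c in range(n_cols):
            lc = landcover[r][c]
            zid = zones[r][c]
            if lc != _WATER:
                glob["total_land_km2"] += pix
            v = comb[r][c]
            if v == _NODATA or v < 1:
                continue
            vals = {name: 0.0 for name in _COMPONENTS}
            if lc in params.water_snow_codes:
                vals["excluded_water_snow"] = pix
            else:
                vals["suitable_area"] = pix
                f = imperv[r][c]
                if f is None or f != f:  # nodata -> 0
                    f = 0.0
                vals["excluded_impervious"] = pix * f
                cult = pix - pix * f
                vals["cultivable_area"] = cult
                p = protected[r][c]
                if p != p:
                    p = 0.0
                if p >= params.protected_threshold:
                    vals["excluded_protected"] = cult
                elif forest[r][c]:
                    vals["excluded_forest"] = cult
                elif lc == params.wetland_code:
                    vals["excluded_wetland"] = cult
                else:
                    vals["available_area"] = cult
            for name in _COMPONENTS:
                a = vals[name]
                if a:
                    ledger[name][r][c] = a
                    glob[name] += a
                    if zid != _NODATA:
                        country.setdefault(
                            zid, {n: 0.0 for n in _COMPONENTS}
                        )[name] += a
            cls = _classify(v, params)
            if cls is not None:
                for inv in class_area:
                    class_area[inv][cls] += vals[inv]
            if cropflag[r][c]:
                for inv in cultivated:
                    cultivated[inv] += vals[inv]

    return TruthSlice(
        combined=np.array(comb, dtype=np.int16),
        ledger={name: np.array(arr) for name, arr in ledger.items()},
        country_totals=country,
        global_totals=glob,
        class_area=class_area,
        already_cultivated=cultivated,
    )
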