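"""Zonal aggregation, suitability-class statistics, CDFs and threshold
sensitivity.

All tables are plain :class:`pandas.DataFrame` objects with documented
columns; areas are km^2, shares are percentages in [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AreaRaster, GridSpec, NODATA_INT, check_same_grid
from .masks import ExclusionLedger, SurfaceLayers, WETLAND_CODE
from .suitability import CombinedSuitability, SuitabilityClass, classify

logger = logging.getLogger(__name__)

CLASS_NAMES = {
    SuitabilityClass.MARGINAL: "marginal",
    SuitabilityClass.MODERATE: "moderate",
    SuitabilityClass.HIGH: "high",
}

#: The six reporting regions used for aggregated results.
REGIONS = (
    "Africa",
    "Asia & Russia",
    "Europe",
    "North America",
    "Oceania",
    "South America",
)


@dataclass
class ZoneMap:
    """Country raster plus the country -> region mapping.

    ``zones`` holds a country id per pixel with ``NODATA_INT`` over ocean;
    ``countries`` has columns ``id``, ``name``, ``region``.  Every country
    belongs to exactly one region.
    """

    grid: GridSpec
    zones: np.ndarray  # int
    countries: pd.DataFrame

    def __post_init__(self) -> None:
        if self.zones.shape != self.grid.shape:
            raise ValueError("zone raster shape does not match grid")
        required = {"id", "name", "region"}
        if not required.issubset(self.countries.columns):
            raise ValueError(f"country table needs columns {required}")
        if self.countries["id"].duplicated().any():
            raise ValueError("duplicate country ids in table")

    def region_of(self) -> dict[int, str]:
        return dict(zip(self.countries["id"], self.countries["region"]))


#: component columns carried from ledger into inventory tables
_LEDGER_COLS = ExclusionLedger.BAND_ORDER
#: inventories that get a suitability-class breakdown
_INVENTORIES = ("suitable_area", "cultivable_area", "available_area")


def _zone_sums(weights: np.ndarray, zone_idx: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(zone_idx, weights=weights.ravel(), minlength=n)


def zonal_inventory(
    ledger: ExclusionLedger,
    suit: CombinedSuitability,
    cropland: np.ndarray,
    zonemap: ZoneMap,
    areas: AreaRaster,
    land_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate the ledger to countries, regions and the globe.

    Returns one row per country, one per region, and a ``GLOBAL`` row, with
    ``level`` in {country, region, global, unassigned}.  Region rows are the
    exact sums of their member-country rows and the global row the exact sum
    of the region rows (plus any unassigned land), so the partition property
    holds bit-for-bit.

    ``already_cultivated_*`` columns intersect each inventory with the
    current-cropland flag, weighted by the inventory's per-pixel area, so
    fractional impervious exclusions carry through.
    """
    check_same_grid(ledger.grid, zonemap.grid)
    check_same_grid(ledger.grid, areas.grid)
    zones = zonemap.zones
    pix = areas.expand()
    cls = classify(suit.values)
    crop = cropland.astype(bool)

    ids = zonemap.countries["id"].to_numpy()
    id_to_pos = {cid: i for i, cid in enumerate(ids)}
    n_zones = len(ids) + 1  # final slot collects unassigned land
    unassigned_pos = len(ids)

    pos = np.full(zones.shape, unassigned_pos, dtype=np.int64)
    for cid, p in id_to_pos.items():
        pos[zones == cid] = p
    if land_mask is None:
        land_mask = zones != NODATA_INT
    land_mask = land_mask.astype(bool)
    no_zone_land = land_mask & (zones == NODATA_INT)
    if no_zone_land.any():
        logger.warning(
            "%d land pixels carry no country id; counted as unassigned",
            int(no_zone_land.sum()),
        )
    idx = pos.ravel()
    onland = land_mask.ravel()

    def zsum(weights: np.ndarray) -> np.ndarray:
        w = np.where(onland, weights.ravel(), 0.0)
        return np.bincount(idx, weights=w, minlength=n_zones)

    data: dict[str, np.ndarray] = {}
    data["total_land_km2"] = zsum(pix)
    for name in _LEDGER_COLS:
        data[name.replace("_area", "") + "_km2"] = zsum(
            getattr(ledger, name)
        )
    flat_cls = cls.ravel()
    for inv in _INVENTORIES:
        comp = getattr(ledger, inv).ravel()
        stem = inv.replace("_area", "")
        for code, cname in CLASS_NAMES.items():
            data[f"{stem}_{cname}_km2"] = zsum(
                np.where(flat_cls == int(code), comp, 0.0)
            )
        data[f"already_cultivated_{stem}_km2"] = zsum(
            np.where(crop.ravel(), comp, 0.0)
        )

    rows = pd.DataFrame(data)
    rows.insert(0, "zone_id", list(ids) + [NODATA_INT])
    rows.insert(1, "name", list(zonemap.countries["name"]) + ["UNASSIGNED"])
    rows.insert(
        2, "region", list(zonemap.countries["region"]) + ["UNASSIGNED"]
    )
    rows.insert(3, "level", ["country"] * len(ids) + ["unassigned"])

    countries = rows[rows["level"] == "country"]
    value_cols = [c for c in rows.columns if c.endswith("_km2")]
    region_rows = []
    for region in sorted(countries["region"].unique()):
        member = countries[countries["region"] == region]
        rec = {c: member[c].sum() for c in value_cols}
        rec.update(zone_id=NODATA_INT, name=region, region=region,
                   level="region")
        region_rows.append(rec)
    regions = pd.DataFrame(region_rows)

    glob = {c: regions[c].sum() for c in value_cols}
    unassigned = rows[rows["level"] == "unassigned"]
    for c in value_cols:
        glob[c] = glob[c] + unassigned[c].sum()
    glob.update(zone_id=NODATA_INT, name="GLOBAL", region="GLOBAL",
                level="global")

    keep_unassigned = unassigned[value_cols].to_numpy().sum() > 0
    parts = [rows[rows["level"] == "country"], regions,
             pd.DataFrame([glob])]
    if keep_unassigned:
        parts.insert(1, unassigned)
    table = pd.concat(parts, ignore_index=True)[rows.columns]

    with np.errstate(invalid="ignore", divide="ignore"):
        land = table["total_land_km2"].to_numpy()
        for stem in ("suitable", "cultivable", "available"):
            table[f"{stem}_share_of_land_pct"] = np.where(
                land > 0, table[f"{stem}_km2"] / np.where(land > 0, land, 1.0)
                * 100.0, 0.0,
            )
        avail = table["available_km2"].to_numpy()
        table["already_cultivated_available_share_pct"] = np.where(
            avail > 0,
            table["already_cultivated_available_km2"]
            / np.where(avail > 0, avail, 1.0) * 100.0,
            0.0,
        )
    return table


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks near
    the ends)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return series.astype(float, copy=True)
    half = window // 2
    out = np.empty(len(series), dtype=float)
    for i in range(len(series)):
        lo = max(0, i - half)
        hi = min(len(series), i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def cdf(
    component: np.ndarray,
    suit: CombinedSuitability,
    smoothing_window: int = 5,
) -> pd.DataFrame:
    """Area by integer suitability value 1..100, its cumulative share of the
    component total, and a smoothed area series.

    Columns: ``value``, ``area_km2``, ``cum_share_pct``,
    ``area_smoothed_km2``.  The cumulative share is nondecreasing and
    reaches 100% at value 100.
    """
    vals = suit.values
    valid = (vals != NODATA_INT) & (vals >= 1)
    area = np.where(valid, component, 0.0)
    binned = np.bincount(
        np.where(valid, vals, 0).ravel(), weights=area.ravel(), minlength=101
    )[1:101]
    total = binned.sum()
    if total <= 0:
        raise ValueError("component has no area on suitable pixels")
    cum = np.cumsum(binned) / total * 100.0
    return pd.DataFrame(
        {
            "value": np.arange(1, 101),
            "area_km2": binned,
            "cum_share_pct": cum,
            "area_smoothed_km2": moving_average(binned, smoothing_window),
        }
    )


#: reporting land-cover classes for the suitability profile, in the
#: priority order used to attribute the non-impervious pixel remainder
PROFILE_CLASSES = ("urban", "cropland", "forest", "pasture", "wetland",
                   "other")


def landcover_by_suitability(
    suit: CombinedSuitability,
    surfaces: SurfaceLayers,
    areas: AreaRaster,
    smoothing_window: int = 1,
) -> pd.DataFrame:
    """Absolute area and relative share of each land-cover class per
    suitability value (long format: value, cover, area_km2, share_pct).

    The impervious fraction of every pixel counts as ``urban``; the
    remainder goes to the first matching class of cropland -> forest ->
    pasture -> wetland -> other.  Water and snow pixels are outside the
    suitable domain and are not profiled.  Shares sum to 100% for every
    occupied value; empty value bins are absent from the table.
    """
    check_same_grid(suit.grid, surfaces.grid)
    pix = areas.expand()
    vals = suit.values
    valid = (vals != NODATA_INT) & (vals >= 1) & ~np.isin(
        surfaces.landcover, (210, 220)
    )
    imperv = np.where(
        np.isfinite(surfaces.impervious_frac), surfaces.impervious_frac, 0.0
    )
    rest = pix * (1.0 - imperv)
    pasture = (
        surfaces.pasture.astype(bool)
        if surfaces.pasture is not None
        else np.zeros(suit.grid.shape, dtype=bool)
    )
    crop = surfaces.cropland.astype(bool)
    forest = surfaces.forest.astype(bool)
    wetland = surfaces.landcover == WETLAND_CODE
    masks = {
        "urban": None,  # fractional, handled separately
        "cropland": crop,
        "forest": forest & ~crop,
        "pasture": pasture & ~crop & ~forest,
        "wetland": wetland & ~crop & ~forest & ~pasture,
        "other": ~crop & ~forest & ~pasture & ~wetland,
    }
    v = np.where(valid, vals, 0).ravel()
    records = []
    per_class = {}
    for cover, mask in masks.items():
        if cover == "urban":
            w = np.where(valid, pix * imperv, 0.0)
        else:
            w = np.where(valid & mask, rest, 0.0)
        per_class[cover] = np.bincount(v, weights=w.ravel(), minlength=101)[
            1:101
        ]
    total_per_value = sum(per_class.values())
    for cover in PROFILE_CLASSES:
        smoothed = moving_average(per_class[cover], smoothing_window)
        for i, value in enumerate(range(1, 101)):
            if total_per_value[i] <= 0:
                continue  # empty bin: shares undefined, row absent
            records.append(
                {
                    "value": value,
                    "cover": cover,
                    "area_km2": per_class[cover][i],
                    "area_smoothed_km2": smoothed[i],
                    "share_pct": per_class[cover][i] / total_per_value[i]
                    * 100.0,
                }
            )
    return pd.DataFrame.from_records(records)


def threshold_sensitivity(
    suit: CombinedSuitability,
    cropland: np.ndarray,
    areas: AreaRaster,
    thresholds: list[int] | tuple[int, ...] = (10, 20, 30),
) -> pd.DataFrame:
    """Reduction of suitable land and loss of current cropland when pixels
    below a suitability threshold are dropped.

    For each threshold ``t``: ``reduction_pct`` is the share of the
    suitable area (suit >= 1) with suitability < t, and
    ``cropland_excluded_pct`` the analogous share over current-cropland
    pixels.  Both columns are nondecreasing in t and 0 at t = 0.
    """
    for t in thresholds:
        if not 0 <= t <= 100:
            raise ValueError("thresholds must lie in [0, 100]")
    pix = areas.expand()
    vals = suit.values
    suitable = (vals != NODATA_INT) & (vals >= 1)
    crop = cropland.astype(bool) & suitable
    total_suit = float(pix[suitable].sum())
    if total_suit <= 0:
        raise ValueError("no suitable area; sensitivity undefined")
    total_crop = float(pix[crop].sum())
    rows = []
    for t in sorted(thresholds):
        below = suitable & (vals < t)
        red = float(pix[below].sum()) / total_suit * 100.0
        if total_crop > 0:
            crop_excl = float(pix[crop & (vals < t)].sum()) / total_crop \
                * 100.0
        else:
            crop_excl = 0.0
        rows.append(
            {
                "threshold": t,
                "reduction_pct": red,
                "cropland_excluded_pct": crop_excl,
            }
        )
    return pd.DataFrame(rows)
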