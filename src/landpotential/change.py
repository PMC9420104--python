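"""Change of cultivable land between time periods and climate scenarios.

Covers the per-pixel gain/loss transition map between the historic period
and a future period under RCP2.6 and RCP8.5, region-level change tables,
and the comparison of a cultivable-land inventory against an external
estimate on a coarser grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .grid import GridSpec, NODATA_INT, aggregate_area_sum, check_same_grid
from .masks import ExclusionLedger
from .stats import CLASS_NAMES
from .suitability import CombinedSuitability, classify

PERIODS = ("1980-2009", "2010-2039", "2040-2069", "2070-2099")
HISTORIC_PERIOD = PERIODS[0]


@dataclass(frozen=True)
class ScenarioKey:
    """(period, scenario) pair; the historic scenario is only valid for the
    historic period 1980-2009."""

    period: str
    scenario: str  # "historic" | "RCP2.6" | "RCP8.5"

    def __post_init__(self) -> None:
        if (self.scenario == "historic") != (self.period == HISTORIC_PERIOD):
            raise ValueError(
                f"scenario 'historic' pairs only with period "
                f"{HISTORIC_PERIOD}; got {self.period}/{self.scenario}"
            )


class ChangeCategory(IntEnum):
    """Transition categories of cultivable land; a pixel counts as
    cultivable when its cultivable area is positive."""

    STABLE_UNCULTIVABLE = 0
    STABLE_CULTIVABLE = 1
    GAIN_RCP26_ONLY = 2
    GAIN_RCP85_ONLY = 3
    GAIN_BOTH = 4
    LOSS_RCP26_ONLY = 5
    LOSS_RCP85_ONLY = 6
    LOSS_BOTH = 7


def classify_change(
    hist: ExclusionLedger,
    fut26: ExclusionLedger,
    fut85: ExclusionLedger,
    land_mask: np.ndarray,
) -> np.ndarray:
    """Per-pixel transition category between the historic and one future
    period under both RCPs.

    Gain = not cultivable historically but cultivable under a scenario;
    loss = the inverse.  The categories partition all land pixels; ocean
    pixels get ``NODATA_INT``.
    """
    check_same_grid(hist.grid, fut26.grid)
    check_same_grid(hist.grid, fut85.grid)
    h = hist.cultivable_area > 0
    f26 = fut26.cultivable_area > 0
    f85 = fut85.cultivable_area > 0
    out = np.full(hist.grid.shape, int(ChangeCategory.STABLE_UNCULTIVABLE),
                  dtype=np.int8)
    out[h & f26 & f85] = ChangeCategory.STABLE_CULTIVABLE
    out[~h & f26 & ~f85] = ChangeCategory.GAIN_RCP26_ONLY
    out[~h & ~f26 & f85] = ChangeCategory.GAIN_RCP85_ONLY
    out[~h & f26 & f85] = ChangeCategory.GAIN_BOTH
    out[h & ~f26 & f85] = ChangeCategory.LOSS_RCP26_ONLY
    out[h & f26 & ~f85] = ChangeCategory.LOSS_RCP85_ONLY
    out[h & ~f26 & ~f85] = ChangeCategory.LOSS_BOTH
    out[~land_mask.astype(bool)] = NODATA_INT
    return out


def change_table(
    inventories: dict[ScenarioKey, pd.DataFrame],
    future_period: str = PERIODS[-1],
) -> pd.DataFrame:
    """Percentage change of cultivable land per region and per RCP between
    the historic period and ``future_period``, with suitability-class
    detail.

    Columns per row (one row per zone x RCP): ``cultivable_hist_km2``,
    ``cultivable_fut_km2``, ``change_pct``, per-class absolute areas for
    both periods, per-class ``change_<class>_pct`` and class-share changes
    ``share_change_<class>_pp``.  Zones with zero historic area report NaN
    change (undefined), never infinity.
    """
    hist_key = ScenarioKey(HISTORIC_PERIOD, "historic")
    if hist_key not in inventories:
        raise ValueError("historic baseline inventory is required")
    hist = inventories[hist_key].set_index("name")
    rows = []
    futures = {
        k: v for k, v in inventories.items() if k.period == future_period
    }
    if not futures:
        raise ValueError(f"no future inventory for period {future_period}")
    for key, fut_table in sorted(futures.items(), key=lambda kv: kv[0].scenario):
        fut = fut_table.set_index("name")
        for name in hist.index:
            if name not in fut.index:
                continue
            h = hist.loc[name]
            f = fut.loc[name]
            rec: dict[str, object] = {
                "name": name,
                "level": h["level"],
                "scenario": key.scenario,
                "period": key.period,
                "cultivable_hist_km2": h["cultivable_km2"],
                "cultivable_fut_km2": f["cultivable_km2"],
                "change_pct": _pct_change(
                    h["cultivable_km2"], f["cultivable_km2"]
                ),
            }
            for cname in CLASS_NAMES.values():
                hk = h[f"cultivable_{cname}_km2"]
                fk = f[f"cultivable_{cname}_km2"]
                rec[f"cultivable_{cname}_hist_km2"] = hk
                rec[f"cultivable_{cname}_fut_km2"] = fk
                rec[f"change_{cname}_pct"] = _pct_change(hk, fk)
                hshare = hk / h["cultivable_km2"] * 100.0 \
                    if h["cultivable_km2"] > 0 else np.nan
                fshare = fk / f["cultivable_km2"] * 100.0 \
                    if f["cultivable_km2"] > 0 else np.nan
                rec[f"share_change_{cname}_pp"] = fshare - hshare
            rows.append(rec)
    return pd.DataFrame(rows)


def _pct_change(hist: float, fut: float) -> float:
    if hist <= 0:
        return float("nan")
    return (fut - hist) / hist * 100.0


def compare_inventories(
    mine: ExclusionLedger,
    other: np.ndarray,
    other_grid: GridSpec,
    suit: CombinedSuitability,
) -> dict[str, object]:
    """Compare my cultivable-land inventory with an external area estimate
    on a coarser, nested grid.

    My per-pixel cultivable areas are summed onto the other grid (area is
    conserved); the report gives both totals, the absolute and percentage
    difference, and the suitability-class composition of the surplus — area
    present in my inventory but not in the other, attributed to classes by
    my native-resolution class mix within each coarse cell.
    """
    if mine.grid.n_rows % other_grid.n_rows or \
            mine.grid.n_cols % other_grid.n_cols:
        raise ValueError("grids are not nested by an integer factor")
    factor = mine.grid.n_rows // other_grid.n_rows
    if mine.grid.n_cols // other_grid.n_cols != factor:
        raise ValueError("row and column aggregation factors differ")
    if mine.grid.coarsen(factor) != other_grid:
        raise ValueError("coarse grid extent does not match")
    if other.shape != other_grid.shape:
        raise ValueError("other raster shape does not match its grid")

    cls = classify(suit.values)
    per_class_coarse = {}
    for code, cname in CLASS_NAMES.items():
        comp = np.where(cls == int(code), mine.cultivable_area, 0.0)
        per_class_coarse[cname], _ = aggregate_area_sum(
            comp, mine.grid, factor
        )
    mine_coarse, _ = aggregate_area_sum(mine.cultivable_area, mine.grid,
                                        factor)
    other_vals = np.where(np.isfinite(other), other, 0.0)

    surplus = np.maximum(mine_coarse - other_vals, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mine_coarse > 0, surplus / np.where(
            mine_coarse > 0, mine_coarse, 1.0), 0.0)
    surplus_by_class = {
        cname: float((per_class_coarse[cname] * scale).sum())
        for cname in CLASS_NAMES.values()
    }
    my_total = float(mine_coarse.sum())
    other_total = float(other_vals.sum())
    surplus_total = float(surplus.sum())
    report: dict[str, object] = {
        "my_total_km2": my_total,
        "other_total_km2": other_total,
        "difference_km2": my_total - other_total,
        "difference_pct": (
            (my_total - other_total) / other_total * 100.0
            if other_total > 0 else float("nan")
        ),
        "surplus_km2": surplus_total,
        "surplus_by_class_km2": surplus_by_class,
        "surplus_class_share_pct": {
            cname: (a / surplus_total * 100.0 if surplus_total > 0 else 0.0)
            for cname, a in surplus_by_class.items()
        },
    }
    return report
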