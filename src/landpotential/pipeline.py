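"""End-to-end orchestration: synthetic or loaded inputs -> combined
suitability -> exclusion ledgers -> inventory, sensitivity and change
products, with deterministic file outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import (
    ScenarioKey,
    change_table,
    classify_change,
)
from .config import PipelineParams
from .grid import AreaRaster, aggregate_area_sum, build_area_raster
from .io import write_ledger, write_raster
from .masks import ExclusionLedger, build_ledger
from .stats import (
    cdf,
    threshold_sensitivity,
    zonal_inventory,
)
from .suitability import CombinedSuitability, combine_regimes, max_over_crops
from .synthetic import HISTORIC_PERIOD, WorldBundle

logger = logging.getLogger(__name__)

Key = tuple[str, str, str]  # (period, scenario, crop_set)


@dataclass
class PipelineResult:
    """In-memory products of one pipeline run."""

    areas: AreaRaster
    combined: dict[Key, CombinedSuitability]
    ledgers: dict[Key, ExclusionLedger]
    inventories: dict[Key, pd.DataFrame]
    sensitivity: pd.DataFrame | None = None
    cdf_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    change_map: np.ndarray | None = None
    change: pd.DataFrame | None = None


def combined_suitability(
    world: WorldBundle,
    period: str,
    scenario: str,
    crop_set: str,
    params: PipelineParams,
) -> CombinedSuitability:
    """Regime combination under current irrigation patterns followed by the
    per-pixel maximum over the crop set."""
    merged = [
        combine_regimes(
            rain, irr, world.surfaces.irrigation,
            policy=params.irrigation_policy,
        )
        for rain, irr in zip(
            world.crop_layers(period, scenario, "rainfed"),
            world.crop_layers(period, scenario, "irrigated"),
        )
    ]
    names = world.config.crop_names()
    n_food = len(names) - world.config.n_secondgen
    members = names if crop_set == "all23" else names[:n_food]
    return max_over_crops(merged, crop_set, members=members)


def build_products(
    world: WorldBundle, params: PipelineParams | None = None
) -> PipelineResult:
    """Run every stage on ``world`` for all scenario keys and crop sets."""
    if params is None:
        params = PipelineParams()
    areas = build_area_raster(world.grid, params.earth_radius_km)
    combined: dict[Key, CombinedSuitability] = {}
    ledgers: dict[Key, ExclusionLedger] = {}
    inventories: dict[Key, pd.DataFrame] = {}
    land = world.land
    for period, scenario in world.config.scenario_keys():
        for crop_set in params.crop_sets:
            key: Key = (period, scenario, crop_set)
            suit = combined_suitability(world, period, scenario, crop_set,
                                        params)
            ledger = build_ledger(
                suit, world.surfaces, areas,
                water_snow_codes=params.water_snow_codes,
                wetland_code=params.wetland_code,
                protected_threshold=params.protected_threshold,
            )
            combined[key] = suit
            ledgers[key] = ledger
            inventories[key] = zonal_inventory(
                ledger, suit, world.surfaces.cropland, world.zonemap, areas,
                land_mask=land,
            )
            logger.info("built %s: %s", key, ledger.totals())

    result = PipelineResult(
        areas=areas, combined=combined, ledgers=ledgers,
        inventories=inventories,
    )

    hist_key: Key = (HISTORIC_PERIOD, "historic", params.crop_sets[0])
    if hist_key in combined:
        suit = combined[hist_key]
        ledger = ledgers[hist_key]
        result.sensitivity = threshold_sensitivity(
            suit, world.surfaces.cropland, areas, params.thresholds
        )
        for comp in ("cultivable_area", "available_area"):
            result.cdf_tables[comp] = cdf(
                getattr(ledger, comp), suit, params.smoothing_window
            )

    future = [p for p in world.config.periods if p != HISTORIC_PERIOD]
    if future and hist_key in ledgers:
        fut = future[-1]
        k26: Key = (fut, "RCP2.6", params.crop_sets[0])
        k85: Key = (fut, "RCP8.5", params.crop_sets[0])
        if k26 in ledgers and k85 in ledgers:
            result.change_map = classify_change(
                ledgers[hist_key], ledgers[k26], ledgers[k85], land
            )
            result.change = change_table(
                {
                    ScenarioKey(HISTORIC_PERIOD, "historic"):
                        inventories[hist_key],
                    ScenarioKey(fut, "RCP2.6"): inventories[k26],
                    ScenarioKey(fut, "RCP8.5"): inventories[k85],
                },
                future_period=fut,
            )
    return result


def run_pipeline(
    world: WorldBundle,
    params: PipelineParams,
    out_dir: str | Path,
    write_rasters: bool = True,
    coarse_factor: int | None = None,
) -> PipelineResult:
    """Run the pipeline and write products plus a run manifest to
    ``out_dir``.  Outputs are deterministic for fixed inputs; rerunning
    yields byte-identical CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = build_products(world, params)
    totals: dict[str, dict[str, float]] = {}
    for key, ledger in result.ledgers.items():
        tag = "_".join(key).replace(".", "")
        inv = result.inventories[key]
        inv.to_csv(out / f"inventory_{tag}.csv", index=False,
                   float_format="%.6f")
        totals[str(key)] = ledger.totals()
        if write_rasters:
            write_raster(out / f"suitability_{tag}.tif",
                         result.combined[key].values, world.grid, nodata=-1)
            write_ledger(out / f"ledger_{tag}.tif", ledger)
            if coarse_factor and coarse_factor > 1:
                coarse, cg = aggregate_area_sum(
                    ledger.available_area, world.grid, coarse_factor
                )
                write_raster(out / f"available_coarse_{tag}.tif", coarse, cg)
    if result.sensitivity is not None:
        result.sensitivity.to_csv(out / "sensitivity.csv", index=False,
                                  float_format="%.6f")
    for comp, table in result.cdf_tables.items():
        table.to_csv(out / f"cdf_{comp}.csv", index=False,
                     float_format="%.6f")
    if result.change is not None:
        result.change.to_csv(out / "change_table.csv", index=False,
                             float_format="%.6f")
    if result.change_map is not None and write_rasters:
        write_raster(out / "change_map.tif", result.change_map, world.grid,
                     nodata=-1)

    cfg_digest = hashlib.sha256(
        json.dumps(
            {
                "params": params.__dict__,
                "world_seed": world.config.seed,
                "grid": world.grid.__dict__,
            },
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "config_sha256": cfg_digest,
        "seed": world.config.seed,
        "global_totals_km2": totals,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
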