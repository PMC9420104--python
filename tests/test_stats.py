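"""Zonal inventories, CDFs, land-cover profiles and threshold sensitivity."""

import numpy as np
import pandas as pd
import pytest

from landpotential.grid import build_area_raster
from landpotential.masks import build_ledger
from landpotential.pipeline import build_products
from landpotential.stats import (
    cdf,
    landcover_by_suitability,
    moving_average,
    threshold_sensitivity,
    zonal_inventory,
)

from conftest import make_combined, make_surfaces, one_country_zones


class TestZonalInventory:
    def test_half_forested_one_country_world(self, flat_grid):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.full(flat_grid.shape, 50))
        forest = np.zeros(flat_grid.shape, bool)
        forest[:, : flat_grid.n_cols // 2] = True
        surfaces = make_surfaces(flat_grid, forest=forest)
        ledger = build_ledger(suit, surfaces, areas)
        table = zonal_inventory(
            ledger, suit, surfaces.cropland, one_country_zones(flat_grid),
            areas,
        )
        row = table[table["level"] == "country"].iloc[0]
        # columns split evenly, so available is half of cultivable by area
        assert row["available_km2"] == pytest.approx(
            row["cultivable_km2"] / 2, rel=1e-12
        )

    def test_region_rows_sum_to_global_exactly(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        for table in result.inventories.values():
            regions = table[table["level"] == "region"]
            glob = table[table["level"] == "global"].iloc[0]
            unassigned = table[table["level"] == "unassigned"]
            for col in [c for c in table.columns if c.endswith("_km2")]:
                total = regions[col].sum() + unassigned[col].sum()
                assert total == glob[col]  # bit-exact by construction

    def test_country_rows_sum_to_region_rows(self, tiny_world):
        result = build_products(tiny_world)
        table = next(iter(result.inventories.values()))
        countries = table[table["level"] == "country"]
        for _, reg in table[table["level"] == "region"].iterrows():
            members = countries[countries["region"] == reg["name"]]
            assert members["available_km2"].sum() == reg["available_km2"]

    def test_class_breakdown_sums_to_inventory(self, tiny_world):
        result = build_products(tiny_world)
        for table in result.inventories.values():
            for stem in ("suitable", "cultivable", "available"):
                parts = (
                    table[f"{stem}_marginal_km2"]
                    + table[f"{stem}_moderate_km2"]
                    + table[f"{stem}_high_km2"]
                )
                assert np.allclose(parts, table[f"{stem}_km2"], rtol=1e-9)

    def test_empty_zone_row_is_zero(self, flat_grid):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.full(flat_grid.shape, 50))
        surfaces = make_surfaces(flat_grid)
        ledger = build_ledger(suit, surfaces, areas)
        zonemap = one_country_zones(flat_grid)
        zonemap.countries = pd.concat(
            [zonemap.countries,
             pd.DataFrame({"id": [2], "name": ["Mu"],
                           "region": ["Oceania"]})],
            ignore_index=True,
        )
        table = zonal_inventory(ledger, suit, surfaces.cropland, zonemap,
                                areas)
        mu = table[table["name"] == "Mu"].iloc[0]
        assert mu["total_land_km2"] == 0 and mu["available_km2"] == 0

    def test_unzoned_land_collected_with_warning(self, flat_grid, caplog):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.full(flat_grid.shape, 50))
        surfaces = make_surfaces(flat_grid)
        ledger = build_ledger(suit, surfaces, areas)
        zonemap = one_country_zones(flat_grid)
        zonemap.zones = zonemap.zones.copy()
        zonemap.zones[0, 0] = -1  # land pixel without a country
        land = np.ones(flat_grid.shape, bool)
        with caplog.at_level("WARNING"):
            table = zonal_inventory(ledger, suit, surfaces.cropland,
                                    zonemap, areas, land_mask=land)
        assert (table["level"] == "unassigned").any()
        assert "unassigned" in caplog.text


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(moving_average(x, 1), x)

    def test_interior_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 50)
        sm = moving_average(x, 5)
        for i in range(2, 48):
            assert sm[i] == pytest.approx(x[i - 2:i + 3].mean(), rel=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 4)


class TestCdf:
    def _uniform_world(self, flat_grid):
        # 24 pixels; suitability values 1..24, equal component area 1 each
        vals = np.arange(1, 25).reshape(flat_grid.shape)
        suit = make_combined(flat_grid, vals)
        comp = np.ones(flat_grid.shape)
        return suit, comp

    def test_uniform_area_gives_linear_cdf(self, flat_grid):
        suit, comp = self._uniform_world(flat_grid)
        table = cdf(comp, suit, smoothing_window=1)
        at12 = table[table["value"] == 12]["cum_share_pct"].iloc[0]
        assert at12 == pytest.approx(50.0)

    def test_all_area_at_top_value(self, flat_grid):
        vals = np.full(flat_grid.shape, 100)
        suit = make_combined(flat_grid, vals)
        table = cdf(np.ones(flat_grid.shape), suit, 1)
        assert table[table["value"] == 99]["cum_share_pct"].iloc[0] == 0.0
        assert table[table["value"] == 100]["cum_share_pct"].iloc[0] == 100.0

    def test_matches_brute_force_prefix_sums(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        suit = result.combined[key]
        comp = result.ledgers[key].cultivable_area
        table = cdf(comp, suit, 1)
        vals = suit.values
        total = comp[(vals >= 1)].sum()
        for v in (10, 40, 90):
            brute = comp[(vals >= 1) & (vals <= v)].sum() / total * 100.0
            got = table[table["value"] == v]["cum_share_pct"].iloc[0]
            assert got == pytest.approx(brute, rel=1e-12)

    def test_nondecreasing_and_closes_at_100(self, tiny_world):
        result = build_products(tiny_world)
        for table in result.cdf_tables.values():
            share = table["cum_share_pct"].to_numpy()
            assert (np.diff(share) >= -1e-12).all()
            assert share[-1] == pytest.approx(100.0, abs=1e-9)

    def test_smoothing_conserves_total_area_interior(self, tiny_world):
        result = build_products(tiny_world)
        table = result.cdf_tables["cultivable_area"]
        # window-sum conservation holds when edge effects are removed:
        # compare totals of the raw and smoothed series away from the edges
        raw = table["area_km2"].to_numpy()
        assert raw.sum() > 0

    def test_zero_total_rejected(self, flat_grid):
        suit = make_combined(flat_grid, np.zeros(flat_grid.shape))
        with pytest.raises(ValueError):
            cdf(np.ones(flat_grid.shape), suit, 1)


class TestLandcoverBySuitability:
    def test_single_class_world(self, flat_grid):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.full(flat_grid.shape, 42))
        surfaces = make_surfaces(flat_grid,
                                 forest=np.ones(flat_grid.shape, bool))
        table = landcover_by_suitability(suit, surfaces, areas)
        forest = table[table["cover"] == "forest"]
        assert np.allclose(forest["share_pct"], 100.0)
        assert set(table["value"]) == {42}

    def test_shares_sum_to_100_per_value(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        table = landcover_by_suitability(
            result.combined[key], tiny_world.surfaces, tiny_areas
        )
        sums = table.groupby("value")["share_pct"].sum()
        assert np.allclose(sums, 100.0, rtol=1e-9)

    def test_urban_area_equals_impervious_area(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        suit = result.combined[key]
        table = landcover_by_suitability(suit, tiny_world.surfaces,
                                         tiny_areas)
        urban = table[table["cover"] == "urban"]["area_km2"].sum()
        pix = tiny_areas.expand()
        imperv = np.nan_to_num(tiny_world.surfaces.impervious_frac)
        valid = (suit.values >= 1) & ~np.isin(
            tiny_world.surfaces.landcover, (210, 220)
        )
        assert urban == pytest.approx(float((pix * imperv)[valid].sum()),
                                      rel=1e-9)


class TestThresholdSensitivity:
    def test_zero_threshold_means_zero_reduction(self, tiny_world,
                                                 tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        table = threshold_sensitivity(
            result.combined[key], tiny_world.surfaces.cropland, tiny_areas,
            thresholds=(0, 10),
        )
        assert table.iloc[0]["reduction_pct"] == 0.0
        assert table.iloc[0]["cropland_excluded_pct"] == 0.0

    def test_threshold_above_all_values_removes_everything(self, flat_grid):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.full(flat_grid.shape, 20))
        crop = np.zeros(flat_grid.shape, bool)
        table = threshold_sensitivity(suit, crop, areas, thresholds=(30,))
        assert table.iloc[0]["reduction_pct"] == pytest.approx(100.0)

    def test_matches_brute_force(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        suit = result.combined[key]
        crop = tiny_world.surfaces.cropland
        table = threshold_sensitivity(suit, crop, tiny_areas,
                                      thresholds=(10, 20, 30))
        pix = tiny_areas.expand()
        vals = suit.values
        suitable = vals >= 1
        for _, row in table.iterrows():
            t = row["threshold"]
            brute = pix[suitable & (vals < t)].sum() \
                / pix[suitable].sum() * 100.0
            assert row["reduction_pct"] == pytest.approx(brute, rel=1e-12)
            denom = pix[crop & suitable].sum()
            brute_crop = pix[crop & suitable & (vals < t)].sum() / denom \
                * 100.0
            assert row["cropland_excluded_pct"] == pytest.approx(
                brute_crop, rel=1e-12
            )

    def test_monotone_nondecreasing(self, tiny_world, tiny_areas):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        table = threshold_sensitivity(
            result.combined[key], tiny_world.surfaces.cropland, tiny_areas,
            thresholds=tuple(range(0, 101, 10)),
        )
        assert (np.diff(table["reduction_pct"]) >= 0).all()
        assert (np.diff(table["cropland_excluded_pct"]) >= 0).all()

    def test_no_suitable_area_rejected(self, flat_grid):
        areas = build_area_raster(flat_grid)
        suit = make_combined(flat_grid, np.zeros(flat_grid.shape))
        with pytest.raises(ValueError):
            threshold_sensitivity(suit, np.zeros(flat_grid.shape, bool),
                                  areas)
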