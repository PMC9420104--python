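"""Scenario-change classification, change tables and external comparison."""

import numpy as np
import pytest

from landpotential.change import (
    ChangeCategory,
    ScenarioKey,
    change_table,
    classify_change,
    compare_inventories,
)
from landpotential.grid import NODATA_INT, aggregate_area_sum
from landpotential.pipeline import build_products
from landpotential.stats import CLASS_NAMES
from landpotential.suitability import classify


class TestScenarioKey:
    def test_historic_pairing_enforced(self):
        ScenarioKey("1980-2009", "historic")
        with pytest.raises(ValueError):
            ScenarioKey("2070-2099", "historic")
        with pytest.raises(ValueError):
            ScenarioKey("1980-2009", "RCP8.5")


def _ledger_like(result, key, cultivable):
    """Clone a ledger with a replaced cultivable_area field."""
    import dataclasses
    return dataclasses.replace(result.ledgers[key],
                               cultivable_area=cultivable)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "h, f26, f85, expected",
        [
            (0.0, 1.0, 1.0, ChangeCategory.GAIN_BOTH),
            (0.0, 1.0, 0.0, ChangeCategory.GAIN_RCP26_ONLY),
            (0.0, 0.0, 1.0, ChangeCategory.GAIN_RCP85_ONLY),
            (1.0, 0.0, 0.0, ChangeCategory.LOSS_BOTH),
            (1.0, 0.0, 1.0, ChangeCategory.LOSS_RCP26_ONLY),
            (1.0, 1.0, 0.0, ChangeCategory.LOSS_RCP85_ONLY),
            (1.0, 1.0, 1.0, ChangeCategory.STABLE_CULTIVABLE),
            (0.0, 0.0, 0.0, ChangeCategory.STABLE_UNCULTIVABLE),
        ],
    )
    def test_transition_definitions(self, tiny_world, h, f26, f85,
                                    expected):
        result = build_products(tiny_world)
        keys = list(result.ledgers)
        hist_k = ("1980-2009", "historic", "all23")
        shape = tiny_world.grid.shape
        hist = _ledger_like(result, hist_k, np.full(shape, h))
        fut26 = _ledger_like(result, hist_k, np.full(shape, f26))
        fut85 = _ledger_like(result, hist_k, np.full(shape, f85))
        land = np.ones(shape, bool)
        out = classify_change(hist, fut26, fut85, land)
        assert (out == expected).all()

    def test_partition_of_land_pixels(self, tiny_world):
        result = build_products(tiny_world)
        cm = result.change_map
        land = tiny_world.land
        assert (cm[~land] == NODATA_INT).all()
        assert (cm[land] >= 0).all()
        n = sum(int((cm[land] == int(cat)).sum()) for cat in ChangeCategory)
        assert n == int(land.sum())

    def test_poleward_gains_under_warming(self, tiny_world):
        """Gains appear and RCP8.5 (the stronger warming) gains at least as
        much area as RCP2.6 gains alone."""
        result = build_products(tiny_world)
        cm = result.change_map
        gains = np.isin(
            cm,
            [int(ChangeCategory.GAIN_BOTH),
             int(ChangeCategory.GAIN_RCP85_ONLY),
             int(ChangeCategory.GAIN_RCP26_ONLY)],
        )
        assert gains.any()


class TestChangeTable:
    def test_identical_inventories_give_zero_change(self, tiny_world):
        result = build_products(tiny_world)
        hist_inv = result.inventories[("1980-2009", "historic", "all23")]
        table = change_table(
            {
                ScenarioKey("1980-2009", "historic"): hist_inv,
                ScenarioKey("2070-2099", "RCP2.6"): hist_inv,
                ScenarioKey("2070-2099", "RCP8.5"): hist_inv,
            }
        )
        nonzero_hist = table["cultivable_hist_km2"] > 0
        assert np.allclose(table.loc[nonzero_hist, "change_pct"], 0.0)

    def test_percentage_arithmetic(self, tiny_world):
        result = build_products(tiny_world)
        hist = result.inventories[("1980-2009", "historic", "all23")].copy()
        fut = hist.copy()
        fut["cultivable_km2"] = hist["cultivable_km2"] * 1.13
        table = change_table(
            {
                ScenarioKey("1980-2009", "historic"): hist,
                ScenarioKey("2070-2099", "RCP8.5"): fut,
            }
        )
        nonzero = table["cultivable_hist_km2"] > 0
        assert np.allclose(table.loc[nonzero, "change_pct"], 13.0)

    def test_consistent_with_absolute_totals(self, tiny_world):
        result = build_products(tiny_world)
        table = result.change
        nonzero = table["cultivable_hist_km2"] > 0
        recomputed = (
            (table["cultivable_fut_km2"] - table["cultivable_hist_km2"])
            / table["cultivable_hist_km2"] * 100.0
        )
        assert np.allclose(table.loc[nonzero, "change_pct"],
                           recomputed[nonzero], rtol=1e-9)

    def test_zero_historic_reports_nan_not_inf(self, tiny_world):
        result = build_products(tiny_world)
        hist = result.inventories[("1980-2009", "historic", "all23")].copy()
        hist["cultivable_km2"] = 0.0
        fut = result.inventories[("1980-2009", "historic", "all23")]
        table = change_table(
            {
                ScenarioKey("1980-2009", "historic"): hist,
                ScenarioKey("2070-2099", "RCP8.5"): fut,
            }
        )
        assert table["change_pct"].isna().all()
        assert not np.isinf(table["change_pct"].fillna(0)).any()

    def test_missing_baseline_rejected(self, tiny_world):
        result = build_products(tiny_world)
        fut = result.inventories[("2070-2099", "RCP8.5", "all23")]
        with pytest.raises(ValueError, match="historic"):
            change_table({ScenarioKey("2070-2099", "RCP8.5"): fut})


class TestCompareInventories:
    def test_self_comparison_is_zero(self, tiny_world):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        ledger = result.ledgers[key]
        other, ogrid = aggregate_area_sum(ledger.cultivable_area,
                                          tiny_world.grid, 4)
        report = compare_inventories(ledger, other, ogrid,
                                     result.combined[key])
        assert report["difference_km2"] == pytest.approx(0.0, abs=1e-6)
        assert report["surplus_km2"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_other_gives_full_class_breakdown(self, tiny_world):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        ledger = result.ledgers[key]
        ogrid = tiny_world.grid.coarsen(4)
        report = compare_inventories(
            ledger, np.zeros(ogrid.shape), ogrid, result.combined[key]
        )
        total = float(ledger.cultivable_area.sum())
        assert report["difference_km2"] == pytest.approx(total, rel=1e-12)
        cls = classify(result.combined[key].values)
        for code, cname in CLASS_NAMES.items():
            brute = float(
                ledger.cultivable_area[cls == int(code)].sum()
            )
            assert report["surplus_by_class_km2"][cname] == pytest.approx(
                brute, rel=1e-9
            )

    def test_matches_brute_force_per_cell(self, tiny_world):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        ledger = result.ledgers[key]
        factor = 6
        ogrid = tiny_world.grid.coarsen(factor)
        rng = np.random.default_rng(12)
        other = rng.uniform(0, 2e6, ogrid.shape)
        report = compare_inventories(ledger, other, ogrid,
                                     result.combined[key])
        cls = classify(result.combined[key].values)
        surplus = 0.0
        by_class = {c: 0.0 for c in CLASS_NAMES.values()}
        for R in range(ogrid.n_rows):
            for C in range(ogrid.n_cols):
                block = ledger.cultivable_area[
                    R * factor:(R + 1) * factor,
                    C * factor:(C + 1) * factor,
                ]
                cblock = cls[R * factor:(R + 1) * factor,
                             C * factor:(C + 1) * factor]
                mine = block.sum()
                s = max(mine - other[R, C], 0.0)
                surplus += s
                if mine > 0:
                    for code, cname in CLASS_NAMES.items():
                        by_class[cname] += s * block[
                            cblock == int(code)
                        ].sum() / mine
        assert report["surplus_km2"] == pytest.approx(surplus, rel=1e-9)
        for cname in CLASS_NAMES.values():
            assert report["surplus_by_class_km2"][cname] == pytest.approx(
                by_class[cname], rel=1e-9
            )

    def test_aggregation_conserves_area(self, tiny_world):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        ledger = result.ledgers[key]
        coarse, _ = aggregate_area_sum(ledger.cultivable_area,
                                       tiny_world.grid, 9)
        assert float(coarse.sum()) == pytest.approx(
            float(ledger.cultivable_area.sum()), rel=1e-12
        )

    def test_non_nested_grids_rejected(self, tiny_world):
        result = build_products(tiny_world)
        key = ("1980-2009", "historic", "all23")
        bad_grid = tiny_world.grid.coarsen(4)
        bad_grid = type(bad_grid)(
            lon_min=bad_grid.lon_min + 1.0, lat_max=bad_grid.lat_max,
            n_rows=bad_grid.n_rows, n_cols=bad_grid.n_cols,
            resolution=bad_grid.resolution,
        )
        with pytest.raises(ValueError):
            compare_inventories(
                result.ledgers[key], np.zeros(bad_grid.shape), bad_grid,
                result.combined[key],
            )
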