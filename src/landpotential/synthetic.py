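"""Seeded synthetic world generator.

Produces small co-registered stand-ins for the global input layers the
pipeline consumes: per-crop rainfed/irrigated suitability for several
periods and climate scenarios, ESA-CCI-style land cover, impervious and
protected fractions, forest / cropland / irrigation flags and a country
map.  Fields are spatially smooth (filtered white noise), fully determined
by one seed, and built so future scenarios shift the climatic suitability
ridge poleward — stronger under RCP8.5 than RCP2.6 — emulating a warming
driven migration of the agricultural frontier.

The generator is first-class, tested code: its statistical targets (layer
fractions) are part of the study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from . import crops as crop_tables
from .grid import GridSpec, NODATA_INT
from .masks import SNOW_CODE, WATER_CODE, WETLAND_CODE, SurfaceLayers
from .stats import REGIONS, ZoneMap
from .suitability import CropSuitabilityLayer

import pandas as pd

#: synthetic land-cover codes (ESA-CCI-style)
CROPLAND_CODE = 10
FOREST_CODE = 50
GRASS_CODE = 130

HISTORIC_PERIOD = "1980-2009"

#: poleward shift of the climatic suitability ridge, in degrees latitude,
#: reached by the last configured period under each scenario
POLEWARD_SHIFT_DEG = {"RCP2.6": 3.0, "RCP8.5": 8.0}


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of one synthetic world.

    All cover fractions are targets over **land pixels** except
    ``land_fraction``, which is over all pixels.  Forest, wetland and
    cropland are mutually exclusive cover states; impervious, protected and
    irrigation are independent overlays.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec.global_grid(1800.0)  # 0.5 degrees
    )
    n_crops: int = 23
    n_secondgen: int = 6
    periods: tuple[str, ...] = (HISTORIC_PERIOD, "2070-2099")
    scenarios: tuple[str, ...] = ("RCP2.6", "RCP8.5")
    seed: int = 0
    land_fraction: float = 0.29
    forest_fraction: float = 0.31
    wetland_fraction: float = 0.03
    urban_fraction: float = 0.015
    protected_fraction: float = 0.05
    irrigated_fraction: float = 0.07
    cropland_fraction: float = 0.11
    n_countries: int = 12
    region_mapping: tuple[tuple[str, str], ...] | None = None
    smooth_sigma: float = 4.0

    def __post_init__(self) -> None:
        for name in ("land_fraction", "forest_fraction", "wetland_fraction",
                     "urban_fraction", "protected_fraction",
                     "irrigated_fraction", "cropland_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        exclusive = (self.forest_fraction + self.wetland_fraction
                     + self.cropland_fraction)
        if exclusive > 1.0 + 1e-9:
            raise ValueError(
                f"exclusive cover targets (forest + wetland + cropland) sum "
                f"to {exclusive:.3f} > 1"
            )
        if self.n_crops < 1:
            raise ValueError("need at least one crop")
        if self.n_secondgen > self.n_crops:
            raise ValueError("n_secondgen exceeds n_crops")

    def crop_names(self) -> tuple[str, ...]:
        """23 crops use the canonical names; other counts get generic ids
        with the last ``n_secondgen`` flagged second-generation."""
        if self.n_crops == 23 and self.n_secondgen == 6:
            return crop_tables.ALL23
        n_food = self.n_crops - self.n_secondgen
        return tuple(
            [f"crop_{i:02d}" for i in range(n_food)]
            + [f"energycrop_{i:02d}" for i in range(self.n_secondgen)]
        )

    def scenario_keys(self) -> tuple[tuple[str, str], ...]:
        keys: list[tuple[str, str]] = []
        for period in self.periods:
            if period == HISTORIC_PERIOD:
                keys.append((period, "historic"))
            else:
                keys.extend((period, s) for s in self.scenarios)
        return tuple(keys)


@dataclass
class WorldBundle:
    """All synthetic input layers of one world on one grid."""

    config: WorldConfig
    grid: GridSpec
    #: (crop, regime, period, scenario) -> int16 suitability
    suitability: dict[tuple[str, str, str, str], np.ndarray]
    surfaces: SurfaceLayers
    zonemap: ZoneMap

    @property
    def land(self) -> np.ndarray:
        return self.surfaces.landcover != WATER_CODE

    def crop_layers(
        self, period: str, scenario: str, regime: str
    ) -> list[CropSuitabilityLayer]:
        return [
            CropSuitabilityLayer(
                crop=crop, regime=regime, period=period, scenario=scenario,
                values=self.suitability[(crop, regime, period, scenario)],
                grid=self.grid,
            )
            for crop in self.config.crop_names()
        ]


def _smooth01(rng: np.random.Generator, shape: tuple[int, int],
              sigma: float) -> np.ndarray:
    """Smoothed white noise rank-normalized to [0, 1]; periodic in
    longitude."""
    noise = rng.standard_normal(shape)
    sm = gaussian_filter(noise, sigma=sigma, mode=["nearest", "wrap"])
    flat = sm.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return (ranks / max(flat.size - 1, 1)).reshape(shape)


def _top_k(field01: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting the k highest field values among candidate
    pixels."""
    mask = np.zeros(field01.shape, dtype=bool)
    k = min(k, int(candidates.sum()))
    if k <= 0:
        return mask
    vals = np.where(candidates, field01, -np.inf).ravel()
    idx = np.argpartition(vals, -k)[-k:]
    mask.ravel()[idx] = True
    return mask


def generate_world(config: WorldConfig) -> WorldBundle:
    """Generate one deterministic world from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    shape = grid.shape
    sigma = config.smooth_sigma
    lats = np.broadcast_to(grid.cell_center_lats()[:, None], shape)

    # --- land / ocean -----------------------------------------------------
    f_land = _smooth01(rng, shape, sigma * 1.5)
    n_land = round(config.land_fraction * f_land.size)
    land = _top_k(f_land, np.ones(shape, dtype=bool), n_land)

    # --- exclusive cover states on land ----------------------------------
    landcover = np.full(shape, WATER_CODE, dtype=np.int16)
    landcover[land] = GRASS_CODE
    n_on_land = int(land.sum())
    unassigned = land.copy()

    cropland = _top_k(_smooth01(rng, shape, sigma), unassigned,
                      round(config.cropland_fraction * n_on_land))
    unassigned &= ~cropland
    forest = _top_k(_smooth01(rng, shape, sigma), unassigned,
                    round(config.forest_fraction * n_on_land))
    unassigned &= ~forest
    wetland = _top_k(_smooth01(rng, shape, sigma), unassigned,
                     round(config.wetland_fraction * n_on_land))
    unassigned &= ~wetland
    snow = unassigned & (np.abs(lats) > 72.0)  # polar caps
    landcover[cropland] = CROPLAND_CODE
    landcover[forest] = FOREST_CODE
    landcover[wetland] = WETLAND_CODE
    landcover[snow] = SNOW_CODE

    # --- overlay fractions ------------------------------------------------
    f_urb = _smooth01(rng, shape, sigma * 0.5)
    urban = _top_k(f_urb, land, round(config.urban_fraction * n_on_land))
    impervious = np.zeros(shape)
    if urban.any():
        lo = f_urb[urban].min()
        hi = f_urb[urban].max()
        span = max(hi - lo, 1e-12)
        impervious[urban] = 0.05 + 0.9 * (f_urb[urban] - lo) / span
    impervious[~land] = np.nan  # no impervious observations over ocean

    f_prot = _smooth01(rng, shape, sigma)
    protected = np.zeros(shape)
    if n_on_land:
        ranks = np.empty(n_on_land)
        order = np.argsort(f_prot[land], kind="stable")
        ranks[order] = np.arange(n_on_land)
        p = ranks / max(n_on_land - 1, 1)
        pf = config.protected_fraction
        if pf >= 1.0:
            vals = 0.5 + 0.5 * p
        elif pf <= 0.0:
            vals = 0.4999 * p
        else:
            vals = np.where(
                p >= 1.0 - pf,
                0.5 + 0.5 * (p - (1.0 - pf)) / pf,
                0.5 * p / (1.0 - pf),
            )
        protected[land] = np.clip(vals, 0.0, 1.0)

    irrigation = _top_k(_smooth01(rng, shape, sigma), land,
                        round(config.irrigated_fraction * n_on_land))

    surfaces = SurfaceLayers(
        grid=grid,
        landcover=landcover,
        impervious_frac=impervious,
        forest=forest,
        cropland=cropland,
        protected_frac=protected,
        irrigation=irrigation,
    )

    # --- countries and regions -------------------------------------------
    zonemap = _make_zones(rng, grid, land, config)

    # --- per-crop suitability --------------------------------------------
    suitability = _make_suitability(rng, config, land, lats)

    return WorldBundle(
        config=config, grid=grid, suitability=suitability,
        surfaces=surfaces, zonemap=zonemap,
    )


def _make_zones(
    rng: np.random.Generator, grid: GridSpec, land: np.ndarray,
    config: WorldConfig,
) -> ZoneMap:
    """Nearest-seed (Voronoi-like) country partition of the land pixels."""
    zones = np.full(grid.shape, NODATA_INT, dtype=np.int32)
    land_idx = np.argwhere(land)
    n = config.n_countries
    if len(land_idx) and n > 0:
        pick = rng.choice(len(land_idx), size=min(n, len(land_idx)),
                          replace=False)
        seeds = land_idx[pick]  # (n, 2) row/col
        # distance in pixel space with longitudinal wrap
        dr = land_idx[:, 0][:, None] - seeds[:, 0][None, :]
        dc = np.abs(land_idx[:, 1][:, None] - seeds[:, 1][None, :])
        dc = np.minimum(dc, grid.n_cols - dc)
        nearest = (dr * dr + dc * dc).argmin(axis=1)
        zones[land_idx[:, 0], land_idx[:, 1]] = nearest + 1  # ids 1..n
    if config.region_mapping is not None:
        mapping = dict(config.region_mapping)
        names = sorted(mapping)
        countries = pd.DataFrame(
            {
                "id": np.arange(1, len(names) + 1),
                "name": names,
                "region": [mapping[nm] for nm in names],
            }
        )
    else:
        countries = pd.DataFrame(
            {
                "id": np.arange(1, config.n_countries + 1),
                "name": [f"Country_{i:02d}"
                         for i in range(1, config.n_countries + 1)],
                "region": [REGIONS[(i - 1) % len(REGIONS)]
                           for i in range(1, config.n_countries + 1)],
            }
        )
    return ZoneMap(grid=grid, zones=zones, countries=countries)


def _shift_for(config: WorldConfig, period: str, scenario: str) -> float:
    """Poleward ridge shift (degrees) of a period/scenario, linear in the
    period sequence and largest under RCP8.5."""
    if scenario == "historic":
        return 0.0
    idx = config.periods.index(period)
    frac = idx / max(len(config.periods) - 1, 1)
    return POLEWARD_SHIFT_DEG.get(scenario, 5.0) * frac


def _make_suitability(
    rng: np.random.Generator,
    config: WorldConfig,
    land: np.ndarray,
    lats: np.ndarray,
) -> dict[tuple[str, str, str, str], np.ndarray]:
    shape = config.grid.shape
    names = config.crop_names()
    # one moisture field shared by all crops drives the irrigation benefit
    dryness = _smooth01(rng, shape, config.smooth_sigma)
    # soil fertility is crop-independent, so per-crop suitabilities are
    # strongly correlated and the cross-crop maximum does not saturate
    fertility = _smooth01(rng, shape, config.smooth_sigma)
    out: dict[tuple[str, str, str, str], np.ndarray] = {}
    for crop in names:
        ridge = float(rng.uniform(0.0, 45.0))  # |lat| of the climate optimum
        width = float(rng.uniform(12.0, 30.0))
        own = _smooth01(rng, shape, config.smooth_sigma)
        quality = 0.7 * fertility + 0.3 * own
        for period, scenario in config.scenario_keys():
            shift = _shift_for(config, period, scenario)
            # warming both moves the climatic optimum poleward and widens
            # the viable band, so high-latitude gains outweigh the losses
            # on the warm edge (the emulated frontier expansion)
            climate = np.exp(
                -(((np.abs(lats) - (ridge + shift))
                   / (width + 0.5 * shift)) ** 2)
            )
            # rainfed cultivation degrades in arid zones; irrigation
            # compensates, so the dry-area boost below restores it
            moisture = 1.0 - 0.45 * dryness**2
            raw = 100.0 * (
                1.15 * climate * moisture * (0.2 + 0.8 * quality) - 0.10
            )
            rain = np.clip(np.rint(raw), 0, 100).astype(np.int16)
            irr = np.clip(
                rain + np.rint(45.0 * dryness * climate), 0, 100
            ).astype(np.int16)
            rain[~land] = NODATA_INT
            irr[~land] = NODATA_INT
            out[(crop, "rainfed", period, scenario)] = rain
            out[(crop, "irrigated", period, scenario)] = irr
    return out
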