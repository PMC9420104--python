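import numpy as np
import pandas as pd
import pytest

from landpotential.grid import GridSpec, build_area_raster
from landpotential.masks import SurfaceLayers
from landpotential.stats import ZoneMap
from landpotential.suitability import CombinedSuitability
from landpotential.synthetic import WorldConfig, generate_world


def tiny_config(seed: int = 7, **overrides) -> WorldConfig:
    """5-degree global world with 5 crops: fast enough for unit tests,
    rich enough to exercise every exclusion path."""
    defaults = dict(
        grid=GridSpec.global_grid(5 * 3600.0),  # 36 x 72
        n_crops=5,
        n_secondgen=2,
        n_countries=8,
        seed=seed,
    )
    defaults.update(overrides)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config())


@pytest.fixture(scope="session")
def tiny_areas(tiny_world):
    return build_area_raster(tiny_world.grid)


@pytest.fixture
def flat_grid():
    """Small near-equator grid where pixel areas are nearly uniform."""
    return GridSpec(lon_min=0.0, lat_max=2.0, n_rows=4, n_cols=6,
                    resolution=3600.0)


def make_combined(grid: GridSpec, values) -> CombinedSuitability:
    return CombinedSuitability(
        values=np.asarray(values, dtype=np.int16), grid=grid,
        crop_set="all23", period="1980-2009", scenario="historic",
    )


def make_surfaces(
    grid: GridSpec,
    landcover=None,
    impervious=None,
    forest=None,
    cropland=None,
    protected=None,
    irrigation=None,
) -> SurfaceLayers:
    shape = grid.shape
    return SurfaceLayers(
        grid=grid,
        landcover=(np.full(shape, 130, dtype=np.int16)
                   if landcover is None else np.asarray(landcover)),
        impervious_frac=(np.zeros(shape) if impervious is None
                         else np.asarray(impervious, dtype=float)),
        forest=(np.zeros(shape, dtype=bool) if forest is None
                else np.asarray(forest, dtype=bool)),
        cropland=(np.zeros(shape, dtype=bool) if cropland is None
                  else np.asarray(cropland, dtype=bool)),
        protected_frac=(np.zeros(shape) if protected is None
                        else np.asarray(protected, dtype=float)),
        irrigation=(np.zeros(shape, dtype=bool) if irrigation is None
                    else np.asarray(irrigation, dtype=bool)),
    )


def one_country_zones(grid: GridSpec) -> ZoneMap:
    zones = np.ones(grid.shape, dtype=np.int32)
    countries = pd.DataFrame(
        {"id": [1], "name": ["Atlantis"], "region": ["Oceania"]}
    )
    return ZoneMap(grid=grid, zones=zones, countries=countries)
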