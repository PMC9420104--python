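"""Per-pixel exclusion ledger for the three nested land inventories.

The ledger partitions each pixel's area into retained and excluded-by-cause
components across three stages:

1. **Potentially suitable land** — pixels with combined suitability >= 1,
   minus water bodies (land-cover code 210) and permanent snow/ice (220).
2. **Potentially cultivable land** — suitable land minus its man-made
   impervious share (settlements, infrastructure), applied fractionally.
3. **Potentially available cropland** — cultivable land minus whole-pixel
   exclusions in a fixed hierarchy: strictly protected pixels (protected
   fraction >= 0.5) first, then forests, then uncultivated wetlands
   (code 180).

The two conservation identities

    suitable  = excluded_water_snow + excluded_impervious + cultivable
    cultivable = excluded_protected + excluded_forest
                 + excluded_wetland + available

hold pixelwise by construction and are asserted on every build.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import AreaRaster, GridSpec, NODATA_INT, check_same_grid
from .suitability import CombinedSuitability

logger = logging.getLogger(__name__)

#: Land-cover codes removed from the suitable inventory.
WATER_CODE = 210
SNOW_CODE = 220
#: Land-cover code for uncultivated wetlands (cultivated wetlands are coded
#: as cropland upstream and therefore pass through).
WETLAND_CODE = 180
#: A pixel is strictly protected when at least this share of it is covered
#: by IUCN Ia/Ib/II protected areas.
PROTECTED_THRESHOLD = 0.5


@dataclass
class SurfaceLayers:
    """Land-surface inputs co-registered on one grid.

    ``landcover`` is categorical (ESA-CCI-style codes), ``impervious_frac``
    and ``protected_frac`` are [0, 1] overlay fractions, the rest are binary
    flags.  Forest / cropland / wetland / water / snow are mutually
    exclusive cover states; violations are warned about, not fixed.
    """

    grid: GridSpec
    landcover: np.ndarray  # int codes
    impervious_frac: np.ndarray  # float in [0,1], NaN = nodata
    forest: np.ndarray  # bool
    cropland: np.ndarray  # bool
    protected_frac: np.ndarray  # float in [0,1]
    irrigation: np.ndarray  # bool
    pasture: np.ndarray | None = None  # optional, reporting only

    def __post_init__(self) -> None:
        for name in ("landcover", "impervious_frac", "forest", "cropland",
                     "protected_frac", "irrigation"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} does not "
                                 f"match grid {self.grid.shape}")
        overlap = self.forest & self.cropland
        if overlap.any():
            logger.warning(
                "%d pixels flagged both forest and cropland", overlap.sum()
            )
        special = np.isin(self.landcover, [WETLAND_CODE, WATER_CODE, SNOW_CODE])
        mixed = special & (self.forest | self.cropland)
        if mixed.any():
            logger.warning(
                "%d wetland/water/snow pixels also carry a forest or "
                "cropland flag", mixed.sum()
            )


@dataclass
class ExclusionLedger:
    """Pixelwise km^2 partition of the nested inventories."""

    grid: GridSpec
    suitable_area: np.ndarray
    excluded_water_snow: np.ndarray
    excluded_impervious: np.ndarray
    cultivable_area: np.ndarray
    excluded_protected: np.ndarray
    excluded_forest: np.ndarray
    excluded_wetland: np.ndarray
    available_area: np.ndarray
    #: cultivable area on protected-excluded pixels that are forested,
    #: for composition statistics of the protected bucket
    protected_forest_area: np.ndarray | None = None

    #: fixed band order for the multi-band raster product
    BAND_ORDER = (
        "suitable_area",
        "excluded_water_snow",
        "excluded_impervious",
        "cultivable_area",
        "excluded_protected",
        "excluded_forest",
        "excluded_wetland",
        "available_area",
    )

    def components(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.BAND_ORDER}

    def validate(self, rtol: float = 1e-12) -> None:
        """Assert the conservation identities, non-negativity and nesting."""
        atol = rtol * max(float(self.suitable_area.max(initial=0.0)), 1.0)
        for name, comp in self.components().items():
            if comp.shape != self.grid.shape:
                raise ValueError(f"component {name!r} shape mismatch")
            if (comp < -atol).any():
                raise AssertionError(f"negative areas in {name!r}")
        # water/snow exclusion happens before the suitable bucket is
        # formed, so the first identity reduces to suitable = impervious
        # + cultivable
        if not np.allclose(self.suitable_area,
                           self.excluded_impervious + self.cultivable_area,
                           rtol=0, atol=atol):
            raise AssertionError(
                "suitable != impervious + cultivable somewhere"
            )
        lhs2 = (self.excluded_protected + self.excluded_forest
                + self.excluded_wetland + self.available_area)
        if not np.allclose(self.cultivable_area, lhs2, rtol=0, atol=atol):
            raise AssertionError(
                "cultivable != protected + forest + wetland + available "
                "somewhere"
            )
        if ((self.available_area - self.cultivable_area) > atol).any():
            raise AssertionError("available exceeds cultivable somewhere")
        if ((self.cultivable_area - self.suitable_area) > atol).any():
            raise AssertionError("cultivable exceeds suitable somewhere")
        wholepixel = [self.excluded_protected, self.excluded_forest,
                      self.excluded_wetland]
        nonzero = sum((c > atol).astype(int) for c in wholepixel)
        if (nonzero > 1).any():
            raise AssertionError(
                "more than one whole-pixel exclusion category active on a "
                "pixel"
            )

    def totals(self) -> dict[str, float]:
        """Global km^2 sums per component (doubles as the stage log)."""
        return {name: float(comp.sum())
                for name, comp in self.components().items()}


def suitable_area(
    suit: CombinedSuitability,
    landcover: np.ndarray,
    areas: AreaRaster,
    water_snow_codes: tuple[int, ...] = (WATER_CODE, SNOW_CODE),
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 1: potentially suitable land.

    Returns ``(suitable_area, excluded_water_snow)`` in km^2.  A pixel is
    suitable when its combined suitability is >= 1 and its land cover is
    neither water nor permanent snow/ice.
    """
    check_same_grid(suit.grid, areas.grid)
    if landcover.shape != suit.grid.shape:
        raise ValueError("landcover shape does not match grid")
    pix = areas.expand()
    is_suit = (suit.values != NODATA_INT) & (suit.values >= 1)
    wet_or_ice = np.isin(landcover, water_snow_codes)
    suitable = np.where(is_suit & ~wet_or_ice, pix, 0.0)
    excluded = np.where(is_suit & wet_or_ice, pix, 0.0)
    return suitable, excluded


def cultivable_area(
    suitable: np.ndarray, impervious_frac: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: potentially cultivable land.

    The impervious share of each suitable pixel is excluded fractionally:
    ``excluded = suitable * frac`` and ``cultivable = suitable - excluded``,
    so the stage identity is exact in floating point.  Nodata impervious
    fractions count as 0 (logged).
    """
    frac = np.asarray(impervious_frac, dtype=float)
    finite = np.isfinite(frac)
    if np.any((frac[finite] < 0) | (frac[finite] > 1)):
        raise ValueError("impervious fractions must lie in [0, 1]")
    n_imputed = int((~finite & (suitable > 0)).sum())
    if n_imputed:
        logger.info(
            "impervious fraction missing on %d suitable pixels; treated as 0",
            n_imputed,
        )
    frac = np.where(finite, frac, 0.0)
    excluded = suitable * frac
    cultivable = suitable - excluded
    return cultivable, excluded


def available_area(
    cultivable: np.ndarray,
    protected_frac: np.ndarray,
    forest: np.ndarray,
    landcover: np.ndarray,
    protected_threshold: float = PROTECTED_THRESHOLD,
    wetland_code: int = WETLAND_CODE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stage 3: potentially available cropland.

    Whole-pixel exclusion hierarchy, first match wins:
    protected (fraction >= threshold) -> forest -> wetland -> available.
    Also returns the forested share of the protected bucket so its cover
    composition can be reported.
    """
    prot = np.asarray(protected_frac, dtype=float)
    finite = np.isfinite(prot)
    if np.any((prot[finite] < 0) | (prot[finite] > 1)):
        raise ValueError("protected fractions must lie in [0, 1]")
    prot = np.where(finite, prot, 0.0)
    is_protected = prot >= protected_threshold
    is_forest = forest.astype(bool)
    is_wetland = landcover == wetland_code

    excl_protected = np.where(is_protected, cultivable, 0.0)
    excl_forest = np.where(~is_protected & is_forest, cultivable, 0.0)
    excl_wetland = np.where(
        ~is_protected & ~is_forest & is_wetland, cultivable, 0.0
    )
    available = cultivable - excl_protected - excl_forest - excl_wetland
    protected_forest = np.where(is_protected & is_forest, cultivable, 0.0)
    return excl_protected, excl_forest, excl_wetland, available, \
        protected_forest


def build_ledger(
    suit: CombinedSuitability,
    surfaces: SurfaceLayers,
    areas: AreaRaster,
    water_snow_codes: tuple[int, ...] = (WATER_CODE, SNOW_CODE),
    wetland_code: int = WETLAND_CODE,
    protected_threshold: float = PROTECTED_THRESHOLD,
) -> ExclusionLedger:
    """Chain the three stages into a validated :class:`ExclusionLedger`."""
    check_same_grid(suit.grid, surfaces.grid)
    check_same_grid(suit.grid, areas.grid)
    suitable, excl_ws = suitable_area(
        suit, surfaces.landcover, areas, water_snow_codes
    )
    cultivable, excl_imp = cultivable_area(suitable, surfaces.impervious_frac)
    excl_prot, excl_for, excl_wet, available, prot_forest = available_area(
        cultivable,
        surfaces.protected_frac,
        surfaces.forest,
        surfaces.landcover,
        protected_threshold,
        wetland_code,
    )
    ledger = ExclusionLedger(
        grid=suit.grid,
        suitable_area=suitable,
        excluded_water_snow=excl_ws,
        excluded_impervious=excl_imp,
        cultivable_area=cultivable,
        excluded_protected=excl_prot,
        excluded_forest=excl_for,
        excluded_wetland=excl_wet,
        available_area=available,
        protected_forest_area=prot_forest,
    )
    ledger.validate()
    return ledger
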