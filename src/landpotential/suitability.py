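"""Combination and classification of per-crop agricultural suitability.

Suitability is an integer index 0-100 per pixel, crop and water regime
(rainfed / irrigated).  The pipeline first selects the regime per pixel
according to current irrigation patterns, then takes the per-pixel maximum
over a crop set, and finally bins values into marginal / moderate / high
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .crops import ALL23, CROP_SETS
from .grid import NODATA_INT, GridSpec, check_same_grid

HISTORIC = "historic"


class SuitabilityClass(IntEnum):
    """Suitability classes: marginal 1-32, moderate 33-74, high 75-100."""

    UNSUITABLE = 0
    MARGINAL = 1
    MODERATE = 2
    HIGH = 3


#: Lower bounds of (marginal, moderate, high); values below MARGINAL_MIN
#: are unsuitable.
MARGINAL_MIN = 1
MODERATE_MIN = 33
HIGH_MIN = 75


@dataclass
class CropSuitabilityLayer:
    """Integer 0-100 suitability of one crop under one regime / period /
    scenario; ``NODATA_INT`` marks missing pixels (e.g. ocean)."""

    crop: str
    regime: str  # "rainfed" | "irrigated" | "current_irrigation"
    period: str
    scenario: str  # "historic" | "RCP2.6" | "RCP8.5"
    values: np.ndarray  # int16
    grid: GridSpec

    def __post_init__(self) -> None:
        valid = self.values != NODATA_INT
        if valid.any():
            lo = int(self.values[valid].min())
            hi = int(self.values[valid].max())
            if lo < 0 or hi > 100:
                raise ValueError(
                    f"suitability values out of range [0, 100]: {lo}..{hi}"
                )


@dataclass
class CombinedSuitability:
    """Per-pixel maximum suitability over a crop set."""

    values: np.ndarray  # int16, NODATA_INT for nodata
    grid: GridSpec
    crop_set: str  # "all23" | "food17"
    period: str
    scenario: str
    regime_policy: str = "current_irrigation"


def combine_regimes(
    rainfed: CropSuitabilityLayer,
    irrigated: CropSuitabilityLayer,
    irrigation_mask: np.ndarray,
    policy: str = "irrigated",
) -> CropSuitabilityLayer:
    """Merge rainfed and irrigated suitability under current irrigation
    patterns.

    With the default ``"irrigated"`` policy, pixels in the irrigation mask
    take the irrigated value and all others the rainfed value; nodata
    propagates from the selected layer only.  The alternative ``"max"``
    policy takes the elementwise maximum of the two layers on irrigated
    pixels.
    """
    check_same_grid(rainfed.grid, irrigated.grid)
    for attr in ("crop", "period", "scenario"):
        if getattr(rainfed, attr) != getattr(irrigated, attr):
            raise ValueError(
                f"layer key mismatch on {attr!r}: "
                f"{getattr(rainfed, attr)} vs {getattr(irrigated, attr)}"
            )
    if irrigation_mask.shape != rainfed.grid.shape:
        raise ValueError("irrigation mask shape does not match grid")
    mask = irrigation_mask.astype(bool)
    if policy == "irrigated":
        values = np.where(mask, irrigated.values, rainfed.values)
    elif policy == "max":
        both = np.maximum(rainfed.values, irrigated.values)
        # max() of a nodata pair must stay nodata, not -1-vs-x
        either_nodata = (rainfed.values == NODATA_INT) | (
            irrigated.values == NODATA_INT
        )
        both = np.where(
            either_nodata,
            np.where(
                rainfed.values == NODATA_INT, irrigated.values, rainfed.values
            ),
            both,
        )
        values = np.where(mask, both, rainfed.values)
    else:
        raise ValueError(f"unknown irrigation policy {policy!r}")
    return replace(
        rainfed, regime="current_irrigation", values=values.astype(np.int16)
    )


def max_over_crops(
    layers: Sequence[CropSuitabilityLayer],
    crop_set: str = "all23",
    members: Iterable[str] | None = None,
) -> CombinedSuitability:
    """Per-pixel maximum suitability over the layers whose crop belongs to
    ``crop_set``.  Pixels where every contributing layer is nodata stay
    nodata; all-zero pixels are 0 (unsuitable).

    ``members`` overrides the crop list of the named set (needed for worlds
    whose crops are not the canonical 23).
    """
    if not layers:
        raise ValueError("need at least one suitability layer")
    members = set(CROP_SETS[crop_set] if members is None else members)
    selected = [lyr for lyr in layers if lyr.crop in members]
    if not selected:
        raise ValueError(f"no layer belongs to crop set {crop_set!r}")
    ref = selected[0]
    for lyr in selected[1:]:
        check_same_grid(ref.grid, lyr.grid)
        if (lyr.period, lyr.scenario, lyr.regime) != (
            ref.period,
            ref.scenario,
            ref.regime,
        ):
            raise ValueError("mixed period/scenario/regime in crop stack")
    stack = np.stack([lyr.values for lyr in selected])
    valid = stack != NODATA_INT
    filled = np.where(valid, stack, np.int16(0))
    best = filled.max(axis=0)
    best = np.where(valid.any(axis=0), best, np.int16(NODATA_INT))
    return CombinedSuitability(
        values=best.astype(np.int16),
        grid=ref.grid,
        crop_set=crop_set,
        period=ref.period,
        scenario=ref.scenario,
        regime_policy=ref.regime,
    )


def argmax_crop(
    layers: Sequence[CropSuitabilityLayer],
    ordering: Sequence[str] = ALL23,
) -> np.ndarray:
    """Index (into ``ordering``) of the most suitable crop per pixel.

    Ties break to the crop earliest in ``ordering``; pixels whose maximum
    is 0 or nodata get ``NODATA_INT`` (no suitable crop).
    """
    if not layers:
        raise ValueError("need at least one suitability layer")
    order = {crop: i for i, crop in enumerate(ordering)}
    ranked = sorted(layers, key=lambda lyr: order[lyr.crop])
    ref = ranked[0]
    for lyr in ranked[1:]:
        check_same_grid(ref.grid, lyr.grid)
    stack = np.stack([lyr.values for lyr in ranked])
    filled = np.where(stack == NODATA_INT, np.int16(0), stack)
    best = filled.max(axis=0)
    winner_pos = filled.argmax(axis=0)  # first occurrence = earliest crop
    idx = np.array([order[lyr.crop] for lyr in ranked])
    out = idx[winner_pos].astype(np.int16)
    out[best <= 0] = NODATA_INT
    return out


def classify(values: np.ndarray | int) -> np.ndarray | int:
    """Map suitability 0-100 to SuitabilityClass codes; nodata passes
    through as ``NODATA_INT``."""
    arr = np.asarray(values)
    valid = arr != NODATA_INT
    if np.any((arr[valid] < 0) | (arr[valid] > 100)):
        raise ValueError("suitability values out of range [0, 100]")
    out = np.full(arr.shape, NODATA_INT, dtype=np.int8)
    out[valid & (arr < MARGINAL_MIN)] = SuitabilityClass.UNSUITABLE
    out[valid & (arr >= MARGINAL_MIN) & (arr < MODERATE_MIN)] = (
        SuitabilityClass.MARGINAL
    )
    out[valid & (arr >= MODERATE_MIN) & (arr < HIGH_MIN)] = (
        SuitabilityClass.MODERATE
    )
    out[valid & (arr >= HIGH_MIN)] = SuitabilityClass.HIGH
    if np.isscalar(values):
        return int(out[()])
    return out


def apply_threshold(
    combined: CombinedSuitability, threshold: int
) -> CombinedSuitability:
    """Zero out pixels with suitability strictly below ``threshold``.

    ``threshold=0`` is the identity; a pixel exactly at the threshold is
    kept.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    vals = combined.values.copy()
    if threshold > 0:
        cut = (vals != NODATA_INT) & (vals < threshold)
        vals[cut] = 0
    return replace(combined, values=vals)
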