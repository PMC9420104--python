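"""Crop sets used by the suitability analysis.

The inventory considers 23 globally important crops: 17 food, feed, fiber
and first-generation bioenergy crops, plus 6 second-generation bioenergy
crops (non-food energy crops).  The ``food17`` variant of every product
drops the second-generation crops, excluding land that is suitable only
for them.
"""

from __future__ import annotations

#: Food, feed, fiber and first-generation bioenergy crops (17).
FOOD17: tuple[str, ...] = (
    "barley",
    "cassava",
    "groundnut",
    "maize",
    "millet",
    "oilpalm",
    "potato",
    "rapeseed",
    "rice",
    "rye",
    "sorghum",
    "soy",
    "sugarbeet",
    "sugarcane",
    "sunflower",
    "summer_wheat",
    "winter_wheat",
)

#: Second-generation bioenergy crops (6).
SECOND_GENERATION: tuple[str, ...] = (
    "jatropha",
    "miscanthus",
    "switchgrass",
    "reed_canary_grass",
    "eucalyptus",
    "willow",
)

#: Canonical ordering of all 23 crops; also the tie-break order for the
#: most-suitable-crop product (earlier wins on equal suitability).
ALL23: tuple[str, ...] = FOOD17 + SECOND_GENERATION

CROP_SETS: dict[str, tuple[str, ...]] = {"all23": ALL23, "food17": FOOD17}


def crop_index(crop: str) -> int:
    """Position of ``crop`` in the canonical ordering."""
    return ALL23.index(crop)
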