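"""Pipeline configuration.

Every constant of the analysis is surfaced here rather than hard-coded:
suitability class bounds, the excluded land-cover codes, the protected-area
threshold, the Earth radius, the irrigation policy, the CDF smoothing
window and the sensitivity thresholds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .grid import EARTH_RADIUS_KM


INVENTORIES = ("suitable", "cultivable", "available")
REGIMES = ("rainfed", "irrigated", "current_irrigation")
RESOLUTIONS = ("native", "coarse", "country")
PRODUCT_PERIODS = ("1980-2009", "2010-2039", "2040-2069", "2070-2099")
SCENARIOS = ("historic", "RCP2.6", "RCP8.5")


@dataclass(frozen=True)
class ProductKey:
    """One cell of the product matrix: every inventory is published per
    period and scenario, under current irrigation patterns as well as
    rainfed and irrigated separately, for both crop sets, at native and
    coarse resolution and aggregated to country level.  The historic
    scenario pairs only with the historic period."""

    inventory: str
    period: str
    scenario: str
    regime: str = "current_irrigation"
    crop_set: str = "all23"
    resolution: str = "native"

    def __post_init__(self) -> None:
        if self.inventory not in INVENTORIES:
            raise ValueError(f"unknown inventory {self.inventory!r}")
        if self.period not in PRODUCT_PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.scenario == "historic") != (
            self.period == PRODUCT_PERIODS[0]
        ):
            raise ValueError(
                "historic scenario is valid exactly for the historic period"
            )
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.crop_set not in ("all23", "food17"):
            raise ValueError(f"unknown crop set {self.crop_set!r}")
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {self.resolution!r}")


@dataclass
class PipelineParams:
    earth_radius_km: float = EARTH_RADIUS_KM
    marginal_min: int = 1
    moderate_min: int = 33
    high_min: int = 75
    protected_threshold: float = 0.5
    water_snow_codes: tuple[int, ...] = (210, 220)
    wetland_code: int = 180
    irrigation_policy: str = "irrigated"  # or "max"
    smoothing_window: int = 5
    thresholds: tuple[int, ...] = (10, 20, 30)
    crop_sets: tuple[str, ...] = ("all23", "food17")

    def __post_init__(self) -> None:
        if not (0 < self.marginal_min <= self.moderate_min <= self.high_min
                <= 100):
            raise ValueError("class bounds must be ordered within 1..100")
        if not 0.0 <= self.protected_threshold <= 1.0:
            raise ValueError("protected threshold must lie in [0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("water_snow_codes", "thresholds", "crop_sets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
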