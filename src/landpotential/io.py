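"""GeoTIFF raster I/O and world-directory serialization.

Rasters are single- or multi-band GeoTIFFs in geographic (EPSG:4326)
coordinates, written through :mod:`tifffile` with the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL
nodata tag, so the files open in GDAL/QGIS.  The exact :class:`GridSpec`
is additionally embedded as JSON in the image description, which makes
the grid metadata round-trip bit-exactly regardless of the binary
representation of the pixel scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grid import GridSpec
from .masks import ExclusionLedger, SurfaceLayers
from .stats import ZoneMap
from .synthetic import WorldBundle, WorldConfig

logger = logging.getLogger(__name__)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORMATION = 34264
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

#: GeoKeyDirectory: GTModelType = geographic, GTRasterType = PixelIsArea,
#: GeographicType = EPSG 4326
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_raster(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float | int | None = None,
) -> None:
    """Write a 2-D (or 3-D band-stacked) layer as a GeoTIFF."""
    values = np.asarray(values)
    if values.shape[-2:] != grid.shape:
        raise ValueError(
            f"layer shape {values.shape} does not match grid {grid.shape}"
        )
    res = grid.res_deg
    desc = json.dumps(
        {
            "grid": {
                "lon_min": grid.lon_min,
                "lat_max": grid.lat_max,
                "n_rows": grid.n_rows,
                "n_cols": grid.n_cols,
                "resolution": grid.resolution,
            },
            "nodata": nodata,
        }
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(
        path,
        values,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
    )


def read_raster(
    path: str | Path,
) -> tuple[np.ndarray, GridSpec, float | int | None]:
    """Read a GeoTIFF written by :func:`write_raster` or a compatible tool.

    Returns ``(values, grid, nodata)``.  Rotated geotransforms and files
    without geographic referencing are rejected; a missing nodata tag reads
    as ``None`` with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_TRANSFORMATION in tags:
            raise ValueError(
                f"{path.name}: rotated/general geotransforms are not "
                "supported"
            )
        grid = None
        desc = tags.get("ImageDescription")
        nodata: float | int | None = None
        nodata_declared = False  # an explicit "no nodata" needs no warning
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                g = meta["grid"]
                grid = GridSpec(**g)
                nodata = meta.get("nodata")
                nodata_declared = "nodata" in meta
            except (json.JSONDecodeError, KeyError, TypeError):
                grid = None
        values = tif.asarray()
        if grid is None:
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise ValueError(
                    f"{path.name}: missing geographic referencing "
                    "(ModelPixelScale/ModelTiepoint)"
                )
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-12 * max(sx, sy):
                raise ValueError(f"{path.name}: non-square pixels")
            tie = tags[_TAG_TIEPOINT].value
            if tie[0] != 0 or tie[1] != 0:
                raise ValueError(f"{path.name}: tiepoint not at raster "
                                 "origin")
            n_rows, n_cols = values.shape[-2:]
            grid = GridSpec(
                lon_min=float(tie[3]),
                lat_max=float(tie[4]),
                n_rows=n_rows,
                n_cols=n_cols,
                resolution=sx * 3600.0,
            )
        if nodata is None and not nodata_declared:
            if _TAG_GDAL_NODATA in tags:
                raw = tags[_TAG_GDAL_NODATA].value
                nodata = float(raw)
                if nodata == int(nodata) and np.issubdtype(
                    values.dtype, np.integer
                ):
                    nodata = int(nodata)
            else:
                warnings.warn(
                    f"{path.name}: no nodata tag; assuming none",
                    stacklevel=2,
                )
    if values.shape[-2:] != grid.shape:
        raise ValueError(f"{path.name}: data shape does not match grid")
    return values, grid, nodata


def write_ledger(path: str | Path, ledger: ExclusionLedger) -> None:
    """Multi-band km^2 GeoTIFF (band order = ``ExclusionLedger.BAND_ORDER``)
    plus a JSON sidecar of global component totals."""
    stack = np.stack([ledger.components()[n] for n in ledger.BAND_ORDER])
    write_raster(path, stack.astype(np.float64), ledger.grid, nodata=None)
    sidecar = Path(path).with_suffix(".totals.json")
    sidecar.write_text(
        json.dumps(
            {"bands": list(ledger.BAND_ORDER), "totals_km2": ledger.totals()},
            indent=2,
        )
    )


def read_ledger(path: str | Path) -> ExclusionLedger:
    values, grid, _ = read_raster(path)
    if values.ndim != 3 or values.shape[0] != len(ExclusionLedger.BAND_ORDER):
        raise ValueError(f"{path}: expected "
                         f"{len(ExclusionLedger.BAND_ORDER)}-band ledger")
    comps = dict(zip(ExclusionLedger.BAND_ORDER, values))
    return ExclusionLedger(grid=grid, **comps)


# ---------------------------------------------------------------------------
# world directory


def write_world(bundle: WorldBundle, directory: str | Path) -> None:
    """Serialize a synthetic world: one GeoTIFF per layer, the country
    table as CSV and a YAML manifest (config + layer inventory)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layers: list[str] = []
    for (crop, regime, period, scenario), arr in bundle.suitability.items():
        name = f"suit_{crop}_{regime}_{period}_{scenario}.tif"
        write_raster(directory / name, arr, bundle.grid, nodata=-1)
        layers.append(name)
    surf = bundle.surfaces
    for name, arr, nodata in (
        ("landcover", surf.landcover, None),
        ("impervious_frac", surf.impervious_frac, float("nan")),
        ("forest", surf.forest.astype(np.uint8), None),
        ("cropland", surf.cropland.astype(np.uint8), None),
        ("protected_frac", surf.protected_frac, None),
        ("irrigation", surf.irrigation.astype(np.uint8), None),
        ("zones", bundle.zonemap.zones, -1),
    ):
        fname = f"{name}.tif"
        write_raster(directory / fname, np.asarray(arr), bundle.grid, nodata)
        layers.append(fname)
    bundle.zonemap.countries.to_csv(directory / "countries.csv", index=False)
    cfg = bundle.config
    manifest = {
        "seed": cfg.seed,
        "config": {
            "grid": {
                "lon_min": cfg.grid.lon_min,
                "lat_max": cfg.grid.lat_max,
                "n_rows": cfg.grid.n_rows,
                "n_cols": cfg.grid.n_cols,
                "resolution": cfg.grid.resolution,
            },
            "n_crops": cfg.n_crops,
            "n_secondgen": cfg.n_secondgen,
            "periods": list(cfg.periods),
            "scenarios": list(cfg.scenarios),
            "seed": cfg.seed,
            "land_fraction": cfg.land_fraction,
            "forest_fraction": cfg.forest_fraction,
            "wetland_fraction": cfg.wetland_fraction,
            "urban_fraction": cfg.urban_fraction,
            "protected_fraction": cfg.protected_fraction,
            "irrigated_fraction": cfg.irrigated_fraction,
            "cropland_fraction": cfg.cropland_fraction,
            "n_countries": cfg.n_countries,
            "smooth_sigma": cfg.smooth_sigma,
        },
        "layers": sorted(layers),
    }
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False)
    )


def read_world(directory: str | Path) -> WorldBundle:
    """Load a world written by :func:`write_world`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    cfg_raw = dict(manifest["config"])
    cfg_raw["grid"] = GridSpec(**cfg_raw["grid"])
    cfg_raw["periods"] = tuple(cfg_raw["periods"])
    cfg_raw["scenarios"] = tuple(cfg_raw["scenarios"])
    config = WorldConfig(**cfg_raw)
    grid = config.grid

    suitability: dict[tuple[str, str, str, str], np.ndarray] = {}
    for crop in config.crop_names():
        for regime in ("rainfed", "irrigated"):
            for period, scenario in config.scenario_keys():
                name = f"suit_{crop}_{regime}_{period}_{scenario}.tif"
                arr, g, _ = read_raster(directory / name)
                if g != grid:
                    raise ValueError(f"{name}: grid differs from manifest")
                suitability[(crop, regime, period, scenario)] = arr

    def _load(name: str) -> np.ndarray:
        arr, g, _ = read_raster(directory / f"{name}.tif")
        if g != grid:
            raise ValueError(f"{name}.tif: grid differs from manifest")
        return arr

    surfaces = SurfaceLayers(
        grid=grid,
        landcover=_load("landcover"),
        impervious_frac=_load("impervious_frac"),
        forest=_load("forest").astype(bool),
        cropland=_load("cropland").astype(bool),
        protected_frac=_load("protected_frac"),
        irrigation=_load("irrigation").astype(bool),
    )
    countries = pd.read_csv(directory / "countries.csv")
    zonemap = ZoneMap(grid=grid, zones=_load("zones"), countries=countries)
    return WorldBundle(
        config=config, grid=grid, suitability=suitability,
        surfaces=surfaces, zonemap=zonemap,
    )
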