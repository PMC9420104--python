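# landpotential

Global inventories of land **potentially suitable**, **potentially
cultivable** and **potentially available** for cropland, derived from
per-crop agricultural-suitability rasters and land-surface layers.

Land-use and integrated-assessment models need a consistent answer to the
question *where could cropland expand?*  This package computes three nested
global inventories from co-registered geographic rasters:

1. **Potentially suitable land** — pixels whose combined agricultural
   suitability *S* ≥ 1, excluding water bodies (land-cover code 210) and
   permanent snow/ice (220).  The combined suitability is the per-pixel
   maximum over a crop set, `S(x) = max_c s_c(x)`, where each crop's
   rainfed or irrigated value is selected according to current irrigation
   patterns.  Two crop sets are supported: all 23 food, feed, fiber and
   bioenergy crops, or the 17 crops excluding second-generation bioenergy
   crops.
2. **Potentially cultivable land** — suitable land minus its man-made
   impervious share (settlements, roads), removed fractionally per pixel:
   `cultivable = suitable · (1 − f_imp)`.
3. **Potentially available cropland** — cultivable land minus whole-pixel
   exclusions in a fixed hierarchy: strictly protected pixels (protected
   fraction ≥ 0.5, IUCN Ia/Ib/II), then forests, then uncultivated
   wetlands (code 180).

Every pixel's area (true spherical km², `A = R² Δλ (sin φ_N − sin φ_S)`)
is partitioned into an **exclusion ledger** whose conservation identities

    suitable   = excluded_impervious + cultivable
    cultivable = excluded_protected + excluded_forest
                 + excluded_wetland + available

hold exactly and are asserted on every run.  On top of the ledger the
package computes country/region inventory tables, suitability-class
breakdowns (marginal 1–32, moderate 33–74, high 75–100), cumulative
distribution functions, suitability-threshold sensitivity, climate-scenario
change maps and tables (RCP2.6 vs RCP8.5), and comparisons against
external estimates on coarser grids.

Because the real global inputs are tens of gigabytes, the package ships a
seeded **synthetic world generator** that emulates all input layers on a
small grid, plus an **independent per-pixel reference implementation**
(plain Python loops, no shared code) that serves as an exact oracle for
every pipeline product.

## Worked example

```python
import landpotential as lp

world = lp.generate_world(lp.WorldConfig(seed=42))   # 0.5°, 23 crops
result = lp.build_products(world)

inv = result.inventories[("1980-2009", "historic", "all23")]
glob = inv[inv.level == "global"].iloc[0]
print(f"suitable   {glob.suitable_km2/1e6:6.1f} M km2")
print(f"cultivable {glob.cultivable_km2/1e6:6.1f} M km2")
print(f"available  {glob.available_km2/1e6:6.1f} M km2")
print(result.sensitivity.round(2).to_string(index=False))
```

prints

```
suitable    135.7 M km2
cultivable  134.8 M km2
available    85.7 M km2
 threshold  reduction_pct  cropland_excluded_pct
        10           4.96                   5.41
        20           9.45                   9.62
        30          18.16                  19.33
```

Reading: on this synthetic world 135.7 million km² of land is suitable for
at least one crop; removing impervious surfaces leaves 134.8 million km²
cultivable, and additionally excluding protected areas, forests and
wetlands leaves 85.7 million km² potentially available for cropland.  The
sensitivity table shows how much suitable land (and how much of the
current cropland) a minimum-suitability threshold of 10/20/30 would
discard.

## Command line

```bash
landpotential synth --seed 2 --rows 90 --out world/
landpotential build --world world/ --out products/
landpotential sensitivity --world world/ --out sens.csv
landpotential change --world world/ --out change/
```

Rasters are GeoTIFFs (EPSG:4326, GDAL-compatible tags), tables are CSV,
and every run writes a JSON manifest with the config hash and global
totals.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, what
the synthetic generator does and does not emulate, and numerical choices.
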