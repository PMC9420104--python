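# Methods

## The three nested inventories

The pipeline classifies every pixel of a geographic grid into nested land
inventories by chaining three stages over co-registered rasters.

**Combined suitability.**  Input is one integer suitability layer (0–100,
nodata over ocean) per crop, water regime (rainfed/irrigated), time period
and climate scenario.  Per pixel, the regime is selected from the current
irrigation pattern: irrigated pixels take the irrigated value, all others
the rainfed value (an alternative `max` policy — irrigated pixels take the
maximum of both regimes — is available behind the `irrigation_policy`
parameter; the default reflects that an irrigated pixel is actually
operated under irrigation).  The combined suitability is then the maximum
over the crop set.  "Suitable" means combined value ≥ 1.  The `food17`
crop set drops the six second-generation bioenergy crops (jatropha,
miscanthus, switchgrass, reed canary grass, eucalyptus, willow), excluding
land suitable only for them.

**Suitable → cultivable.**  Suitable pixels that are water (code 210) or
permanent snow/ice (220) are removed first.  The impervious exclusion is
*fractional*: `excluded = suitable_area · f_imp`, so a pixel 25% covered
by settlement contributes 75% of its area to cultivable land.  A missing
impervious fraction is imputed as 0 and counted in the run log.

**Cultivable → available.**  Whole-pixel exclusions apply in a fixed
hierarchy, first match wins: (1) strictly protected (protected-area
fraction ≥ 0.5), (2) forest, (3) uncultivated wetland (code 180),
(4) otherwise available.  The hierarchy ordering makes the excluded-area
accounting unambiguous: a protected forest pixel counts as protected, and
its forest cover is reported separately for composition statistics.
Wetlands already drained and farmed carry the cropland code upstream, so
they pass through to the available inventory.

**Area model.**  Pixel areas are spherical:
`A = R² Δλ (sin φ_N − sin φ_S)` with R = 6371.0088 km (IUGG mean radius,
configurable).  This closed form is exact on the sphere; an authalic
(WGS84-equivalent) radius would shift global totals by well under 0.5%,
which is why a spherical model was adopted.  Grids are corner-registered
and north-up with half-open cells; resolution is stored in arc-seconds.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| class bounds | 1 / 33 / 75 | marginal 1–32, moderate 33–74, high 75–100 |
| `protected_threshold` | 0.5 | pixel protected-fraction at or above which it is strictly protected |
| `water_snow_codes` | (210, 220) | land-cover codes removed from the suitable inventory |
| `wetland_code` | 180 | uncultivated-wetland code |
| `irrigation_policy` | `irrigated` | regime selection on irrigated pixels |
| `smoothing_window` | 5 | centered moving-average window of the CDF/profile area series (edge-truncated) |
| `thresholds` | (10, 20, 30) | suitability cutoffs evaluated by the sensitivity analysis |
| `earth_radius_km` | 6371.0088 | spherical Earth radius |

All of these are surfaced in `PipelineParams` (YAML round-trip) — nothing
is hard-coded in the stages.

## Zonal statistics and derived tables

Country sums use the zone raster and per-row pixel areas; region rows are
the exact sums of their member-country rows and the global row the exact
sum of the region rows (plus any unassigned land), so the partition
identity holds bit-for-bit, not just to rounding.  Land pixels without a
country id are collected into an `UNASSIGNED` row with a warning.

"Already cultivated" intersects each inventory with the current-cropland
flag and weights by the inventory's per-pixel area, so fractional
impervious exclusions carry through; overlap shares are reported relative
to the inventory's total.

The CDF table bins a ledger component by integer suitability value and
normalizes the cumulative sum by the component total; it is nondecreasing
and closes at 100% by construction.  Smoothing is a centered moving
average with edge truncation (the window shrinks near values 1 and 100);
the smoothed series is display-oriented and conserves the total only in
the interior.

Threshold sensitivity reports, for each cutoff t, the share of suitable
area (suit ≥ 1) with suitability < t, and the analogous share over
current-cropland pixels.  The cropland column is normalized by the
suitable cropland area, so it reaches 100% at t = 101.

## Scenario change

A pixel is "cultivable" for change classification when its cultivable
area is positive — no minimum-area cutoff is applied, consistent with the
fractional impervious rule (a pixel loses cultivability only when its
suitability drops to 0 or it is fully impervious).  Gains and losses
between the historic and a future period are resolved across RCP2.6 and
RCP8.5 into eight categories that partition all land pixels.  Change
tables report percentage change per region and suitability class; a zero
historic baseline yields NaN (undefined), never infinity.

For comparisons with an external coarse-resolution estimate, the native
cultivable areas are summed onto the external grid (area-conserving).
The surplus in each coarse cell — area present here but not in the
external estimate — is attributed to suitability classes proportionally
to the native-resolution class mix inside that cell.  The external raster
is compared as-is; no adjustment for nonproductive subpixel uses is
applied to either side.

## The synthetic world

The generator emulates the statistical structure the pipeline assumes, on
a 0.5° global grid by default (360 × 720), with one seed fixing all
randomness:

- **Smooth fields** are Gaussian-filtered white noise, rank-normalized to
  [0, 1], periodic in longitude — this supplies the spatial
  autocorrelation of real climatic and edaphic fields.
- **Covers** (ocean, cropland, forest, wetland, polar snow, other) are
  mutually exclusive states assigned by thresholding independent smooth
  fields at the configured target fractions (defaults: land 29% of the
  globe; of land: forest 31%, cropland 11%, wetland 3% — the observed
  global orders of magnitude).  Impervious (1.5% of land, urban blobs),
  protected (5% of land at fraction ≥ 0.5) and irrigation (7% of land)
  are independent overlays.  Cultivated wetlands are encoded as cropland,
  so the pass-through rule is exercised.
- **Suitability** per crop combines a latitudinal climate optimum
  (Gaussian ridge in |lat|), a crop-independent fertility field (weight
  0.7) plus a per-crop field (0.3), and an aridity penalty on rainfed
  values that the irrigated variant compensates.  The shared fertility
  keeps per-crop values correlated, so the cross-crop maximum does not
  saturate; the coefficients were set so the suitable land splits into
  roughly 30% marginal / 55% moderate / 12% high, the composition regarded
  as realistic for a global suitability surface.
- **Warming** moves each crop's ridge poleward — by 2070–2099, 3° under
  RCP2.6 and 8° under RCP8.5, linearly interpolated across intermediate
  periods — and slightly widens the band, so high-latitude gains outweigh
  warm-edge losses: the agricultural frontier expands poleward, more
  strongly under the high-emission scenario.
- **Countries** are a nearest-seed partition of the land pixels (12 by
  default), each mapped to one of six reporting regions.

What the generator does **not** emulate: real geography and coastlines,
the co-location of soils, climate and land cover (covers are placed
independently of suitability, so the synthetic cultivable share of land is
higher than observed), subpixel land-cover mixtures, and the fuzzy-logic
mechanics that produce real suitability surfaces.  Passing tests therefore
demonstrate the correctness of the accounting, aggregation and change
logic under known ground truth — not the realism of any particular global
number.

## Verification strategy

An independent reference implementation recomputes every product with
literal per-pixel Python loops — regime selection, crop maximum, exclusion
hierarchy, zonal sums — sharing no array code with the pipeline, and
rederiving pixel areas from the closed form with `math` only.  The test
suite requires the pipeline to match it bit-for-bit on integer layers and
to 1e−9 relative on area sums, across five full-scale seeded worlds.
Analytic checks anchor the area model (full-sphere total = 4πR², band
sums against the closed form), and property tests cover the conservation
identities, inventory nesting, CDF/sensitivity monotonicity, the change
partition and crop-set dominance.

## Numerical choices and degenerate inputs

- Integer nodata is −1; fraction layers use NaN.  Arithmetic with nodata
  yields nodata, except area sums, which skip it.
- Categorical aggregation breaks area ties to the lowest class code; the
  most-suitable-crop product breaks ties by the canonical crop ordering.
- The ledger's second identity is computed as
  `available = cultivable − excluded…`, making both identities exact in
  floating point, with a validation tolerance of 1e−12 relative to the
  largest pixel area.
- `apply_threshold` keeps values exactly at the threshold; threshold 0 is
  the identity.
- All-ocean worlds produce identically zero ledgers; empty countries
  produce all-zero rows; empty CDF components and worlds without suitable
  area raise errors rather than emitting undefined shares.
- Problem sizes: unit tests run on a 5° grid (36 × 72) with 5 crops;
  full-scale verification and the acceptance script use the default 0.5°
  grid (360 × 720) with 23 crops × 2 regimes × 3 period/scenario keys,
  about 7 s per world end-to-end including the reference implementation.

## Known limitations

- Whole-pixel forest/wetland exclusions inherit the binary input
  granularity; only the impervious exclusion is fractional.
- Streaming row-block processing is not implemented; layers are held in
  memory, which is ample for the synthetic scale but would need chunking
  at a true 30 arc-second global grid.
- Scenario products cover climate-driven suitability change only; land
  cover, protection status and impervious surfaces are held at their
  reference state across periods.
- Projected coordinate systems and rotated geotransforms are out of
  scope; rasters must be north-up geographic grids.
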