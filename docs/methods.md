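# Methods

## Scope and data model

The package analyzes categorical land-cover change between epochs on
co-registered rasters, overlays the detected change with conservation
polygons, and summarizes biodiversity exposure. It operates on two kinds of
inputs interchangeably: real land-cover products read from disk (harmonized
through shipped legend tables) or synthetic landscapes generated internally
with known ground truth. All raster I/O uses ESRI ASCII grids plus a JSON
sidecar for the attributes the header cannot carry; vector layers use
GeoJSON. Both are plain text, diff-able and GIS-readable.

## Harmonization

Each product's native legend maps totally onto six harmonized codes:
CULTIVATED, GRASS_SHRUB, NONFOREST_WETLAND, FOREST, OTHER, NODATA. The four
analysis classes are the first four; OTHER absorbs water, ice, bare ground,
built-up and tundra. Key rules encoded in the shipped YAML tables:

- GLCLUC separates vegetation by height: tree cover ≥ 5 m (including
  forested wetlands) is forestland; shorter vegetation is grass/shrub on
  terra firma and non-forested wetland in the wetland stratum, as is open
  surface water present 20–79% of the year.
- GLC_FCS30D's swamp and mangrove are woody and count as forestland, which
  is conservative for non-forested wetland extent; its cropland includes
  tree crops.
- GlobeLand30 cannot split forested from non-forested wetland, so its whole
  wetland class is non-forested wetland and never forestland; its cultivated
  class includes cultivated pasture.
- Tundra maps to OTHER in every product rather than to grass/shrub, because
  the products classify it inconsistently.

Tables are data, not code: native integer legends differ between product
versions, so each YAML names the legend it was built against and can be
edited without touching the package. The GLCLUC table ships with one
representative code per stratum group; a run against the real product should
regenerate it from the full 0–255 strata. Harmonization preserves geometry,
nodata placement and the valid-cell count, and errors on any unmapped code,
naming it and its cell count.

## Transition detection and accounting

Two harmonized epochs of one dataset are compared cell-wise. Natural →
cultivated cells are coded by source class (CONV_GRASS, CONV_WETLAND,
CONV_FOREST); cultivated → natural is REVERSION, a diagnostic counterpart
used to gauge spurious change; identical classes are STABLE; everything else
is OTHER_CHANGE. A cell that is nodata in either epoch is nodata in the
transition raster and excluded from every numerator and denominator — the
symmetric choice that avoids biasing rates where coverage differs between
epochs.

Areas are in hectares. Equal-area grids (local metric grids, or Mollweide
for real products) use the constant (cell size)²/10⁴; geographic grids use
the exact spherical quadrangle area R²·Δλ·(sin φ_n − sin φ_s) with the
authalic radius 6 371 007.181 m. Zone assignment and polygon rasterization
both use cell-center containment, so partial boundary cells are attributed
unambiguously and identically everywhere. Coarse-grid summaries (the 10 km
analysis scale on real data) partition the raster into blocks anchored at
the raster origin; ragged edge blocks are kept and normalized by their own
valid-cell counts.

Multi-period spans are merged so a cell counts as converted over the full
span if it converted in either period, with the earlier period's code
winning. Because a cell that converted in the first period is cultivated at
the start of the second, per-period conversion sets are disjoint and the
combined conversion area equals the sum of the per-period areas — the
additivity the pipeline tests assert.

## Hotspots

Hotspot cells: per-cell converted areas are averaged across datasets, cells
are sorted descending (ties broken by ascending cell id for determinism),
and the minimal prefix reaching the coverage threshold (default 90% of the
global total) is selected. Hotspot countries: zones are ranked per dataset
by non-forest conversion area; a zone in the top k (default 10) for at least
`min_datasets` (default 2) datasets is flagged, and the table is ordered by
cross-dataset mean. Zones absent from a dataset's table count as zero area
there, since absence means no detected conversion. The transition codes
included are a parameter; the default is the two non-forest conversion
codes.

## Protected areas

IUCN categories I–VI are analyzed; Ia/Ib collapse into I. Marine-flagged
polygons are excluded from land analyses. Where PAs of different categories
overlap, a cell is attributed to the strictest (lowest-numbered) category —
a deterministic convention. Year filtering keeps PAs established strictly
before the cutoff; PAs with unknown establishment year cannot satisfy
"established before" and are excluded and counted in the run report.
Per-period category shares use period-specific cutoffs; the full-span rate
analysis uses the first period's start year.

Rates are class-conditional: converted area of a natural class inside a
category's PAs divided by that class's initial-epoch area inside the same
PAs, with an OUTSIDE row over the complement of all PAs. Zero-baseline
combinations are flagged undefined rather than reported as zero. These are
descriptive overlay statistics; land inside and outside PAs differs
systematically in accessibility and suitability, so rate differences must
not be read as causal PA effectiveness.

## Biodiversity

Species carry a taxon (amphibian, mammal, reptile, bird), a Red List code,
and a habitat-affinity set restricted to the three natural classes; only
VU/EN/CR species are analyzed. Richness is counted on a coarse equal-area
square grid — a deliberate simplification of hexagonal ecological grids
that keeps the semantics (distinct species whose range intersects the cell)
while avoiding a tessellation dependency — optionally restricted to
consensus cells, i.e. coarse cells where every dataset detects conversion.
Coarse resolution is used because conversion threatens biodiversity beyond
the converted pixel itself.

A species is affected when its range polygon has a positive-area
intersection with at least one converted cell; pure boundary contact does
not count. This is the one place the cell-center rule is not used, because a
range map asserts potential presence over an area, not per-pixel occupancy.
Affected species are counted once per taxon and once per focal class in
their habitat set under the bucket named by the size of that set (endemic /
two / three) — so a two-habitat species appears under both of its classes,
and per focal class the three buckets partition its affected species
exactly. The affected-species computation runs against one designated
dataset (configurable; defaults to the first), since cross-dataset
differences at pixel scale are small relative to range extents. KBA tables
report, per zone and class, conversion inside KBAs, inside PAs, and inside
KBAs but outside all PAs (the protection gap), using the same cell-center
masks.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, not
remote-sensing physics. Time-zero maps are Gaussian random fields smoothed
at the scenario's autocorrelation range (default 8 cells) and sliced at the
class-proportion quantiles by rank, which yields contiguous patches with
proportions exact up to integer rounding. Defaults: 200×200 cells of 100 m
(1 ha) on a local equal-area grid; class mix 25% cultivated, 30%
grass/shrub, 5% non-forested wetland, 30% forest, 10% other, mirroring the
ordering of the real extents (grass/shrub and forest large, wetland small).

Epoch transitions are applied independently per cell from a row-stochastic
matrix; defaults are 10% grass/shrub, 5% wetland and 3% forest converting
to cultivated per decade, with 2% reversion — chosen so that conversion is
pervasive enough to exercise every overlay yet class-conditional rates
remain exactly binomial, giving recovery tests closed-form 3-SE error bars.
Real conversion clusters spatially along agricultural frontiers; the i.i.d.
choice is a deliberate simplification that keeps the null hypothesis of the
inside-vs-outside PA comparison exactly true by construction. Passing tests
therefore demonstrate that the overlay machinery introduces no artefactual
PA effect — not that real landscapes lack one.

PA and KBA polygons are rectangles with corners snapped off cell-boundary
multiples so partial-cell overlay decisions are exercised; placement rejects
candidates overlapping an accepted PA by more than 50%, warning if fewer
polygons fit. Zones are vertical strips cut at random integer cell columns:
an exact partition whose edges can never coincide with cell centers.
Species ranges are buffered random points clipped to the extent, with
threatened fraction 0.6 and habitat-set sizes drawn with probabilities
0.5/0.3/0.2 for one/two/three classes.

All randomness flows from the single scenario seed through named substreams
(field, nodata, transitions, PAs, KBAs, zones, species), so any layer is
reproducible independently and the whole output is bit-identical across
runs and platforms. Multi-dataset runs realize the same scenario
independently per dataset style from per-dataset substreams: the datasets
agree statistically but disagree pixel-wise, emulating real cross-product
disagreement with known margins.

What the generator does not emulate: classification error processes,
spatially clustered change (available as future work; the matrix applies
i.i.d.), 30 m global extents, multipolygon country geometries, and realistic
range-size distributions. Conclusions from synthetic runs therefore validate
the accounting machinery, not the ecological realism of any particular
number.

## Numerical choices

- Ties in hotspot ranking break by ascending cell/zone id; all sorts are
  stable.
- CSV floats are serialized with 6 significant digits so reruns diff clean.
- Transition sampling guards the u≈1 float edge by clipping the searchsorted
  index into the destination range.
- Geographic cell areas use the exact spherical formula rather than a
  cosine-midpoint approximation; the two differ at the 4th decimal for 0.5°
  cells, but the exact form costs nothing.
- Zero-conversion hotspot inputs and zero-baseline rates return empty/NaN
  with warnings or flags, never silent zeros.

## Test problem sizes

Oracle-equivalence checks run exhaustive per-cell loops on 60×60–80×80
landscapes, where brute force is exact and fast. Parameter-recovery and
null-effect checks use 100 replicates of 200×200 and 120×120 landscapes
respectively — large enough that 3-SE binomial bands are a few tenths of a
percentage point wide, small enough that the full suite runs in tens of
seconds. Hotspot logic is verified against exhaustive search on 2 000
randomized tables.

## Known limitations

- No tiled/out-of-core processing: real 30 m global products must be
  windowed or down-sampled upstream.
- No design-based (sampling) area estimation with confidence intervals;
  areas are pixel-count aggregates.
- The coarse richness grid is square, not hexagonal.
- Zone grouping into aggregates (e.g. the EU) is a post-processing step on
  area tables from a user-supplied grouping file, not built-in geometry
  dissolution.
- Inside/outside PA comparisons are descriptive; no matching or causal
  design is implemented.
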