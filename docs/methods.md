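# Methods

## The mapping model

The package treats irrigation mapping as a constrained allocation
problem. For each administrative region and year, the reported
irrigated area `Area_c` (hectares) is taken as the binding constraint on
*extent*; a per-pixel **rank field** supplies the *location*
information. Two rank fields are used in sequence:

1. **Annual peak greenness index** (step one). GI = ρ_NIR / ρ_green is
   a chlorophyll-sensitive greenness measure; its annual maximum is a
   proxy for peak biomass, and irrigated crops — supplied with water
   through dry spells — reach systematically higher peaks than rainfed
   crops in the same region. Pixels with green reflectance ≤ 1e-6 or
   missing bands are invalid.
2. **Multi-product agreement score** (step two). Given N binary
   irrigation products in a descending weight order (rank 1 = most
   trusted), a pixel's agreement vector is mapped to an integer score
   in 0..2^N − 1. Scores order pixels primarily by agreement level
   (how many products say "irrigated") and secondarily by which
   products agree, higher-weighted products counting for more. The
   weight order is an expert input, not something the software infers.

### The allocator

Within a region, cropland pixels are grouped by distinct rank value in
descending order and cumulative areas `Area_1, Area_1+Area_2, …` are
formed (pixel area default 25 ha: a 500-m grid cell). The chosen
threshold is the level whose cumulative area minimizes
`|cumulative − Area_c|`; every pixel at or above it is labeled
irrigated. Decisions fixed here:

- **Tie groups are atomic.** All pixels sharing the threshold value are
  taken together, even when splitting the group would match the target
  better. This keeps the output an exact superlevel set of the rank
  field.
- **Equidistant tie-break: the smaller cumulative area** (higher
  threshold) wins. This is deterministic and conservative, appropriate
  given that reported statistics tend to underestimate true irrigated
  extent; it also makes the selected set nested (monotonically growing)
  in the target.
- **Zero target ⇒ empty selection; target ≥ total cropland area ⇒ the
  whole region's cropland.** The empty set is never a candidate for a
  positive target: the iteration always starts at the top rank level.
- Continuous rank fields group by exact value; an optional quantization
  (e.g. round GI to 3 decimals, the pipeline default) emulates discrete
  index levels and makes tie groups meaningful for float fields.

The allocator's achieved area deviates from the target by at most half
the area of the largest tie group whenever the target lies between the
first and the last cumulative area; outside that range it is clamped to
the nearest reachable extent.

### The score table

For five products the canonical published 32-entry table is embedded
verbatim (`mode="paper5"`). Its ordering *within* agreement level 3
does not follow the descending-lexicographic rule that levels 2 and 4
obey, so no single generation rule reproduces it; whether that ordering
is intentional is undecidable from the source material. We therefore
keep the canonical table as the default and provide
`mode="systematic"` — vectors sorted by (agreement level descending,
vector descending lexicographically with the rank-1 product most
significant), scored 2^N − 1 … 0 — as the clean generalization for any
N. The two modes agree everywhere except within level 3; both guarantee
that any level-k vector outscores any level-(k−1) vector and that
adding an agreeing product always raises a pixel's score.

## Smoothing

GI series are smoothed with a Savitzky–Golay filter before the annual
peak is taken. Window 7 composites (56 days) and polynomial order 2 are
the defaults — a common choice for 8-day vegetation-index series that
suppresses single-composite outliers while preserving the seasonal
peak; both are configurable. Ends are handled by evaluating the
polynomial fitted to the edge window, so series length is preserved and
polynomials up to the filter order pass through exactly. Missing
composites are linearly interpolated over time before filtering and
re-masked afterwards. The annual peak is taken over the calendar year
(no growing-season window).

## Statistics preparation

Area series per region are completed by linear interpolation between
the nearest reported years; leading/trailing gaps take the nearest
reported value (constant extrapolation — interior interpolation has no
defined counterpart at the edges, so the least-assuming rule is used).
County-level records take priority; when only a municipal or provincial
total exists, it is apportioned to counties in proportion to their
cropland pixel counts, which conserves the coarse total exactly and
keeps the allocator's per-region contract uniform. A pass-through mode
(treat the coarse region as one allocation unit) is available. The
fallback order is strictly county → municipal → provincial. Internal
unit is hectares; a unit factor converts inputs recorded in other units.

## Accuracy assessment

With irrigated as the positive class: PA = tp/(tp+fn),
UA = tp/(tp+fp), OA = (tp+tn)/n, F1 = 2·PA·UA/(PA+UA), and Cohen's
kappa with the standard two-class chance agreement
p_e = [(tp+fn)(tp+fp) + (fp+tn)(fn+tn)]/n². Zero-denominator metrics
are reported as NaN with a warning, never as a silent zero. Reports
round to 3 decimals. Samples given as coordinates map to the containing
cell; no interpolation.

## Trend analysis

Yearly binary maps are block-averaged by an integer factor (default 12:
500 m → 6 km) into irrigated fractions; edge blocks that do not divide
evenly average their existing pixels only. Each cell's fraction series
is regressed on calendar year (OLS; two-sided t-test on the slope,
n − 2 df). Cells are masked when p > 0.05 or the maximum fraction over
the record is below 5%. The fraction denominator is all pixels of the
block by default; a cropland-denominator mode divides by the block's
cropland fraction instead (cells without cropland are masked). A
constant series is reported as slope 0, p = 1. No multiple-testing
correction is applied across cells — a faithful-but-naive per-cell
rule, stated as such.

## Synthetic landscapes

The generator emulates exactly the regularities the method relies on,
nothing more:

- **Structure.** Regions are a Voronoi partition of seeded points;
  cropland and irrigated truth are thresholded smoothed Gaussian noise
  fields (smoothing sigma 3 pixels by default), so masks are spatially
  clumped the way real agricultural landscapes are — which matters
  because allocator tie behaviour differs on clumped versus
  salt-and-pepper truth. Fractions are hit exactly at pixel resolution
  (defaults: 50% cropland, 40% of cropland irrigated).
- **Signal.** Each cropland pixel follows a Gaussian-in-time seasonal
  GI curve over the 46 composites, rising from a baseline of 1.0 to a
  class peak of 6.0 (irrigated) or 4.0 (rainfed) at composite 23 with
  width 5 composites, plus i.i.d. noise (sd 0.5 by default, i.e. the
  class peaks sit 4 noise-sd apart). Only the annual peak matters
  downstream, so any unimodal shape would do. Non-cropland pixels are a
  flat low profile. GI is clipped at zero.
- **Statistics.** Reported areas are the true per-region areas times a
  configurable bias (default 1.0; values < 1 emulate the documented
  tendency of reported statistics to underestimate).
- **Products.** Each product is the truth with irrigated pixels dropped
  at a per-product omission rate and rainfed cropland pixels added at a
  commission rate. Default rates grow from (0.05, 0.03) for product A
  to (0.25, 0.15) for product E, consistent with the descending weight
  order.
- **Determinism.** One root seed; every operation derives its own
  child stream (keyed by operation and year), so regions and cropland
  persist across years while truth, noise and product errors re-draw,
  and every layer is bit-reproducible.

What the generator does *not* emulate: cloud contamination and QA
flags, mixed pixels and sub-pixel area fractions, spatially correlated
product errors, administrative-boundary changes over time, and
reporting errors that vary by region. Passing tests therefore
demonstrate the correctness of the algorithms under the model's own
assumptions — higher peak GI for irrigated pixels, area-faithful
statistics, independent product errors — not the accuracy attainable on
real satellite and census inputs, which depends on how far those
assumptions hold.

## Problem sizes and numerical choices

The test suite exercises the full pipeline on 200×200-pixel, 10-region
scenes (one composite year ≈ 1.8 M values), the scale at which every
statistical check (binomial tolerances, class-separation CLT bounds)
is comfortably sharp; individual operations are verified against
enumeration and closed-form oracles on instances up to 200 pixels where
exhaustive search is exact. Grids share one lattice by construction;
heterogeneous coordinate systems are refused rather than reprojected,
and a nearest-neighbour alignment utility handles resolution changes on
a common CRS (boundary ties resolve to the containing cell). Pixel
area is explicit configuration (default 25 ha for a 500-m grid) rather
than being derived from geographic coordinates.

## Known limitations

- The allocator matches each region-year independently; no temporal
  consistency is imposed across years.
- Fusion assumes co-registered binary inputs; resampling products from
  other grids is limited to nearest-neighbour on a shared CRS.
- Kappa uses the standard two-class formula; published figures computed
  with a nonstandard single-class variant would differ.
- The canonical score table is specific to N = 5; other N use the
  systematic ordering.
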