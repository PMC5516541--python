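# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It describes what the code computes and why
the defaults are what they are; every number quoted here is produced by
the test suite or `scripts/acceptance.py`, not asserted from elsewhere.

## Standard schema and table harmonisation

All subnational age/sex information is reduced to one row per
administrative unit: 14 age-group percentages (`A0004` … `A6064`,
`A65PL`, the last open-ended at 65) and a two-way sex split
(`MPROP`/`FPROP`), both summing to 100. Units are keyed by the
(`NAME`, `ADM_NAME`) composite, with a numeric `unit_id` index added for
joins to boundaries.

Raw tables arrive as counts or percentages over single-year or
multi-year bins with an open top bin anywhere at or above 65. Rebinning
requires every raw interval to nest inside a single standard bin;
intervals at or above 65 all collapse into `A65PL` (gaps above 65 are
tolerated since they collapse anyway, e.g. 65–69, 70–74, 80+ with no
75–79 bin). An interval that straddles a 5-year boundary (say ages 3–7)
is rejected with an explicit error: splitting it would require an
interpolation model the data do not support, and failing loudly was
preferred over guessing. Counts are conserved exactly under rebinning;
conversion to percentages happens at full precision, with rounding to
one decimal only on CSV export. The QA sum checks use a tolerance of
0.15 percentage points, sized to absorb the worst-case accumulation of
1-decimal rounding over 14–16 addends.

When a raw table carries no sex breakdown, `MPROP`/`FPROP` default to
50/50 rather than being left missing, so downstream sex-split stages
remain total; tables with real sex counts never hit this branch.

## Tabulation estimators

**Census microdata** are tabulated with the binary-indicator workflow:
one 0/1 indicator per (age group, sex) cell per person row, summed by
unit, divided by the unit's record count. Weights and de-facto flags are
ignored by this estimator (each record counts 1). The implementation is
deliberately the indicator-matrix construction rather than a library
cross-tabulation; an independent pandas pivot-table oracle checks
equivalence in the tests, keeping implementation and oracle distinct.

**Household surveys** use the weighted de-facto estimator: rows whose
de-facto flag is false are dropped first, then each person contributes
its sampling weight to its (unit, group, sex) cell, and percentages
divide by the unit's de-facto weight sum. The estimator reduces exactly
to the census estimator under constant weights and is invariant to
per-unit weight rescaling. A unit whose de-facto weight sum is zero is
an error, not an imputation — the upstream sources give no rule for such
units. Stratum and PSU identifiers are carried through for reporting
only: point estimates are what feed the maps, and no variance or CI
estimation is attempted (a deliberate non-goal).

Ages must be nonnegative integers at load; any age ≥ 65 maps to the open
bin regardless of magnitude.

## Dependency ratios

With `pc0_14`, `pc15_64`, `pc65` the young, working-age and old
population shares of a unit,

- `YDR = pc0_14 / pc15_64 × 100`
- `ODR = pc65 / pc15_64 × 100`
- `CDR = (pc0_14 + pc65) / pc15_64 × 100 = YDR + ODR` (exact identity).

The combined ratio is computed as the sum of the parenthesised
numerator over the working-age share — the formulation consistent with
the prose definition and with additivity.

When all 14 fields of a row are present, `pc15_64` is the explicit sum
of the ten middle fields (with a warning if the row fails the 100-sum
QA); the complement `100 − pc0_14 − pc65` is used only when middle
fields are missing, as for the packaged partially-printed Bhutan table.
A zero working-age share raises an explicit undefined-ratio error rather
than returning infinity. Ratios are scale-invariant (fractions or
percentages give identical results) and are exported at 2 decimals,
computed at full precision.

National aggregation weighs unit *triples* by unit population and takes
ratios of the aggregated triple — never the mean of unit ratios, which
is a different (and wrong) statistic. Countries with no subnational
source get the same formulas applied to their national structure,
flagged admin level 0, yielding a spatially constant surface within the
country mask.

## Grid model and rasterisation

All layers share one axis-aligned WGS84 grid template (west/north
origin, square cell size in degrees, row/column counts); the default
resolution is 30 arc seconds (1/120°, ≈1 km at the equator). Alignment
is bit-exact by construction — every output layer carries the template
unchanged, and no resampling exists anywhere in the pipeline; cellwise
map algebra is therefore well defined.

Rasterisation assigns each cell the attribute of the polygon containing
its center. Containment is tested boundary-inclusive with
first-polygon-wins ordering, so a center lying exactly on a shared edge
deterministically goes to the polygon earliest in file order. Cells
covered by no polygon get the nodata sentinel (−99999.0; zero is a legal
data value). Proportions are stored as fractions in [0, 1] in rasters
and as percentages in tables, converted only at the table→raster
boundary.

Population adjustment multiplies each country's cells by
`target / current_sum` from the ISO-code mask; disaggregation is the
cellwise product of proportion layers and the adjusted population
surface, with the age-proportion stack checked to sum to 1 (tolerance
1e−6) wherever data exist and nodata propagated. Because rasters are
in-memory numpy arrays, serialisation uses the plain-text ESRI ASCII
grid format, which round-trips the template and values exactly enough
for the conservation tolerances used here and is readable by standard
GIS tools; boundaries are GeoJSON.

## Synthetic country generator

The generator defines the study conditions under which the pipeline is
validated.

- **Geometry**: the grid extent is tiled exactly by rectangular admin-2
  units nested in horizontal admin-1 bands; non-divisible partitions are
  errors naming the offending dimension.
- **Age structure**: each unit's pyramid is a single-parameter
  exponential over bin index, `p_g ∝ exp(−ρ·g)`, `g = 0…13` — the
  simplest model producing realistic monotone pyramids with a
  closed-form (geometric series) oracle; ρ = 0 is the uniform limit and
  the young-age dependency ratio is strictly increasing in ρ. Default
  unit values of ρ are drawn uniformly on [0.05, 0.30] and the male
  share on [0.48, 0.53], realistic magnitudes for high-fertility
  settings.
- **Realized truth**: unit populations apportion the country total over
  lognormal(0, 0.4) unit weights by largest remainder; each unit's
  population is then apportioned over its 28 model (bin, sex) cell
  probabilities by largest remainder. The operative ground truth is this
  integer composition, with proportions defined as counts/population —
  so full enumeration reproduces the truth to machine precision, while
  the exponential model is matched to within half a person per cell
  (and the model's exactly-uniform sex split to within one person per
  cell).
- **Population grid**: each unit's population is spread over its cells
  by a seeded multinomial over Dirichlet(2) cell weights (or uniformly
  on request), so per-unit zonal sums equal unit populations exactly.
- **Census microdata**: per-unit sample sizes are Binomial(population,
  fraction), default fraction 5% (within the 2–15% range typical of
  census microdata samples); persons are drawn without replacement from
  the realized composition (multivariate hypergeometric over cells), so
  fraction 1 is exact enumeration. Integer ages are uniform within the
  person's bin (open bin: uniform on 65–84); rebinned results are
  invariant to this placement by construction.
- **Survey microdata**: strata are admin-1 units; the default two-stage
  design samples 10 of 50 PSUs per stratum, then 15 of 40 households
  per PSU, household size 1 + Poisson(4), giving ~1,500 persons — DHS-like
  magnitudes scaled to a small synthetic country (real survey design
  parameters vary widely and are not calibrated to any specific survey).
  Every person carries the constant design weight 1/(π_psu·π_hh) = 13.33,
  stratum and PSU identifiers, and a Bernoulli(0.95) de-facto flag.
  Person (age, sex) cells are i.i.d. from the stratum's aggregated
  pyramid, which makes the weighted estimator exactly design-unbiased;
  the de-facto filter drops members independently of age and so
  preserves unbiasedness.
- **Seeding**: one global seed; each generator stage draws from a
  substream derived by a fixed offset, so stages can be regenerated
  independently and identical spec + seed gives byte-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic fertility/mortality schedules,
household age clustering (ages are i.i.d., so design effects from
within-household correlation are absent and survey variance is
understated), kinship structure, non-rectangular boundaries, and
systematically undersampled groups. The recovery results certify the
estimators and the plumbing, not the field accuracy of any real survey.

## Problem sizes and observed results

The conservation audit runs on a 200×200-cell country (8 units, one
million persons): the summed 28-layer age/sex stack reproduces the
adjusted population raster with max cellwise relative deviation ~6e−16
and national totals exact to float precision, against a tolerance of
1e−6. The census route at fraction 1 recovers true proportions with
max error 0.0 (threshold 1e−9, percent scale). The survey route,
averaged over 500 seeded replicates of the default design, shows max
absolute per-cell bias ≈ 0.07–0.11 percentage points across seeds
(threshold 0.3). Single-replicate survey noise is on the order of 1–3
percentage points, as the examples show.

## Source catalogue

The packaged catalogue transcribes the published per-country source
tables: 87 countries (50 Africa, 37 Asia), routed by data type —
census tables to standardisation, census microdata to the indicator
tabulation, DHS/MIS/AIS/SIS/MICS to the weighted survey tabulation, and
9 countries with no subnational source to the national fallback. Row
tallies by type are Census 31, census microdata 13, DHS 22, MICS 8,
MIS/AIS/SIS 4, UN 9; the accompanying prose in the original source
quotes 30/17/19 for the first three, a discrepancy that is documented
here and in the table transcription rather than resolved. The
transcription is authoritative for all fixtures and tests.

## Known limitations

- Only two raw-table dialects are parsed (counts/percentages with
  parseable interval headers); arbitrary national census layouts need
  manual restructuring upstream.
- No variance estimation for survey estimates; point estimates only.
- No reprojection or partial-cell (area-weighted) rasterisation; inputs
  must share the grid template.
- The between-round difference procedure pools regions by supplied
  totals (equal weights if omitted); results on real survey rounds
  require the licensed microdata and are out of scope here — the
  procedure is validated on constructed synthetic rounds instead.
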