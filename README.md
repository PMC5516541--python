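# demogrid

Subnational age/sex population structures, dependency ratios, and gridded
5-year age/sex count layers — a tested, reusable implementation of the
demographic mapping workflow used to turn heterogeneous subnational data
(census tables, census microdata, weighted household surveys) into
harmonised proportional age structures and high-resolution demographic
raster surfaces for countries in Africa and Asia.

## Who this is for

Population geographers, epidemiologists and health planners who need
subnational age structure where only mixed-quality sources exist: a full
census table in one country, a ~5% census microdata sample in the next,
and a two-stage cluster household survey in a third. The package
harmonises all three into one standard schema, derives dependency-ratio
surfaces, and disaggregates a gridded population-count raster into
per-age-group, per-sex count layers — with the conservation and
validation checks built in.

## The model

Every administrative unit is reduced to a row of the **standard schema**:
the percentage of its population in each of 14 age groups (0–4, 5–9, …,
60–64, 65+) plus a two-way male/female split (`MPROP`/`FPROP`). From the
young share `pc0_14 = A0004 + A0509 + A1014`, working-age share
`pc15_64` (ages 15–64) and old share `pc65 = A65PL`, the dependency
ratios per unit are

```
YDR = (pc0_14 / pc15_64) × 100        young-age dependency ratio
ODR = (pc65   / pc15_64) × 100        old-age dependency ratio
CDR = ((pc0_14 + pc65) / pc15_64) × 100 = YDR + ODR
```

i.e. dependents per 100 working-age persons.

Microdata sources are tabulated per unit: census microdata with the
binary-indicator workflow (one 0/1 field per age-group × sex cell,
summed by unit and divided by the unit's record count), household
surveys with the weighted de-facto estimator

```
p̂(g, a) = Σᵢ wᵢ · 1[ageᵢ ∈ g, unitᵢ = a, de factoᵢ] / Σᵢ wᵢ · 1[unitᵢ = a, de factoᵢ]
```

where `wᵢ` is the sampling weight (inverse inclusion probability).

Gridded outputs are produced on one shared WGS84 grid template (default
resolution 30 arc seconds): unit attributes are rasterised by
cell-center containment, the population-count surface `P` is scaled per
country to national reference totals, and count layers follow the
cellwise product

```
C_g = π_g × P
```

where `π_g` is the gridded proportion layer of age group `g` and `C_g`
the resulting count layer; sex splits multiply in the per-unit
male/female proportion layers. By construction `Σ_g C_g = P` cellwise —
the conservation audit checks exactly this.

A fully specified **synthetic country generator** (exponential age
pyramids with known steepness, largest-remainder integer populations,
binomial census sampling, two-stage stratified cluster surveys with
design weights) provides ground truth for every stage, so the whole
pipeline is testable end-to-end without any licensed microdata.

## Worked example

Dependency ratios for Bhutan's districts from the packaged standardised
table (`examples/03_dependency_ratios.py`):

```
district               YDR     ODR     CDR
BUMTHANG             48.89    9.84   58.73
CHHUKHA              45.81    3.89   49.70
TSIRANG              55.85    8.90   64.74
...
district YDR spread: min 45.0, Q1 52.1, median 56.0, Q3 58.7, max 68.0
national reference 52.0 is outside the IQR
```

For BUMTHANG the young share is 8.5 + 9.9 + 12.4 = 30.8%, the old share
6.2%, so the working-age complement is 63.0% and YDR = 30.8/63.0 × 100 =
48.89 young dependents per 100 working-age persons; CDR = YDR + ODR
exactly. The five-number summary shows how much district-level variation
a single national figure hides — a reference outside the interquartile
range is the typical signature of national averages dominated by
high-density areas.

The other examples each run one capability end to end and print what
they compute: synthetic-country generation (`01`), raw-table
standardisation (`02`), gridded age/sex counts with the conservation
audit (`04`), weighted survey tabulation against known truth (`05`) and
the source catalogue routing (`06`).

A thin CLI mirrors the stages: `demogrid simulate`, `demogrid catalog
summarize`, `demogrid standardize`, `demogrid tabulate`, `demogrid
ratios`, `demogrid grid rasterize|adjust|extract`, `demogrid validate
recover|compare`.

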