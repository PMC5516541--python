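"""Synthetic-country generator.

Builds a fully specified small country -- nested rectangular administrative
units, a known ("true") per-unit age/sex structure, a gridded population
count surface, and census-style and household-survey-style microdata samples
-- so that every stage of the pipeline can be tested against known ground
truth without any licensed demographic data.

The true age pyramid of each unit is a single-parameter exponential over
bin index: ``p_g \\propto exp(-rho * g)`` for the 14 standard bins.  Larger
``rho`` gives a younger population (a steeper pyramid); ``rho = 0`` is the
uniform limit.  The sex split is uniform across age bins, matching the
pipeline's own output constraint, so the sex-split stage is exact on
synthetic data.

Sampling emulates the source variety of real subnational demographic data:
census microdata as a simple random sample of a few percent of each unit's
population, and household surveys as a two-stage stratified cluster sample
(strata = admin-1 units; PSUs then households) with inverse-inclusion-
probability weights and a de-facto residence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .boundaries import AdminBoundarySet
from .grid import GridTemplate, RasterLayer
from .schema import STANDARD_14, STANDARD_COLUMNS, AgeSchema

# Fixed substream offsets: stages can be regenerated independently from one
# global seed without sharing random state.
_SUB_STRUCTURE = 1
_SUB_GRID = 2
_SUB_CENSUS = 3
_SUB_SURVEY = 4

#: Upper age (inclusive) used when drawing an integer age in the open
#: 65+ bin: uniform on 65..84.
OPEN_BIN_TOP_AGE = 84

SEXES = ("male", "female")

MICRODATA_COLUMNS = ["unit_id", "age", "sex", "weight", "stratum_id", "psu_id", "de_facto"]


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Two-stage stratified cluster design; one stratum per admin-1 unit."""

    psus_per_stratum: int = 50
    psus_sampled: int = 10
    households_per_psu: int = 40
    households_sampled: int = 15
    mean_household_size: float = 5.0

    def __post_init__(self):
        if not (0 < self.psus_sampled <= self.psus_per_stratum):
            raise ValueError("psus_sampled must be in 1..psus_per_stratum")
        if not (0 < self.households_sampled <= self.households_per_psu):
            raise ValueError("households_sampled must be in 1..households_per_psu")
        if self.mean_household_size < 1:
            raise ValueError("mean_household_size must be >= 1")

    @property
    def weight(self) -> float:
        """Inverse inclusion probability, constant within design cells."""
        pi_psu = self.psus_sampled / self.psus_per_stratum
        pi_hh = self.households_sampled / self.households_per_psu
        return 1.0 / (pi_psu * pi_hh)


@dataclass(frozen=True)
class SyntheticCountrySpec:
    """Parameters of the synthetic country.

    ``pyramid_decay`` and ``male_share`` may be scalars (shared by all
    admin-2 units) or one value per unit; ``None`` draws unit values from
    the global seed (decay uniform on [0.05, 0.30], male share uniform on
    [0.48, 0.53] -- realistic magnitudes for high-fertility settings).
    """

    seed: int = 0
    n_admin1: int = 2
    n_admin2_per_admin1: int = 2
    grid: GridTemplate = field(
        default_factory=lambda: GridTemplate(west=10.0, north=10.0, resolution=0.05,
                                             n_rows=40, n_cols=40)
    )
    total_population: int = 1_000_000
    pyramid_decay: float | tuple[float, ...] | None = None
    male_share: float | tuple[float, ...] | None = None
    census_sample_fraction: float = 0.05
    survey_design: SurveyDesignSpec = field(default_factory=SurveyDesignSpec)
    defacto_prob: float = 0.95

    def __post_init__(self):
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")
        if not (0 < self.census_sample_fraction <= 1):
            raise ValueError("census_sample_fraction must be in (0, 1]")
        if not (0 < self.defacto_prob <= 1):
            raise ValueError("defacto_prob must be in (0, 1]")

    @property
    def n_units(self) -> int:
        return self.n_admin1 * self.n_admin2_per_admin1

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, substream])

    def _per_unit(self, value, low, high, offset) -> np.ndarray:
        if value is None:
            rng = np.random.default_rng([self.seed, _SUB_STRUCTURE, offset])
            return rng.uniform(low, high, self.n_units)
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_units,))
        return arr.copy()

    def decay_per_unit(self) -> np.ndarray:
        arr = self._per_unit(self.pyramid_decay, 0.05, 0.30, 0)
        if (arr < 0).any():
            raise ValueError("pyramid_decay must be >= 0")
        return arr

    def male_share_per_unit(self) -> np.ndarray:
        arr = self._per_unit(self.male_share, 0.48, 0.53, 1)
        if ((arr <= 0) | (arr >= 1)).any():
            raise ValueError("male_share must be in (0, 1)")
        return arr


@dataclass
class TrueStructure:
    """Ground-truth per-unit structure.

    The truth is a realized integer population: each unit's population is
    apportioned across the 28 (age bin, sex) cells of its model pyramid by
    largest remainder, and ``proportions = cell_counts / population``
    exactly.  A full enumeration of the population therefore reproduces
    the proportions to machine precision; the exponential model is matched
    to within half a person per cell.

    ``proportions`` has one row per admin-2 unit and a column per
    (age bin, sex) cell, as fractions summing to 1 within each row.
    """

    proportions: pd.DataFrame           # index unit_id, columns like "A0004_male"
    cell_counts: pd.DataFrame           # integer persons per (bin, sex) cell
    unit_populations: pd.Series         # index unit_id, integer persons
    admin1_of: pd.Series                # index unit_id -> admin1 id
    male_share: pd.Series               # model male share per unit, fraction
    schema: AgeSchema = field(default_factory=lambda: STANDARD_14)

    def __post_init__(self):
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("per-unit (bin, sex) proportions must sum to 1")
        if (self.proportions.values < 0).any():
            raise ValueError("proportions must be nonnegative")

    def age_proportions(self) -> pd.DataFrame:
        """Age-only fractions per unit (summed over sexes), one column per bin."""
        out = {}
        for lab in self.schema.labels:
            out[lab] = sum(self.proportions[f"{lab}_{s}"] for s in SEXES)
        return pd.DataFrame(out, index=self.proportions.index)

    def admin1_aggregate(self) -> "TrueStructure":
        """Aggregation of admin-2 cell counts up to admin-1 units."""
        counts = self.cell_counts.copy()
        counts["__a1"] = self.admin1_of
        agg = counts.groupby("__a1").sum()
        agg.index.name = "unit_id"
        a1_pop = agg.sum(axis=1)
        props = agg.div(a1_pop, axis=0)
        male = sum(props[f"{lab}_male"] for lab in self.schema.labels)
        return TrueStructure(
            proportions=props,
            cell_counts=agg,
            unit_populations=a1_pop.astype(int),
            admin1_of=pd.Series(props.index, index=props.index),
            male_share=male,
            schema=self.schema,
        )

    def to_standard_table(self, country: str = "Synthetica") -> pd.DataFrame:
        """Express the truth in the standardised percentage schema."""
        age = self.age_proportions() * 100.0
        male = sum(self.proportions[f"{lab}_male"] for lab in self.schema.labels)
        out = pd.DataFrame(
            {
                "NAME": country,
                "ADM_NAME": [f"UNIT_{u}" for u in self.proportions.index],
                "MPROP": male * 100.0,
                "FPROP": (1.0 - male) * 100.0,
            },
            index=self.proportions.index,
        )
        for lab in self.schema.labels:
            out[lab] = age[lab]
        return out[STANDARD_COLUMNS]


def exponential_pyramid(rho: float, n_bins: int = 14) -> np.ndarray:
    """Normalised exponential age pyramid ``p_g \\propto exp(-rho*g)``."""
    if rho < 0:
        raise ValueError("pyramid decay must be >= 0")
    w = np.exp(-rho * np.arange(n_bins))
    return w / w.sum()


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion integer ``total`` across nonnegative ``weights`` (Hamilton)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_admin_mosaic(spec: SyntheticCountrySpec) -> AdminBoundarySet:
    """Tile the grid extent with nested rectangular admin units.

    Admin-1 units are horizontal bands of rows; each band is split into
    ``n_admin2_per_admin1`` vertical slabs of columns.  Polygons are
    grid-cell-aligned, non-overlapping and exactly tile the extent.
    """
    g = spec.grid
    if g.n_rows % spec.n_admin1:
        raise ValueError(
            f"n_rows={g.n_rows} not divisible by n_admin1={spec.n_admin1}"
        )
    if g.n_cols % spec.n_admin2_per_admin1:
        raise ValueError(
            f"n_cols={g.n_cols} not divisible by "
            f"n_admin2_per_admin1={spec.n_admin2_per_admin1}"
        )
    rows_per_band = g.n_rows // spec.n_admin1
    cols_per_slab = g.n_cols // spec.n_admin2_per_admin1
    geoms, rows = [], []
    uid = 0
    for a1 in range(spec.n_admin1):
        r0, r1 = a1 * rows_per_band, (a1 + 1) * rows_per_band
        for a2 in range(spec.n_admin2_per_admin1):
            uid += 1
            c0, c1 = a2 * cols_per_slab, (a2 + 1) * cols_per_slab
            geoms.append(
                box(
                    g.west + c0 * g.resolution,
                    g.north - r1 * g.resolution,
                    g.west + c1 * g.resolution,
                    g.north - r0 * g.resolution,
                )
            )
            rows.append({"unit_id": uid, "admin1_id": a1 + 1})
    attrs = pd.DataFrame(rows).set_index("unit_id")
    return AdminBoundarySet(geoms, attrs)


def generate_true_structure(spec: SyntheticCountrySpec) -> TrueStructure:
    """Realize the ground-truth structure: pyramids, sex splits, unit sizes.

    Unit populations apportion the country total over lognormal unit
    weights; each unit's population is then apportioned over the 28 model
    (bin, sex) cell probabilities by largest remainder, making the truth
    an exact integer composition.
    """
    decay = spec.decay_per_unit()
    male = spec.male_share_per_unit()
    n_bins = STANDARD_14.n_bins
    unit_ids = np.arange(1, spec.n_units + 1)

    rng = spec.rng(_SUB_STRUCTURE)
    w = rng.lognormal(mean=0.0, sigma=0.4, size=spec.n_units)
    pops = largest_remainder(w, spec.total_population)

    cols = [f"{lab}_{s}" for lab in STANDARD_14.labels for s in SEXES]
    counts = np.empty((spec.n_units, 2 * n_bins), dtype=np.int64)
    for i, (rho, ms) in enumerate(zip(decay, male)):
        p = exponential_pyramid(rho, n_bins)
        cell_p = np.empty(2 * n_bins)
        cell_p[0::2] = p * ms
        cell_p[1::2] = p * (1.0 - ms)
        counts[i] = largest_remainder(cell_p, int(pops[i]))
    idx = pd.Index(unit_ids, name="unit_id")
    cell_counts = pd.DataFrame(counts, index=idx, columns=cols)
    props = cell_counts.div(pd.Series(pops, index=idx), axis=0)

    admin1 = 1 + (unit_ids - 1) // spec.n_admin2_per_admin1
    return TrueStructure(
        proportions=props,
        cell_counts=cell_counts,
        unit_populations=pd.Series(pops, index=idx),
        admin1_of=pd.Series(admin1, index=idx),
        male_share=pd.Series(male, index=idx),
    )


def generate_population_grid(
    spec: SyntheticCountrySpec,
    boundaries: AdminBoundarySet,
    structure: TrueStructure,
    uniform: bool = False,
) -> RasterLayer:
    """Distribute each unit's population across its grid cells.

    With ``uniform=True`` every cell of a unit receives pop/n_cells; the
    default draws a seeded multinomial over Dirichlet cell weights, so
    per-unit cell sums equal unit populations exactly.
    """
    from .gridding import rasterize_attribute

    unit_raster = rasterize_attribute(boundaries, None, spec.grid, unit_index=True)
    values = np.full(spec.grid.shape, spec.grid.nodata)
    rng = spec.rng(_SUB_GRID)
    for uid in boundaries.unit_ids:
        cells = unit_raster.values == uid
        n_cells = int(cells.sum())
        if n_cells == 0:
            continue
        pop = int(structure.unit_populations.loc[uid])
        if uniform:
            values[cells] = pop / n_cells
        else:
            probs = rng.dirichlet(np.full(n_cells, 2.0))
            values[cells] = rng.multinomial(pop, probs)
    return RasterLayer(spec.grid, values, semantics="count")


def generate_iso_mask(spec: SyntheticCountrySpec, code: int = 1) -> RasterLayer:
    """Single-country ISO-code mask covering the whole grid extent."""
    return RasterLayer(
        spec.grid, np.full(spec.grid.shape, float(code)), semantics="iso-code"
    )


def _ages_for_bins(
    rng: np.random.Generator, bins: np.ndarray, schema: AgeSchema
) -> np.ndarray:
    """Integer ages uniform within each person's 5-year bin.

    The open top bin draws uniform on ``open_lower..OPEN_BIN_TOP_AGE``.
    Rebinned results are invariant to the within-bin placement by
    construction.
    """
    lo = np.asarray(schema.lower_edges)[bins]
    hi = np.append(np.asarray(schema.lower_edges[1:]), OPEN_BIN_TOP_AGE + 1)[bins]
    return rng.integers(lo, hi)


def _expand_cells(
    rng: np.random.Generator, cell_counts: np.ndarray, schema: AgeSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-(bin, sex) cell counts into person rows."""
    cells = np.repeat(np.arange(cell_counts.size), cell_counts)
    bins, sexes = cells // 2, cells % 2
    return _ages_for_bins(rng, bins, schema), sexes


def _draw_persons(
    rng: np.random.Generator,
    cell_probs: np.ndarray,
    n: int,
    schema: AgeSchema = STANDARD_14,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. (age, sex) pairs from flat cell probabilities."""
    cells = rng.choice(cell_probs.size, size=n, p=cell_probs)
    bins, sexes = cells // 2, cells % 2
    return _ages_for_bins(rng, bins, schema), sexes


def sample_census_microdata(
    structure: TrueStructure, fraction: float, seed: int
) -> pd.DataFrame:
    """Simple random sample of each unit's population, one row per person.

    Per-unit sample size is Binomial(unit population, fraction); (bin, sex)
    cells are drawn from the unit's true proportions.  Deterministic for a
    fixed seed.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng([seed, _SUB_CENSUS])
    frames = []
    for uid, row in structure.cell_counts.iterrows():
        cell_counts = row.to_numpy()
        pop = int(structure.unit_populations.loc[uid])
        if fraction == 1:
            # full enumeration of the realized population
            sampled = cell_counts
        else:
            n = int(rng.binomial(pop, fraction))
            sampled = rng.multivariate_hypergeometric(cell_counts, n)
        ages, sexes = _expand_cells(rng, sampled, structure.schema)
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": uid,
                    "age": ages,
                    "sex": np.where(sexes == 0, "male", "female"),
                    "weight": 1.0,
                    "stratum_id": pd.NA,
                    "psu_id": pd.NA,
                    "de_facto": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[MICRODATA_COLUMNS]


def sample_survey_microdata(
    structure: TrueStructure,
    design: SurveyDesignSpec,
    defacto_prob: float,
    seed: int,
) -> pd.DataFrame:
    """Two-stage stratified cluster sample with design weights.

    Strata are admin-1 units.  Within each stratum, ``psus_sampled`` of
    ``psus_per_stratum`` PSUs are drawn without replacement, then
    ``households_sampled`` of ``households_per_psu`` households per PSU.
    Household size is 1 + Poisson(mean_household_size - 1); member (age,
    sex) cells are i.i.d. from the stratum's aggregated true pyramid, so
    the weighted tabulation is exactly design-unbiased.  Every person
    carries weight 1/(pi_psu * pi_hh) and a Bernoulli de-facto flag.
    """
    if not (0 < defacto_prob <= 1):
        raise ValueError("defacto_prob must be in (0, 1]")
    rng = np.random.default_rng([seed, _SUB_SURVEY])
    admin1 = structure.admin1_aggregate()
    w = design.weight
    frames = []
    for a1, row in admin1.proportions.iterrows():
        psu_ids = np.sort(
            rng.choice(design.psus_per_stratum, design.psus_sampled, replace=False)
        )
        # household sizes for every sampled household of every sampled PSU
        sizes = 1 + rng.poisson(
            design.mean_household_size - 1.0,
            (design.psus_sampled, design.households_sampled),
        )
        per_psu = sizes.sum(axis=1)
        n = int(per_psu.sum())
        ages, sexes = _draw_persons(rng, row.to_numpy(), n, structure.schema)
        psu_labels = np.repeat([f"S{a1}-P{p}" for p in psu_ids], per_psu)
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": a1,
                    "age": ages,
                    "sex": np.where(sexes == 0, "male", "female"),
                    "weight": w,
                    "stratum_id": a1,
                    "psu_id": psu_labels,
                    "de_facto": rng.random(n) < defacto_prob,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[MICRODATA_COLUMNS]


@dataclass
class SyntheticCountry:
    """Bundle of all generated artefacts for one spec + seed."""

    spec: SyntheticCountrySpec
    boundaries: AdminBoundarySet
    structure: TrueStructure
    population: RasterLayer
    iso_mask: RasterLayer
    census: pd.DataFrame
    survey: pd.DataFrame


def simulate_country(spec: SyntheticCountrySpec) -> SyntheticCountry:
    """Run every generator off the spec's single global seed."""
    boundaries = generate_admin_mosaic(spec)
    structure = generate_true_structure(spec)
    population = generate_population_grid(spec, boundaries, structure)
    iso = generate_iso_mask(spec)
    census = sample_census_microdata(structure, spec.census_sample_fraction, spec.seed)
    survey = sample_survey_microdata(
        structure, spec.survey_design, spec.defacto_prob, spec.seed
    )
    return SyntheticCountry(spec, boundaries, structure, population, iso, census, survey)
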