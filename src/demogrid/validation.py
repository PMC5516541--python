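"""Validation procedures: conservation audit, national comparison,
between-round differences, and the synthetic parameter-recovery harness.

The conservation audit re-derives the check used to validate gridded
age/sex count stacks: summing every age/sex layer back into a single
surface must reproduce the adjusted population raster cellwise, and
per-country totals must match the national reference figures.

The national comparison summarises the spread of subnational ratios per
country (five-number summary across units) against a user-supplied
national reference value, flagging references falling outside the
interquartile range.  The round-difference procedure computes signed
percentage-point changes in age composition between two survey rounds on
a finer 17-group schema, per region and for the country as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterLayer, require_aligned, zonal_sum
from .ratios import compute_ratios, pyramid_triple
from .schema import FINE_17, AgeSchema
from .synthetic import (
    SyntheticCountrySpec,
    sample_census_microdata,
    sample_survey_microdata,
    simulate_country,
)
from .tabulate import tabulate_census_microdata, tabulate_weighted_survey


@dataclass
class ConservationReport:
    """Outcome of the stack-vs-population conservation audit."""

    per_country: pd.DataFrame      # stack_sum, target, abs_dev, rel_dev, status
    cellwise_max_rel_dev: float
    tolerance: float

    @property
    def passed(self) -> bool:
        checked = self.per_country[self.per_country["status"] != "no-data"]
        return bool(
            (checked["status"] == "pass").all()
            and self.cellwise_max_rel_dev <= self.tolerance
        )


def audit_conservation(
    count_stack: dict[str, RasterLayer],
    population: RasterLayer,
    iso: RasterLayer,
    targets: dict[int, float],
    tol: float = 1e-6,
) -> ConservationReport:
    """Check that the age/sex count stack conserves the population surface.

    Cellwise: the sum over all stack layers must equal the population
    raster within ``tol`` relative.  Per country: the stack total must
    equal the national target within ``tol`` relative.  Countries present
    in the mask but with no data cells are reported as ``no-data``.
    """
    layers = list(count_stack.values())
    require_aligned(population, iso, *layers)
    mask = population.data_mask()
    for lyr in layers:
        mask &= lyr.data_mask()
    total = sum(lyr.values * mask for lyr in layers)
    ref = population.filled()
    denom = np.where(ref[mask] > 0, ref[mask], 1.0)
    cell_rel = (
        float(np.max(np.abs(total[mask] - ref[mask]) / denom)) if mask.any() else 0.0
    )

    stack_total = population.with_values(np.where(mask, total, population.nodata))
    sums = zonal_sum(stack_total, iso)
    rows = []
    for code in sorted(set(np.unique(iso.values[iso.data_mask()]).astype(int))):
        target = float(targets.get(code, np.nan))
        s = sums.get(code)
        if s is None:
            rows.append(
                {"country": code, "stack_sum": 0.0, "target": target,
                 "abs_dev": np.nan, "rel_dev": np.nan, "status": "no-data"}
            )
            continue
        abs_dev = s - target
        rel_dev = abs(abs_dev) / target if target else abs(abs_dev)
        rows.append(
            {
                "country": code,
                "stack_sum": s,
                "target": target,
                "abs_dev": abs_dev,
                "rel_dev": rel_dev,
                "status": "pass" if rel_dev <= tol else "fail",
            }
        )
    report = pd.DataFrame(rows).set_index("country")
    return ConservationReport(report, cell_rel, tol)


@dataclass(frozen=True)
class NationalComparison:
    """Five-number summary of subnational ratios vs a national reference."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    reference: float
    reference_outside_iqr: bool
    n_units: int


def compare_to_national(values, reference: float) -> NationalComparison:
    """Summarise unit-level ratio values against a national estimate.

    Quartiles are unweighted across units with the linear-interpolation
    quantile rule; the flag marks references below Q1 or above Q3 --
    the signature of national averages dominated by high-density areas.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no unit values to summarise")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return NationalComparison(
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(arr.max()),
        reference=float(reference),
        reference_outside_iqr=bool(reference < q1 or reference > q3),
        n_units=int(arr.size),
    )


def round_difference(
    std_t1: pd.DataFrame,
    std_t2: pd.DataFrame,
    schema: AgeSchema = FINE_17,
    totals_t1: pd.Series | None = None,
    totals_t2: pd.Series | None = None,
) -> pd.DataFrame:
    """Signed percentage-point change per region and age group, t2 - t1.

    Both inputs are region-indexed percentage tables on the (finer)
    comparison schema.  The ``Total`` row differences country-pooled
    proportions (each round's regions weighted by its ``totals`` --
    person or weight totals per region; equal weights if omitted), not
    the mean of the per-region differences.
    """
    cols = list(schema.labels)
    r1, r2 = set(std_t1.index), set(std_t2.index)
    if r1 != r2:
        raise ValueError(
            f"mismatched region sets; symmetric difference: {sorted(r1 ^ r2)}"
        )
    t1 = std_t1.loc[sorted(r1), cols]
    t2 = std_t2.loc[sorted(r1), cols]
    diff = t2 - t1

    def pooled(tab: pd.DataFrame, totals: pd.Series | None) -> pd.Series:
        w = (
            pd.Series(1.0, index=tab.index)
            if totals is None
            else totals.reindex(tab.index).astype(float)
        )
        if w.isna().any() or (w < 0).any():
            raise ValueError("invalid region totals")
        return tab.mul(w, axis=0).sum() / w.sum()

    diff.loc["Total"] = pooled(t2, totals_t2) - pooled(t1, totals_t1)
    return diff


@dataclass
class RecoveryReport:
    """End-to-end parameter-recovery errors per data route (percent scale)."""

    census_table_max_err: float
    census_full_max_err: float
    census_sample_max_err: float
    survey_bias_per_bin: pd.DataFrame
    survey_max_abs_bias: float
    ydr_true: float
    ydr_recovered: float
    n_survey_replicates: int
    conservation: ConservationReport = field(repr=False, default=None)

    @property
    def summary(self) -> dict[str, float]:
        return {
            "census_table_max_err": self.census_table_max_err,
            "census_full_max_err": self.census_full_max_err,
            "census_sample_max_err": self.census_sample_max_err,
            "survey_max_abs_bias": self.survey_max_abs_bias,
            "ydr_true": self.ydr_true,
            "ydr_recovered": self.ydr_recovered,
        }


def recover_parameters(
    spec: SyntheticCountrySpec, n_survey_replicates: int = 500
) -> RecoveryReport:
    """Run the full pipeline on a synthetic country and measure recovery.

    Exercises the three data routes against the known truth: the census
    table route (truth expressed as a standard table), the census
    microdata route at full enumeration and at the spec's sampling
    fraction, and the survey route averaged over seeded replicates.
    Also runs the gridded conservation audit on the pipeline's own
    output stack.
    """
    from .gridding import (
        adjust_to_national_totals,
        disaggregate_age_sex,
        table_to_proportion_layers,
    )

    country = simulate_country(spec)
    truth_pct = country.structure.proportions * 100.0

    # census-table route: truth -> standard table -> (bin, sex) percentages
    from .standardize import apply_uniform_sex_split

    table = country.structure.to_standard_table()
    split = apply_uniform_sex_split(table)
    census_table_err = float((split - truth_pct).abs().to_numpy().max())

    # census-microdata route, full enumeration
    full = tabulate_census_microdata(sample_census_microdata(country.structure, 1.0, spec.seed))
    census_full_err = float(
        (full.percentages - truth_pct).abs().to_numpy().max()
    )

    # census-microdata route at the spec's sampling fraction
    sample = tabulate_census_microdata(country.census)
    census_sample_err = float(
        (sample.percentages - truth_pct).abs().to_numpy().max()
    )

    # survey route: mean estimate over replicates vs admin-1 truth
    admin1 = country.structure.admin1_aggregate()
    truth_a1_age = admin1.proportions.copy()
    acc = None
    for rep in range(n_survey_replicates):
        micro = sample_survey_microdata(
            country.structure, spec.survey_design, spec.defacto_prob, spec.seed + rep
        )
        est = tabulate_weighted_survey(micro).percentages
        acc = est if acc is None else acc + est
    mean_est = acc / n_survey_replicates
    bias = mean_est - truth_a1_age * 100.0
    survey_max_bias = float(bias.abs().to_numpy().max())

    # ratio propagation: YDR from the full-census recovered structure
    age_true = country.structure.age_proportions().mul(
        country.structure.unit_populations, axis=0
    ).sum()
    p_true = (age_true / age_true.sum()).to_numpy()
    ydr_true = compute_ratios(pyramid_triple(p_true)).ydr
    age_rec = full.age_percentages().mul(full.totals, axis=0).sum()
    p_rec = (age_rec / age_rec.sum()).to_numpy()
    ydr_rec = compute_ratios(pyramid_triple(p_rec)).ydr

    # gridded route + conservation audit on the pipeline's own stack
    targets = {1: float(spec.total_population)}
    population = adjust_to_national_totals(country.population, country.iso_mask, targets)
    age_stack, sex_stack = table_to_proportion_layers(
        country.boundaries, table, spec.grid
    )
    counts_stack = disaggregate_age_sex(age_stack, population, sex_stack)
    conservation = audit_conservation(counts_stack, population, country.iso_mask, targets)

    return RecoveryReport(
        census_table_max_err=census_table_err,
        census_full_max_err=census_full_err,
        census_sample_max_err=census_sample_err,
        survey_bias_per_bin=bias,
        survey_max_abs_bias=survey_max_bias,
        ydr_true=float(ydr_true),
        ydr_recovered=float(ydr_rec),
        n_survey_replicates=n_survey_replicates,
        conservation=conservation,
    )
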