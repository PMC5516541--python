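"""Per-unit age/sex proportions from person-level microdata.

Two estimators share one mechanical core:

* census microdata -- the binary-indicator workflow: one 0/1 indicator
  field per (5-year age group, sex) cell per person, summed by
  administrative unit and divided by the unit's record count;
* household surveys -- the weighted de-facto procedure: non-de-facto
  members are dropped, then indicator sums and totals are computed with
  each person's sampling weight, so weighted tallies estimate population
  proportions under the survey design.

Point estimates only: stratum and PSU identifiers are carried through for
reporting, but no variance estimation is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import STANDARD_14, STANDARD_COLUMNS, AgeSchema

SEXES = ("male", "female")


@dataclass
class TabulationResult:
    """Weighted counts and percentages per unit and (age bin, sex) cell.

    ``counts`` and ``percentages`` are indexed by unit id with one column
    per cell (``A0004_male`` ...); ``totals`` is the per-unit weight sum
    and ``n_records`` the raw row count.  Percentages per unit sum to 100
    to near machine precision before any rounding.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    totals: pd.Series
    n_records: pd.Series
    mode: str = "census"
    excluded_units: list = field(default_factory=list)
    schema: AgeSchema = field(default_factory=lambda: STANDARD_14)

    def age_percentages(self) -> pd.DataFrame:
        """Age-only percentages (summed over sexes), one column per bin."""
        out = {}
        for lab in self.schema.labels:
            out[lab] = self.percentages[f"{lab}_male"] + self.percentages[f"{lab}_female"]
        return pd.DataFrame(out, index=self.percentages.index)

    def sex_percentages(self) -> pd.DataFrame:
        """Two-way sex split per unit (percent of unit total)."""
        male = sum(self.percentages[f"{lab}_male"] for lab in self.schema.labels)
        return pd.DataFrame({"MPROP": male, "FPROP": 100.0 - male})

    def to_standard_table(self, country: str = "NA") -> pd.DataFrame:
        """Express the result in the standardised Table schema."""
        age = self.age_percentages()
        sex = self.sex_percentages()
        out = pd.DataFrame(
            {
                "NAME": country,
                "ADM_NAME": [str(u) for u in self.percentages.index],
                "MPROP": sex["MPROP"],
                "FPROP": sex["FPROP"],
            },
            index=self.percentages.index,
        )
        for lab in self.schema.labels:
            out[lab] = age[lab]
        return out[STANDARD_COLUMNS]


def load_microdata(path: str | Path) -> pd.DataFrame:
    """Read person microdata CSV and validate ages, sexes and weights."""
    df = pd.read_csv(path)
    if not {"unit_id", "age", "sex"} <= set(df.columns):
        raise ValueError("microdata requires unit_id, age, sex columns")
    ages = df["age"]
    if (ages < 0).any() or not np.allclose(ages, ages.astype(int)):
        raise ValueError("ages must be nonnegative integers")
    if not df["sex"].isin(SEXES).all():
        raise ValueError(f"sex must be one of {SEXES}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if (df["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    if "de_facto" not in df.columns:
        df["de_facto"] = True
    return df


def _indicator_matrix(data: pd.DataFrame, schema: AgeSchema) -> pd.DataFrame:
    """One binary column per (bin, sex) cell, one row per person."""
    edges = list(schema.lower_edges[1:]) + [np.inf]
    bin_idx = np.searchsorted(edges, data["age"].to_numpy(), side="right")
    is_male = (data["sex"] == "male").to_numpy()
    ind = {}
    for g, lab in enumerate(schema.labels):
        in_bin = bin_idx == g
        ind[f"{lab}_male"] = (in_bin & is_male).astype(float)
        ind[f"{lab}_female"] = (in_bin & ~is_male).astype(float)
    return pd.DataFrame(ind, index=data.index)


def _tabulate(data: pd.DataFrame, weights: np.ndarray, schema: AgeSchema) -> tuple:
    ind = _indicator_matrix(data, schema)
    weighted = ind.mul(weights, axis=0)
    weighted["__unit"] = data["unit_id"].to_numpy()
    counts = weighted.groupby("__unit").sum()
    counts.index.name = "unit_id"
    totals = counts.sum(axis=1)
    pct = counts.div(totals, axis=0) * 100.0
    n = data.groupby("unit_id").size().reindex(counts.index)
    return counts, pct, totals, n


def tabulate_census_microdata(
    data: pd.DataFrame,
    schema: AgeSchema = STANDARD_14,
    expected_units: list | None = None,
) -> TabulationResult:
    """Unweighted indicator tabulation of census-style microdata.

    Weights and de-facto flags, if present, are ignored: each record
    counts 1.  Units listed in ``expected_units`` but absent from the data
    are excluded with a warning and listed on the result.
    """
    _check_ages(data)
    counts, pct, totals, n = _tabulate(data, np.ones(len(data)), schema)
    excluded = []
    if expected_units is not None:
        excluded = sorted(set(expected_units) - set(counts.index))
        if excluded:
            warnings.warn(f"units with zero records excluded: {excluded}")
    return TabulationResult(counts, pct, totals, n, "census", excluded, schema)


def tabulate_weighted_survey(
    data: pd.DataFrame, schema: AgeSchema = STANDARD_14
) -> TabulationResult:
    """Weighted de-facto tabulation of household-survey microdata.

    Rows flagged not de facto are dropped first; each remaining person
    contributes its sampling weight to its (unit, bin, sex) cell, and
    percentages divide by the unit's de-facto weight sum.
    """
    if "weight" not in data.columns or data["weight"].isna().any():
        raise ValueError("survey tabulation requires a weight on every row")
    if "de_facto" not in data.columns or data["de_facto"].isna().any():
        raise ValueError("survey tabulation requires a de_facto flag on every row")
    _check_ages(data)
    if (data["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    kept = data[data["de_facto"].astype(bool)]
    empty = sorted(set(data["unit_id"]) - set(kept["unit_id"]))
    if empty:
        raise ValueError(f"unit(s) with zero de-facto weight: {empty}")
    counts, pct, totals, n = _tabulate(kept, kept["weight"].to_numpy(), schema)
    return TabulationResult(counts, pct, totals, n, "survey", [], schema)


def _check_ages(data: pd.DataFrame) -> None:
    ages = data["age"].to_numpy()
    if (ages < 0).any():
        raise ValueError("negative ages in microdata")
    if not np.allclose(ages, np.round(ages)):
        raise ValueError("non-integer ages in microdata")


def qaqc_tabulation(result: TabulationResult, tol: float = 1e-9) -> pd.DataFrame:
    """Check per unit that cell sums equal totals, in counts and percent.

    Mirrors the tabulation QA steps: the (bin, sex) cell counts must sum
    to the unit total, male + female percentages must sum to 100, and the
    14 age-group percentages must sum to 100.
    """
    cell_sum = result.counts.sum(axis=1)
    age_pct_sum = result.age_percentages().sum(axis=1)
    sex = result.sex_percentages()
    report = pd.DataFrame(
        {
            "count_dev": cell_sum - result.totals,
            "age_pct_dev": age_pct_sum - 100.0,
            "sex_pct_dev": sex["MPROP"] + sex["FPROP"] - 100.0,
        },
        index=result.counts.index,
    )
    report["passed"] = (report.abs() <= tol).all(axis=1)
    return report
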