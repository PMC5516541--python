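"""Harmonising raw age/sex tables into the standard percentage schema.

Raw subnational tables arrive in many dialects: absolute counts or
percentages, single-year or multi-year age bins, open top bins anywhere
above 65.  This module rebins them onto the standard 14-group schema and
expresses every unit as percentages, with the two QA sum invariants
(age groups total 100; male + female total 100) checked explicitly.

Raw intervals must nest inside the standard bins -- an interval straddling
a 5-year boundary (e.g. ages 3-7) cannot be split without an interpolation
assumption, so it is rejected loudly rather than guessed at.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .schema import STANDARD_14, STANDARD_COLUMNS, SUM_TOLERANCE, AgeSchema

_UNIT_KEY = ["NAME", "ADM_NAME"]


@dataclass
class RawAgeTable:
    """A raw wide-format age table.

    ``table`` is indexed by the (NAME, ADM_NAME) composite unit key with
    one numeric column per age interval; ``intervals`` holds the parsed
    ``(lo, hi)`` bounds (inclusive years; ``hi=None`` marks the open top
    interval).  ``sex_values`` optionally carries per-unit male/female
    values in the same ``value_kind``.
    """

    table: pd.DataFrame
    intervals: list[tuple[int, int | None]]
    value_kind: str = "counts"
    sex_values: pd.DataFrame | None = None

    def __post_init__(self):
        if self.value_kind not in ("counts", "percentages"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if len(self.intervals) != self.table.shape[1]:
            raise ValueError("one interval per value column required")
        for lo, hi in self.intervals:
            if hi is not None and hi < lo:
                raise ValueError(f"interval [{lo}, {hi}] has hi < lo")
        spans = sorted(
            (lo, math.inf if hi is None else hi) for lo, hi in self.intervals
        )
        for (_, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("overlapping raw intervals")
        opens = [hi for _, hi in self.intervals if hi is None]
        if len(opens) > 1:
            raise ValueError("at most one open interval allowed")


_LABEL_RE = re.compile(r"^(?:<(\d+)|(\d+)\s*[-–]\s*(\d+)|(\d+)\s*\+|(\d+))$")


def parse_interval_label(label: str) -> tuple[int, int | None]:
    """Parse an age-column label: ``"0-4"``, ``"<5"``, ``"65+"`` or ``"7"``."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable age interval label {label!r}")
    lt, lo2, hi2, open_lo, single = m.groups()
    if lt is not None:
        return 0, int(lt) - 1
    if lo2 is not None:
        return int(lo2), int(hi2)
    if open_lo is not None:
        return int(open_lo), None
    return int(single), int(single)


def read_raw_table(path: str | Path, value_kind: str) -> RawAgeTable:
    """Read a raw CSV: NAME, ADM_NAME, optional MVAL/FVAL, age columns."""
    df = pd.read_csv(path)
    missing = set(_UNIT_KEY) - set(df.columns)
    if missing:
        raise ValueError(f"raw table missing key columns {sorted(missing)}")
    df = df.set_index(_UNIT_KEY)
    sex = None
    if {"MVAL", "FVAL"} <= set(df.columns):
        sex = df[["MVAL", "FVAL"]].astype(float)
        df = df.drop(columns=["MVAL", "FVAL"])
    intervals = [parse_interval_label(c) for c in df.columns]
    return RawAgeTable(df.astype(float), intervals, value_kind, sex)


def rebin_to_schema(raw: RawAgeTable, schema: AgeSchema = STANDARD_14) -> pd.DataFrame:
    """Map raw intervals onto schema bins, conserving totals exactly.

    Every raw interval must lie within a single schema bin (all intervals
    at or above the open threshold collapse into the top bin).  Raises on
    a non-nestable interval or on gaps in age coverage.
    """
    targets = []
    for lo, hi in raw.intervals:
        b_lo = schema.bin_of_age(lo)
        b_hi = schema.n_bins - 1 if hi is None else schema.bin_of_age(hi)
        if b_lo != b_hi:
            hi_txt = "+" if hi is None else str(hi)
            raise ValueError(
                f"non-nestable interval {lo}-{hi_txt}: straddles schema bins "
                f"{schema.labels[b_lo]} and {schema.labels[b_hi]}"
            )
        targets.append(b_lo)
    # coverage: intervals must partition ages below the open threshold
    # without gaps; gaps at or above it are tolerated (those intervals all
    # collapse into the open top bin regardless)
    spans = sorted(
        (lo, math.inf if hi is None else hi) for lo, hi in raw.intervals
    )
    cursor = 0
    for lo, hi in spans:
        if cursor >= schema.open_lower:
            break
        if lo > cursor:
            raise ValueError(f"age coverage gap before age {lo}")
        cursor = hi + 1
    if cursor < schema.open_lower:
        raise ValueError(f"raw intervals do not cover ages {cursor} and above")

    out = pd.DataFrame(
        0.0, index=raw.table.index, columns=list(schema.labels)
    )
    for col, b in zip(raw.table.columns, targets):
        out.iloc[:, b] += raw.table[col].to_numpy()
    return out


def counts_to_percentages(
    binned: pd.DataFrame, sex_values: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Express per-unit binned values as percentages in the standard schema.

    ``binned`` is indexed by (NAME, ADM_NAME) with the 14 standard columns.
    Percentages are kept at full precision; rounding to 1 decimal happens
    only on export.  A numeric ``unit_id`` index is added for joins.
    """
    totals = binned.sum(axis=1)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ValueError(f"zero-total unit(s): {list(zero.index)}")
    pct = binned.div(totals, axis=0) * 100.0
    out = pct.reset_index()
    if sex_values is not None:
        stot = sex_values["MVAL"] + sex_values["FVAL"]
        if (stot <= 0).any():
            raise ValueError("zero male+female total in sex_values")
        out["MPROP"] = (100.0 * sex_values["MVAL"] / stot).to_numpy()
        out["FPROP"] = (100.0 * sex_values["FVAL"] / stot).to_numpy()
    else:
        # no sex breakdown supplied: neutral two-way split
        out["MPROP"] = 50.0
        out["FPROP"] = 50.0
    out.index = pd.RangeIndex(1, len(out) + 1, name="unit_id")
    return out[STANDARD_COLUMNS]


def standardize_raw(raw: RawAgeTable, schema: AgeSchema = STANDARD_14) -> pd.DataFrame:
    """Full raw-to-standard path: rebin then convert to percentages.

    Percentage-valued inputs are renormalised to sum to exactly 100, so
    rounding in the source does not propagate.
    """
    binned = rebin_to_schema(raw, schema)
    return counts_to_percentages(binned, raw.sex_values)


def validate_standard_table(
    table: pd.DataFrame, tol: float = SUM_TOLERANCE, tolerate: bool = False
) -> pd.DataFrame:
    """Per-unit QA on the two sum invariants of the standard schema.

    Returns a report frame with age-sum and sex-sum deviations and a
    ``passed`` flag per unit.  Raises on any failure unless ``tolerate``.
    """
    age_sum = table[list(STANDARD_14.labels)].sum(axis=1)
    sex_sum = table["MPROP"] + table["FPROP"]
    report = pd.DataFrame(
        {
            "NAME": table["NAME"],
            "ADM_NAME": table["ADM_NAME"],
            "age_sum": age_sum,
            "age_dev": age_sum - 100.0,
            "sex_sum": sex_sum,
            "sex_dev": sex_sum - 100.0,
        },
        index=table.index,
    )
    report["passed"] = (report["age_dev"].abs() <= tol) & (report["sex_dev"].abs() <= tol)
    if not tolerate and not report["passed"].all():
        bad = report.loc[~report["passed"], "ADM_NAME"].tolist()
        raise ValueError(f"standard-table QA failed for unit(s): {bad}")
    return report


def apply_uniform_sex_split(table: pd.DataFrame) -> pd.DataFrame:
    """Distribute each unit's two-way sex split uniformly across age bins.

    Returns percentages of the unit total per (bin, sex):
    ``p(g, male) = A_g * MPROP / 100``.  The male and female stacks re-sum
    to the age-only stack exactly.
    """
    out = pd.DataFrame(index=table.index)
    for lab in STANDARD_14.labels:
        out[f"{lab}_male"] = table[lab] * table["MPROP"] / 100.0
        out[f"{lab}_female"] = table[lab] * table["FPROP"] / 100.0
    return out


def write_standard_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Export in the standard dialect: exact header, 1-decimal rounding."""
    table[STANDARD_COLUMNS].round(1).to_csv(path, index=False)


def load_bhutan_example() -> pd.DataFrame:
    """The packaged worked-example table: Bhutan's 20 districts.

    A partially printed standardised table (age groups 35-64 are not
    included), indexed by (NAME, ADM_NAME).  Because the middle groups
    are absent, triples derived from these rows use the complement rule
    for the working-age share.
    """
    from importlib import resources

    path = resources.files("demogrid") / "data" / "table3_bhutan.csv"
    return pd.read_csv(str(path)).set_index(_UNIT_KEY)


def read_standard_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STANDARD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"standard table missing columns {sorted(missing)}")
    df.index = pd.RangeIndex(1, len(df) + 1, name="unit_id")
    return df[STANDARD_COLUMNS]
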