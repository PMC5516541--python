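"""Dependency ratios from standardised age structures.

For each administrative unit the three ratios are computed from the share
of the population aged 0-14 (``pc0_14``), 15-64 (``pc15_64``) and 65+
(``pc65``):

    YDR = (pc0_14 / pc15_64) * 100
    ODR = (pc65  / pc15_64) * 100
    CDR = ((pc0_14 + pc65) / pc15_64) * 100 = YDR + ODR

i.e. dependents per 100 working-age persons.  Ratios are dimensionless;
the triple may be given in percent or fractions (scale cancels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import STANDARD_14, SUM_TOLERANCE

_YOUNG = STANDARD_14.labels[:3]     # A0004, A0509, A1014
_WORKING = STANDARD_14.labels[3:13] # A1519 ... A6064
_OLD = STANDARD_14.labels[13]       # A65PL


class UndefinedRatioError(ZeroDivisionError):
    """The working-age share is zero; the ratio is undefined."""


@dataclass(frozen=True)
class ProportionTriple:
    """Population shares of the young, working-age and old groups."""

    pc0_14: float
    pc15_64: float
    pc65: float

    def __post_init__(self):
        if min(self.pc0_14, self.pc15_64, self.pc65) < 0:
            raise ValueError("proportions must be nonnegative")


@dataclass(frozen=True)
class DependencyRatioRecord:
    unit_id: object
    cdr: float
    ydr: float
    odr: float
    admin_level: int | None = None


def derive_triple(row: pd.Series, tol: float = SUM_TOLERANCE) -> ProportionTriple:
    """Collapse a standard-schema row into the young/working/old triple.

    Uses the explicit sum of the ten middle age groups when all 14 fields
    are present; falls back to the complement ``100 - pc0_14 - pc65``
    (with a warning) only when middle fields are missing, as for partially
    printed rows.
    """
    young = float(sum(row[l] for l in _YOUNG))
    old = float(row[_OLD])
    middle = [row.get(l) for l in _WORKING]
    if any(m is None or (isinstance(m, float) and np.isnan(m)) for m in middle):
        working = 100.0 - young - old
        warnings.warn(
            "middle age groups missing; working-age share taken as complement"
        )
    else:
        working = float(sum(middle))
        total = young + working + old
        if abs(total - 100.0) > tol:
            warnings.warn(
                f"row sums to {total:.3f}, not 100: explicit middle-field sum used"
            )
    return ProportionTriple(young, working, old)


def compute_ratios(
    triple: ProportionTriple, unit_id: object = None, admin_level: int | None = None
) -> DependencyRatioRecord:
    """Young, old and combined dependency ratios of one triple."""
    if triple.pc15_64 == 0:
        raise UndefinedRatioError(
            f"unit {unit_id!r}: working-age share is zero, ratios undefined"
        )
    ydr = triple.pc0_14 / triple.pc15_64 * 100.0
    odr = triple.pc65 / triple.pc15_64 * 100.0
    return DependencyRatioRecord(unit_id, ydr + odr, ydr, odr, admin_level)


def ratios_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-unit CDR/YDR/ODR for a full standard table.

    Returns a frame indexed like ``table`` with NAME, ADM_NAME and the
    three ratios at full precision (round on export only).
    """
    records = []
    for uid, row in table.iterrows():
        rec = compute_ratios(derive_triple(row), unit_id=uid)
        records.append(
            {
                "unit_id": uid,
                "NAME": row["NAME"],
                "ADM_NAME": row["ADM_NAME"],
                "CDR": rec.cdr,
                "YDR": rec.ydr,
                "ODR": rec.odr,
            }
        )
    return pd.DataFrame(records).set_index("unit_id")


def national_fallback(national_row: pd.Series, country: str | None = None) -> DependencyRatioRecord:
    """Ratios from a national (admin level 0) structure, e.g. UN estimates."""
    return compute_ratios(
        derive_triple(national_row),
        unit_id=country or national_row.get("NAME"),
        admin_level=0,
    )


def aggregate_national(
    triples: pd.DataFrame, unit_populations: pd.Series
) -> DependencyRatioRecord:
    """National ratios from unit triples and unit population weights.

    The national triple is the population-weighted mean of the unit
    triples; the ratios are then taken of the aggregated triple -- not
    the mean of the unit-level ratios.
    """
    w = unit_populations.reindex(triples.index).astype(float)
    if w.isna().any():
        raise ValueError("every unit needs a population weight")
    wsum = w.sum()
    agg = ProportionTriple(
        float((triples["pc0_14"] * w).sum() / wsum),
        float((triples["pc15_64"] * w).sum() / wsum),
        float((triples["pc65"] * w).sum() / wsum),
    )
    return compute_ratios(agg, unit_id="national", admin_level=0)


def triples_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised triples for a standard table (columns pc0_14/pc15_64/pc65)."""
    return pd.DataFrame(
        {
            "pc0_14": table[list(_YOUNG)].sum(axis=1),
            "pc15_64": table[list(_WORKING)].sum(axis=1),
            "pc65": table[_OLD],
        },
        index=table.index,
    )


def pyramid_triple(p: np.ndarray) -> ProportionTriple:
    """Triple of a 14-bin age-only pyramid given as fractions."""
    p = np.asarray(p, dtype=float)
    return ProportionTriple(
        float(p[:3].sum()) * 100.0,
        float(p[3:13].sum()) * 100.0,
        float(p[13]) * 100.0,
    )


def write_ratios_csv(ratios: pd.DataFrame, path) -> None:
    """Export unit ratios rounded to 2 decimals."""
    out = ratios.copy()
    for c in ("CDR", "YDR", "ODR"):
        out[c] = out[c].round(2)
    out.to_csv(path, index=True)
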