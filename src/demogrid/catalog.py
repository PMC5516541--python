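"""Machine-readable source catalogue and per-country processing routes.

The packaged catalogue lists, for each of the 87 African and Asian
countries covered, which kind of age/sex data source was used (full census
table, census microdata, one of the weighted household-survey programmes,
or the UN national-estimate fallback), its year, and the administrative
level at which it was collected.  The route is a total function of the
data type and selects which pipeline stage processes that country.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

DATA_TYPES = ("Census", "Census microdata", "DHS", "MIS", "AIS", "SIS", "MICS", "UN")
CONTINENTS = ("Africa", "Asia")
_SURVEY_TYPES = {"DHS", "MIS", "AIS", "SIS", "MICS"}


class ProcessingRoute(enum.Enum):
    STANDARDIZE_TABLE = "standardize_table"
    TABULATE_CENSUS_MICRODATA = "tabulate_census_microdata"
    TABULATE_WEIGHTED_SURVEY = "tabulate_weighted_survey"
    NATIONAL_FALLBACK = "national_fallback"


@dataclass(frozen=True)
class SourceCatalogEntry:
    country: str
    continent: str
    data_type: str
    year: int
    admin_level: int
    source: str

    def __post_init__(self):
        if self.continent not in CONTINENTS:
            raise ValueError(f"{self.country}: unknown continent {self.continent!r}")
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"{self.country}: unknown data_type {self.data_type!r}")
        if not (0 <= self.admin_level <= 3):
            raise ValueError(f"{self.country}: admin_level {self.admin_level} not in 0..3")
        if (self.admin_level == 0) != (self.data_type == "UN"):
            raise ValueError(
                f"{self.country}: admin_level 0 if and only if data_type is UN"
            )


def load_catalog(path: str | Path) -> list[SourceCatalogEntry]:
    """Load and validate a catalogue CSV (columns: country, continent,
    data_type, year, admin_level, source).  Duplicate countries rejected."""
    df = pd.read_csv(path)
    missing = {"country", "continent", "data_type", "year", "admin_level", "source"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                SourceCatalogEntry(
                    country=str(row["country"]),
                    continent=str(row["continent"]),
                    data_type=str(row["data_type"]),
                    year=int(row["year"]),
                    admin_level=int(row["admin_level"]),
                    source=str(row["source"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    seen: set[str] = set()
    for e in entries:
        if e.country in seen:
            raise ValueError(f"duplicate country: {e.country}")
        seen.add(e.country)
    return entries


def load_packaged_catalog(continent: str | None = None) -> list[SourceCatalogEntry]:
    """The catalogue shipped with the package (50 Africa + 37 Asia rows)."""
    data_dir = resources.files("demogrid") / "data"
    files = {
        "Africa": data_dir / "sources_africa.csv",
        "Asia": data_dir / "sources_asia.csv",
    }
    if continent is not None:
        return load_catalog(str(files[continent]))
    return load_catalog(str(files["Africa"])) + load_catalog(str(files["Asia"]))


def count_by_type(entries: list[SourceCatalogEntry]) -> dict[str, int]:
    out: dict[str, int] = {}
    for e in entries:
        out[e.data_type] = out.get(e.data_type, 0) + 1
    return out


def route_entry(entry: SourceCatalogEntry) -> ProcessingRoute:
    """Processing path for one catalogue entry (total in data_type)."""
    if entry.data_type == "Census":
        return ProcessingRoute.STANDARDIZE_TABLE
    if entry.data_type == "Census microdata":
        return ProcessingRoute.TABULATE_CENSUS_MICRODATA
    if entry.data_type in _SURVEY_TYPES:
        return ProcessingRoute.TABULATE_WEIGHTED_SURVEY
    return ProcessingRoute.NATIONAL_FALLBACK


def summarize(entries: list[SourceCatalogEntry]) -> pd.DataFrame:
    """Counts per continent x data type, with route, as a tidy frame."""
    rows = [
        {
            "continent": e.continent,
            "data_type": e.data_type,
            "route": route_entry(e).value,
        }
        for e in entries
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["continent", "data_type", "route"]).size().rename("n_countries").reset_index()
    )
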