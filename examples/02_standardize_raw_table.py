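"""Harmonise a raw age table into the standard percentage schema.

A raw census table with single-year counts for ages 0-6 and 5-year bins
above is rebinned onto the 14-group schema (A0004 ... A65PL), converted
to percentages, and validated against the two sum invariants.
"""

import pandas as pd

from demogrid import RawAgeTable, standardize_raw, validate_standard_table
from demogrid.standardize import parse_interval_label

columns = [str(a) for a in range(7)] + [
    "7-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
    "45-49", "50-54", "55-59", "60-64", "65-69", "70+",
]
counts = [310, 300, 295, 290, 285, 280, 270, 790, 1200, 1100, 950, 820, 700,
          610, 530, 450, 380, 310, 240, 180, 220]

idx = pd.MultiIndex.from_tuples([("Exampleland", "NORTH")], names=["NAME", "ADM_NAME"])
raw = RawAgeTable(
    pd.DataFrame([counts], index=idx, columns=columns, dtype=float),
    [parse_interval_label(c) for c in columns],
    value_kind="counts",
)

table = standardize_raw(raw)
report = validate_standard_table(table)

print("standardised row (percent of unit total):")
print(table.round(1).to_string(index=False))
print()
print(f"QA passed: {bool(report['passed'].all())} "
      f"(age groups sum to {report.iloc[0]['age_sum']:.2f})")
# Ages 0-4 pool five single-year counts; 5-6 joins the 7-9 bin inside
# A0509; 65-69 and 70+ collapse into the open A65PL group; counts are
# conserved exactly before the percentage conversion.
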