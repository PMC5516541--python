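"""Inspect the packaged source catalogue and per-country routing.

The catalogue records, for each of 87 African and Asian countries, the
kind of age/sex source used (census table, census microdata, weighted
household survey, or national-estimate fallback) and routes it to the
pipeline stage that processes it.
"""

from demogrid import count_by_type, load_packaged_catalog, route_entry
from demogrid.catalog import summarize

entries = load_packaged_catalog()
print(f"{len(entries)} countries "
      f"({sum(e.continent == 'Africa' for e in entries)} Africa, "
      f"{sum(e.continent == 'Asia' for e in entries)} Asia)")
print()
print("countries per data type:", count_by_type(entries))
print()
print(summarize(entries).to_string(index=False))
print()
for name in ("Bhutan", "Egypt", "Nepal", "Libya"):
    entry = next(e for e in entries if e.country == name)
    print(f"{name}: {entry.data_type} ({entry.year}, admin level "
          f"{entry.admin_level}) -> {route_entry(entry).value}")
# Nine countries have no usable subnational source and fall back to
# national-level estimates applied uniformly within the country mask.
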