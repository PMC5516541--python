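"""Generate a synthetic country and inspect its ground truth.

Builds a small country of 2 provinces x 2 districts on a 20x20-cell grid,
with exponential age pyramids of known steepness, then prints the true
age structure and unit populations that every downstream stage will be
measured against.
"""

from demogrid import GridTemplate, SyntheticCountrySpec, simulate_country

spec = SyntheticCountrySpec(
    seed=42,
    n_admin1=2,
    n_admin2_per_admin1=2,
    grid=GridTemplate(west=10.0, north=10.0, resolution=0.1, n_rows=20, n_cols=20),
    total_population=100_000,
)
country = simulate_country(spec)

print("unit populations (persons):")
print(country.structure.unit_populations.to_string())
print()
print("true age structure, percent per 5-year group (first 4 groups):")
age = country.structure.age_proportions() * 100
print(age.iloc[:, :4].round(2).to_string())
print()
print(f"census microdata rows (5% sample): {len(country.census)}")
print(f"survey microdata rows (two-stage design): {len(country.survey)}")
print(f"population raster total: {country.population.total():.0f} persons")
# The unit populations sum to the 100,000-person country total exactly, and
# the raster conserves each unit's population cell-by-cell.
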