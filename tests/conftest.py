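import numpy as np
import pandas as pd
import pytest

from demogrid import (
    GridTemplate,
    SurveyDesignSpec,
    SyntheticCountrySpec,
    simulate_country,
)


@pytest.fixture(scope="session")
def small_spec():
    """A small but fully featured synthetic country: 2 admin-1 x 2 admin-2."""
    return SyntheticCountrySpec(
        seed=7,
        n_admin1=2,
        n_admin2_per_admin1=2,
        grid=GridTemplate(west=10.0, north=10.0, resolution=0.1, n_rows=20, n_cols=20),
        total_population=200_000,
        census_sample_fraction=0.05,
        survey_design=SurveyDesignSpec(),
        defacto_prob=0.95,
    )


@pytest.fixture(scope="session")
def small_country(small_spec):
    return simulate_country(small_spec)


@pytest.fixture()
def bumthang_row():
    """The worked-example district row: printed age groups only."""
    from demogrid.standardize import load_bhutan_example

    table = load_bhutan_example()
    return table.loc[("Bhutan", "BUMTHANG")]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_microdata(rng, n=1000, n_units=3, weighted=False):
    """Random person rows for oracle comparisons."""
    df = pd.DataFrame(
        {
            "unit_id": rng.integers(1, n_units + 1, n),
            "age": rng.integers(0, 95, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "weight": rng.uniform(0.5, 5.0, n) if weighted else 1.0,
            "de_facto": True,
        }
    )
    return df
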