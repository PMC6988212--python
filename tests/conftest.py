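import io

import numpy as np
import pytest

import apcspline as aps


@pytest.fixture(scope="session")
def toy_csv():
    return io.StringIO(
        "age,period,cases,denom\n"
        "25,2000,10,100\n"
        "35,2000,20,100\n"
        "25,2010,15,100\n"
        "35,2010,30,100\n"
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A modest synthetic survey grid: 12 ages x 6 surveys, 20k per cell."""
    return aps.default_scenario(denom_per_cell=20_000, seed=7,
                                n_ages=12, n_periods=6)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return aps.simulate(small_scenario)


@pytest.fixture(scope="session")
def small_knots(small_dataset):
    return aps.default_knots(small_dataset)


@pytest.fixture(scope="session")
def fitted_pair(small_dataset, small_knots):
    """The same data fitted under both constraint schemes."""
    out = {}
    for name in ("APC", "ACP"):
        scheme = aps.default_scheme(small_dataset, name)
        design = aps.assemble_design(small_dataset, small_knots, scheme)
        out[name] = aps.fit(design)
    return out


@pytest.fixture(scope="session")
def reduced_models(small_dataset, small_knots):
    scheme = aps.default_scheme(small_dataset, "APC")
    return {
        "A+C": aps.fit(aps.assemble_two_term_design(
            small_dataset, small_knots, scheme, "cohort")),
        "A+P": aps.fit(aps.assemble_two_term_design(
            small_dataset, small_knots, scheme, "period")),
    }
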