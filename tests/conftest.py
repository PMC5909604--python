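import pandas as pd
import pytest

import impactsec as im


@pytest.fixture(scope="session")
def default_inputs():
    """One default synthetic scenario shared across tests (read-only)."""
    return im.generate_scenario(im.ScenarioConfig(seed=20070))


@pytest.fixture(scope="session")
def default_result(default_inputs):
    return im.run_pipeline(default_inputs)


@pytest.fixture(scope="session")
def fixture_bundle():
    return im.paper_fixture_bundle()


@pytest.fixture()
def small_grid():
    """A hand-sized mortality table over 2 sexes x 2 bands x 2 quintiles."""
    rows = []
    for i, sex in enumerate(("male", "female")):
        for j, age in enumerate(("55-64", "65-74")):
            for q in (1, 5):
                pop = 10_000.0 + 1_000 * (i + j + q)
                rows.append((sex, age, q, pop, pop * 1.1,
                             100.0 + 10 * (i + 2 * j + q), 40.0 + 5 * (i + j)))
    return pd.DataFrame(
        rows,
        columns=["sex", "age_band", "secq", "pop_base", "pop_final",
                 "deaths_base", "deaths_final"],
    )
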