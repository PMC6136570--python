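import numpy as np
import pandas as pd
import pytest

from ambuecon import CostParameters, GeneratorConfig, generate_survey, make_pilot_log
from ambuecon import defaults


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig.default()


@pytest.fixture(scope="session")
def survey_responses(default_config):
    """One synthetic survey at the pilot study's published group sizes."""
    return generate_survey(default_config)


@pytest.fixture(scope="session")
def pilot_log():
    return make_pilot_log()


@pytest.fixture(scope="session")
def params() -> CostParameters:
    return CostParameters()


@pytest.fixture(scope="session")
def published_preference_counts() -> pd.DataFrame:
    """The published 4 groups x 3 services pay-preference count table."""
    return pd.DataFrame(
        [counts for counts in defaults.PREFERENCE_FREQS.values()],
        index=[g.value for g in defaults.PREFERENCE_FREQS],
        columns=["field_to_hospital", "hospital_to_hospital", "home_visit"],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(defaults.DEFAULT_SEED)
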