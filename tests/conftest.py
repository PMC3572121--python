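import numpy as np
import pandas as pd
import pytest

from emailnet import builders, ingest
from emailnet.synthetic import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_people=200, seed=3)


@pytest.fixture(scope="session")
def small_pop(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_pairs(small_pop):
    filtered = ingest.filter_internal(small_pop.email_log, small_pop.survey.people)
    return ingest.aggregate_pairs(filtered)


@pytest.fixture(scope="session")
def small_survey_net(small_pop):
    return builders.build_survey_network(small_pop.survey)


@pytest.fixture(scope="session")
def small_features(small_pairs, small_survey_net):
    return builders.build_feature_table(small_pairs, small_survey_net)


@pytest.fixture
def toy_pairs() -> pd.DataFrame:
    """Hand-sized pair summaries: A<->B heavy, A->C light, B->C multi-only."""
    return pd.DataFrame(
        {
            "sender_id": ["A", "B", "A", "B", "C"],
            "recipient_id": ["B", "A", "C", "C", "D"],
            "n_single": [30, 15, 2, 0, 1],
            "n_multi": [4, 0, 0, 3, 0],
            "size_sum": [5000, 2500, 100, 900, 40],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
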