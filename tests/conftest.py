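import pytest
from hypothesis import settings

from ethnosurvey import (SimConfig, fixture_shahrbabak, load_category_map,
                         preprocess, simulate_survey)

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def shahrbabak():
    """The packaged survey fixture (dataset + presence matrix)."""
    return fixture_shahrbabak()


@pytest.fixture(scope="session")
def category_map():
    return load_category_map()


@pytest.fixture(scope="session")
def feature_table(shahrbabak, category_map):
    dataset, _ = shahrbabak
    return preprocess(dataset, category_map)


@pytest.fixture()
def small_survey():
    """A small simulated survey with known ground truth."""
    return simulate_survey(SimConfig(n_informants=15, n_species=40,
                                     n_categories=6, seed=7,
                                     citation_rate=0.12))
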