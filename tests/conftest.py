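import warnings

import numpy as np
import pytest
from hypothesis import settings

import metainsight as mi
from metainsight.model import CohortData, SamplerConfig

# arviz announces its refactor on import; irrelevant to these tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def h1_small_cohort():
    """Reduced full-insight cohort (25 subjects) in expected-count mode."""
    scen = mi.make_scenario("full_insight").with_size(n_subjects=25)
    return mi.simulate_cohort(scen, seed=31, mode="expected")


@pytest.fixture(scope="session")
def h1_small_fit(h1_small_cohort):
    """Insight-model fit of the reduced cohort, reused across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mi.fit_insight_model(
            CohortData.from_cohort(h1_small_cohort),
            config=SamplerConfig(chains=2, draws=500, warmup=500),
            seed=7,
        )


@pytest.fixture(scope="session")
def trial_table():
    """Trial-level table for a small cohort (both conditions, clean)."""
    scen = mi.make_scenario("no_insight").with_size(n_subjects=8)
    return mi.cohort_trials(scen, seed=5)
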