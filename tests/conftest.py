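import logging

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")
logging.getLogger("omu_synergy").setLevel(logging.ERROR)

from omu_synergy import StudyConfig, SynergyModel, generate_study
from omu_synergy.model import PipelineOptions


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study for fast integration tests."""
    return generate_study(
        StudyConfig(n_drugs=10, n_tfs=18, n_genes=80, n_planted_modules=4, seed=11)
    )


@pytest.fixture(scope="session")
def small_results(small_study):
    model = SynergyModel.from_study(small_study, options=PipelineOptions(seed=11))
    return model.fit()


@pytest.fixture(scope="session")
def study20():
    """Default-sized 20-drug study (the standard pipeline conditions)."""
    return generate_study(StudyConfig(n_drugs=20, seed=1))


@pytest.fixture(scope="session")
def results20(study20):
    model = SynergyModel.from_study(study20, options=PipelineOptions(seed=1))
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
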