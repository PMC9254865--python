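import numpy as np
import pytest

from psmcea import PartitionedSurvivalModel

LENV_PEMB = "lenvatinib_pembrolizumab"
LENV_EVER = "lenvatinib_everolimus"
SUNITINIB = "sunitinib"


@pytest.fixture(scope="session")
def fixture_model() -> PartitionedSurvivalModel:
    """The shipped surrogate calibration (three strategies, 5 y horizon)."""
    return PartitionedSurvivalModel.clear_fixture()


@pytest.fixture(scope="session")
def base_results(fixture_model):
    return fixture_model.fit()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
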