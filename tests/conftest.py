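import numpy as np
import pytest

from idletrace.barcodes import BarcodeDesign
from idletrace.population import (
    LineagePopulation,
    PhenotypeLandscape,
    PhenotypeState,
)


@pytest.fixture
def design() -> BarcodeDesign:
    return BarcodeDesign()


@pytest.fixture
def tiny_design() -> BarcodeDesign:
    return BarcodeDesign(shared_prefix="GT", sw_pattern="SWSW")


@pytest.fixture
def one_state_growing() -> PhenotypeLandscape:
    return PhenotypeLandscape(
        (PhenotypeState("s", 0.03, 0.01),), np.zeros((1, 1)), label="grow"
    )


@pytest.fixture
def balanced_two_state() -> PhenotypeLandscape:
    states = (
        PhenotypeState("slow", 0.02, 0.02),
        PhenotypeState("fast", 0.05, 0.05),
    )
    k = np.array([[0.0, 0.01], [0.01, 0.0]])
    return PhenotypeLandscape(states, k, label="balanced")


@pytest.fixture
def small_population() -> LineagePopulation:
    return LineagePopulation.uniform(["L1", "L2", "L3"], 2, 50)
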