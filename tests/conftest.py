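import numpy as np
import pytest

from neuromine.synthetic import worked_example_precursors


@pytest.fixture(scope="session")
def worked_examples() -> dict[str, str]:
    """Synthetic stand-ins for the published worked-example precursors."""
    return worked_example_precursors()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180727)


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def amino_acids() -> str:
    return AMINO_ACIDS
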