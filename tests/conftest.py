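import numpy as np
import pytest
from hypothesis import settings

from readsieve import GenePanel

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_panel(rng: np.random.Generator, n_genes: int, length: int) -> GenePanel:
    return GenePanel([(f"g{i}", random_dna(rng, length)) for i in range(n_genes)])


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def toy_panel(rng):
    return random_panel(rng, 5, 300)
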