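import numpy as np
import pytest

from gbs3d import Genome, builtin_registry
from gbs3d.simulate import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def random_genome_2mb():
    """Uniform-composition 2 Mb genome for statistical digestion checks."""
    return make_genome(GenomeSpec(n_sequences=1, length=2_000_000, gc=0.5, seed=42))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
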