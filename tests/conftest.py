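import numpy as np
import pytest

from apvkit.synth import GenomeSpec, generate_genome


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_aa(rng: np.random.Generator, n: int) -> str:
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(letters[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="session")
def default_genome():
    """One canonical synthetic genome with its ground truth (shared, read-only)."""
    return generate_genome(GenomeSpec(seed=11))


@pytest.fixture(scope="session")
def gtg_genome():
    """A puffin-virus-like genome whose L1 starts with GTG."""
    return generate_genome(GenomeSpec(seed=12, l1_start="GTG"))
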