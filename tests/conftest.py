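import numpy as np
import pytest

from hgtscan.core_encoding import HashFunctionSet, build_hash_functions
from hgtscan.reference_io import ReferenceDatabase


@pytest.fixture(scope="session")
def hfs16() -> HashFunctionSet:
    """Small hash-function set shared by table-level tests."""
    return build_hash_functions(k=16, ell=3, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture()
def two_genome_ref(rng) -> ReferenceDatabase:
    """Two random 2 kb genomes of distinct species."""
    seqs = {"gA": random_dna(rng, 2000), "gB": random_dna(rng, 2000)}
    return ReferenceDatabase(sequences=seqs, species_of={"gA": "sA", "gB": "sB"})
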