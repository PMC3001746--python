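import numpy as np
import pytest

from pash3 import SequenceRecord, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    """10-kb random genome shared by mapper unit tests."""
    return random_genome(10_000, 0.5, seed=77)


@pytest.fixture(scope="session")
def small_genome_records(small_genome):
    return [SequenceRecord("chr1", small_genome)]
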