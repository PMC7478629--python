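import numpy as np
import pytest

from mge_scout import generate_table_suite

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


@pytest.fixture(scope="session")
def table_suite():
    """The four element-archetype fixtures (generated once per session)."""
    return generate_table_suite(seed=100)
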