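import pytest

from eprobedesign import default_table


@pytest.fixture(scope="session")
def table():
    """Shipped default nearest-neighbor parameter table."""
    return default_table()


@pytest.fixture()
def rng():
    import numpy as np

    return np.random.default_rng(20260921)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
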