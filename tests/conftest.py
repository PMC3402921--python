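import random

import pytest
from hypothesis import HealthCheck, settings

from stackpath import (
    RnaSequence,
    SecondaryStructure,
    load_energy_backend,
    parse_structure,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_x() -> RnaSequence:
    return RnaSequence("GGGGAAAACCCCUUUU")


@pytest.fixture(scope="session")
def toy_A() -> SecondaryStructure:
    return parse_structure("((((....))))....")


@pytest.fixture(scope="session")
def toy_B() -> SecondaryStructure:
    return parse_structure("....((((....))))")


@pytest.fixture(scope="session")
def simple_model():
    return load_energy_backend("simple")


@pytest.fixture(scope="session")
def turner_model():
    return load_energy_backend("turner", "turner1999")


def random_valid_structure(
    rng: random.Random, n: int, max_pairs: int = 8, min_hairpin: int = 3
) -> SecondaryStructure:
    """Build a random pseudoknot-free structure by rejection sampling."""
    from stackpath import PairFate, classify_pair

    S = SecondaryStructure()
    for _ in range(max_pairs * 4):
        if len(S) >= max_pairs:
            break
        i = rng.randint(1, n - min_hairpin - 1)
        j = rng.randint(i + min_hairpin + 1, n)
        if classify_pair(S, (i, j)) is PairFate.OK:
            S = S.with_pair((i, j))
    return S
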