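import numpy as np
import pytest

from sinekit.synthetic import (
    make_background,
    make_default_family,
    make_donor_library,
    plant_family,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def donor_library():
    return make_donor_library(seed=11)


@pytest.fixture(scope="session")
def family_spec(donor_library):
    donors, _ = donor_library
    return make_default_family(donors)


@pytest.fixture(scope="session")
def exact_genome(family_spec):
    """50 mutation-free, non-truncated insertions: clean ground truth."""
    genome = make_background(200_000, 0.42, seed=21)
    genome, truths = plant_family(
        genome, family_spec, n=50, divergence=0.0, trunc_prob=0.0, seed=22
    )
    return genome, truths


@pytest.fixture(scope="session")
def diverged_genome(family_spec):
    """30 insertions at 2% divergence with default truncation."""
    genome = make_background(200_000, 0.42, seed=31)
    genome, truths = plant_family(
        genome, family_spec, n=30, divergence=0.02, trunc_prob=0.2, seed=32
    )
    return genome, truths
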