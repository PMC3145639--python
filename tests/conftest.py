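import numpy as np
import pytest

from kinspec import (
    BackgroundFrequencies,
    SimilarityPolicy,
    load_substitution_matrix,
)
from kinspec.alphabet import SERINE_THREONINE
from kinspec.synthetic import SyntheticSpec, generate_database


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def default_policy(blosum62):
    return SimilarityPolicy(blosum62, cutoff=1)


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundFrequencies(b=np.full(20, 0.05), kinase_type=SERINE_THREONINE)


@pytest.fixture(scope="session")
def small_db():
    """A 5-family, 50-sites-per-family synthetic database with truth map."""
    return generate_database(SyntheticSpec(seed=11, n_kinase_families=5))


@pytest.fixture(scope="session")
def medium_db():
    """A 200-record (4 x 50) database used for query property tests."""
    return generate_database(SyntheticSpec(seed=23, n_kinase_families=4))
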