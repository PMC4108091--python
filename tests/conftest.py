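import numpy as np
import pytest

from endemicity import IncidenceMatrix


def random_matrix(rng, n_species, n_areas, density=0.5):
    pres = (rng.random((n_species, n_areas)) < density).astype(int)
    return IncidenceMatrix(
        tuple(f"sp{j}" for j in range(n_species)),
        tuple(f"A{j}" for j in range(n_areas)),
        pres,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_matrix():
    """2 species x 2 areas, diagonal presences."""
    return IncidenceMatrix(("sp1", "sp2"), ("A", "B"), np.array([[1, 0], [0, 1]]))
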