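import numpy as np
import pytest

import traitspaces as ts


@pytest.fixture
def unit_square() -> ts.TraitSpace:
    """Four points at the corners of the unit square: the canonical toy space."""
    return ts.TraitSpace(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float))


@pytest.fixture(scope="session")
def small_study() -> ts.StudyReport:
    """A scaled-down study (2 replicates) shared by pipeline tests."""
    return ts.run_study(n_replicates=2, base_seed=11)


@pytest.fixture(scope="session")
def default_study() -> ts.StudyReport:
    """The full default study (13 space types x 20 replicates)."""
    return ts.run_study(base_seed=42)


def random_space(n: int, d: int, seed: int) -> ts.TraitSpace:
    rng = np.random.default_rng(seed)
    return ts.TraitSpace(rng.normal(size=(n, d)))
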