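import numpy as np
import pytest

from codhet import (
    CauseProfile,
    ScenarioSpec,
    dissimilarity_matrix,
    gbd_fixture_tree,
    generate_tree,
    uniform_dissimilarity,
)


@pytest.fixture(scope="session")
def fixture_tree():
    """Packaged GBD-style 3-level tree (3 / 22 / 133 nodes per level)."""
    return gbd_fixture_tree()


@pytest.fixture(scope="session")
def fixture_dmat(fixture_tree):
    return dissimilarity_matrix(fixture_tree)


@pytest.fixture
def society_a():
    """Three equal-share causes, all pairwise dissimilarity 2/3 (three
    injury-like causes in distinct level-2 groups of one level-1 group)."""
    tree = generate_tree(ScenarioSpec(branching=(1, 3, 1)))
    profile = CauseProfile(tree.analysis_causes, np.full(3, 1 / 3))
    return tree, profile


@pytest.fixture
def society_b():
    """Three equal-share causes in three distinct level-1 groups (all
    pairwise dissimilarity 1)."""
    tree = generate_tree(ScenarioSpec(branching=(3, 1, 1)))
    profile = CauseProfile(tree.analysis_causes, np.full(3, 1 / 3))
    return tree, profile


def random_tree(rng, max_depth=4, max_branch=4):
    """Random uniform-branching tree for property tests."""
    depth = int(rng.integers(2, max_depth + 1))
    branching = tuple(int(rng.integers(1, max_branch + 1)) for _ in range(depth))
    return generate_tree(ScenarioSpec(branching=branching))


def random_profile(rng, causes, concentration=1.0):
    shares = rng.dirichlet(np.full(len(causes), concentration))
    return CauseProfile(tuple(causes), shares)


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)
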