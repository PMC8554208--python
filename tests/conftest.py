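import numpy as np
import pytest

from fntstack.deep_forest import CascadeConfig, GcForestConfig, ScanConfig
from fntstack.evolve import EvolutionConfig, random_tree
from fntstack.synthetic import generate_worked_fixture


@pytest.fixture
def worked_fixture():
    """Fixed 2-operator/3-leaf tree, 4 inputs, hand-computed outputs."""
    return generate_worked_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_trees(rng):
    """A batch of random valid trees over 9 inputs."""
    return [random_tree(9, (2, 3, 4, 5), 4, rng) for _ in range(50)]


@pytest.fixture
def lean_gcforest_config():
    """Small forests for fast tests; structure identical to the default."""
    return GcForestConfig(
        scan=ScanConfig(trees_per_forest=10, seed=0),
        cascade=CascadeConfig(trees_per_forest=25, max_layers=5, seed=0),
    )


@pytest.fixture
def lean_evolution_config():
    """A reduced search budget for unit tests of the evolutionary loop."""
    return EvolutionConfig(population_size=12, generations=6, seed=0)
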