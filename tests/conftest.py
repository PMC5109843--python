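import numpy as np
import pytest

from sabre import DiscoveryConfig, GeneModule, ModuleSet, PlantedDesign, generate_planted


@pytest.fixture(scope="session")
def planted():
    """Default planted-module matrix and ground truth (3x60 blocks, r=0.8)."""
    return generate_planted(PlantedDesign(seed=11))


@pytest.fixture(scope="session")
def planted_x(planted):
    return planted[0]


@pytest.fixture(scope="session")
def planted_truth(planted):
    return planted[1]


@pytest.fixture(scope="session")
def default_config():
    return DiscoveryConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_module_set(rng, universe, n_modules, module_size, prefix="Q"):
    """Disjoint random modules over a universe; remainder unassigned."""
    chosen = rng.choice(sorted(universe), size=n_modules * module_size, replace=False)
    modules = tuple(
        GeneModule(f"{prefix}{i:02d}", frozenset(chosen[i * module_size : (i + 1) * module_size]))
        for i in range(n_modules)
    )
    assigned = set().union(*[m.members for m in modules])
    return ModuleSet(modules, frozenset(universe) - assigned)


@pytest.fixture()
def make_random_module_set(rng):
    def _make(universe, n_modules=5, module_size=8, prefix="Q"):
        return random_module_set(rng, universe, n_modules, module_size, prefix)

    return _make
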