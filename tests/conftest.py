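import numpy as np
import pytest

from netatrophy import (
    SimulationConfig,
    build_morphological_network,
    group_difference,
    simulate_study,
)
from netatrophy.datatypes import ParcellationScheme


@pytest.fixture(scope="session")
def study():
    """One default-condition simulated study shared across read-only tests."""
    scheme, connectomes, cohort, truth = simulate_study(seed=11)
    return {
        "scheme": scheme,
        "connectomes": connectomes,
        "cohort": cohort,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def smn(study):
    controls, _ = study["cohort"].split()
    return build_morphological_network(controls)


@pytest.fixture(scope="session")
def thinning(study):
    return group_difference(study["cohort"]).z


@pytest.fixture()
def tiny_scheme():
    """Six regions, three per hemisphere, hand-placed on the unit spheres."""
    cents = np.array([
        [0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
    ])
    return ParcellationScheme(
        names=np.array(["lh_a", "lh_b", "lh_c", "rh_a", "rh_b", "rh_c"], dtype=object),
        hemisphere=np.array(["left"] * 3 + ["right"] * 3, dtype=object),
        centroids=cents,
    )


def random_graph_and_map(rng, n=20, density=0.3):
    """A random connected-ish symmetric graph plus weights and a map."""
    sc = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < density
    sc[iu[0][mask], iu[1][mask]] = rng.random(mask.sum()) + 0.05
    sc = sc + sc.T
    weights = rng.normal(0.0, 1.0, (n, n))
    weights = (weights + weights.T) / 2
    np.fill_diagonal(weights, 0.0)
    t = rng.normal(0.0, 1.0, n)
    return sc, weights, t
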