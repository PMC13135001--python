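import numpy as np
import pytest

import spatlc as sl


@pytest.fixture(scope="session")
def tiny_config():
    """Small study condition used by fast unit tests (not the desk-scale default)."""
    return sl.SimConfig(seed=7, n_provinces=9, n_regions=2, n_island_provinces=2,
                        max_age=12, n_years=5)


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    graph, spec, truth, dataset = sl.simulate(tiny_config)
    return {"config": tiny_config, "graph": graph, "spec": spec,
            "truth": truth, "dataset": dataset}


@pytest.fixture(scope="session")
def path_graph():
    """1 - 2 - 3 path."""
    return sl.AdjacencyGraph(3, {1: frozenset({2}), 2: frozenset({1, 3}), 3: frozenset({2})})


def random_graph(rng: np.random.Generator, n: int, p_edge: float = 0.15) -> sl.AdjacencyGraph:
    """Erdos-Renyi-style random symmetric graph (possibly disconnected)."""
    nbrs = {i: set() for i in range(1, n + 1)}
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if rng.uniform() < p_edge:
                nbrs[i].add(j)
                nbrs[j].add(i)
    return sl.AdjacencyGraph(n, {i: frozenset(s) for i, s in nbrs.items()})
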