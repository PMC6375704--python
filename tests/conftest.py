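import numpy as np
import pytest

from tfreciprocity import Edge, RateGraph, RateTable
from tfreciprocity.fixtures import mixture, rate_table, residence_table


@pytest.fixture
def fig2d() -> RateTable:
    return rate_table("fig2D")


@pytest.fixture
def fig2e() -> RateTable:
    return rate_table("fig2E")


@pytest.fixture
def residence():
    return residence_table()


@pytest.fixture
def fig3b():
    return mixture("fig3B")


@pytest.fixture
def fig3c():
    return mixture("fig3C")


@pytest.fixture
def fig3d():
    return mixture("fig3D")


def random_reversible_graph(rng: np.random.Generator, n_max: int = 6) -> RateGraph:
    """A random strongly connected reversible graph with rates in [0.1, 10].

    A random spanning tree guarantees connectivity; extra reversible pairs are
    sprinkled on top.
    """
    n = int(rng.integers(2, n_max + 1))
    vertices = [f"v{i}" for i in range(n)]
    pairs = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        pairs.add((min(i, j), max(i, j)))
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for i, j in possible:
        if rng.random() < 0.4:
            pairs.add((i, j))
    edges = []
    for i, j in sorted(pairs):
        edges.append(Edge(vertices[i], vertices[j], rate=float(10 ** rng.uniform(-1, 1))))
        edges.append(Edge(vertices[j], vertices[i], rate=float(10 ** rng.uniform(-1, 1))))
    return RateGraph(vertices=vertices, edges=edges)


def random_rate_table(rng: np.random.Generator) -> RateTable:
    vals = 10 ** rng.uniform(-1, 1, size=8)
    concs = 10 ** rng.uniform(-1, 1, size=2)
    return RateTable(
        k1_on=vals[0], k2_on=vals[1], k3_on=vals[2], k4_on=vals[3],
        k1_off=vals[4], k2_off=vals[5], k3_off=vals[6], k4_off=vals[7],
        conc_S=concs[0], conc_O=concs[1],
    )
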