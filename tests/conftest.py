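import numpy as np
import pytest

from virisome.synthetic_community import (
    default_anchor_panel,
    default_marker_panel,
    generate_community,
    load_bundled_spec,
)


@pytest.fixture(scope="session")
def anchors():
    return default_anchor_panel()


@pytest.fixture(scope="session")
def pola_anchor(anchors):
    return anchors["PolA_anchor"]


@pytest.fixture(scope="session")
def nrda_anchor(anchors):
    return anchors["NrdA_anchor"]


@pytest.fixture(scope="session")
def panel():
    return default_marker_panel()


@pytest.fixture(scope="session")
def small_community():
    """A down-scaled bundled community shared across tests (seeded)."""
    spec = load_bundled_spec(seed=4242)
    for group in spec.groups.values():
        group.count = max(6, group.count // 25)
    spec.total_reads = 3000
    return generate_community(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_additive_matrix(n_taxa, rng):
    """Distances from a random unrooted binary tree built by attaching each
    new leaf to a random existing edge, with positive branch lengths."""
    import networkx as nx

    from virisome.clustering import DistanceMatrix

    g = nx.Graph()
    g.add_edge("t0", "v0", length=float(rng.uniform(0.05, 1.0)))
    g.add_edge("t1", "v0", length=float(rng.uniform(0.05, 1.0)))
    g.add_edge("t2", "v0", length=float(rng.uniform(0.05, 1.0)))
    fresh = 1
    for k in range(3, n_taxa):
        edges = list(g.edges)
        u, v = edges[int(rng.integers(0, len(edges)))]
        old = g.edges[u, v]["length"]
        g.remove_edge(u, v)
        mid = f"v{fresh}"
        fresh += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, length=old * split)
        g.add_edge(mid, v, length=old * (1 - split))
        g.add_edge(f"t{k}", mid, length=float(rng.uniform(0.05, 1.0)))
    ids = [f"t{i}" for i in range(n_taxa)]
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d[i, j] = d[j, i] = lengths[a][b]
    return g, DistanceMatrix(ids=ids, d=d)
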