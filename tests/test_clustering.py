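"""AAI distances, furthest-neighbour and hit-graph clustering, core genes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virisome.clustering import (
    ClusterSet,
    DistanceMatrix,
    choose_representative,
    core_clusters,
    furthest_neighbor_clusters,
    homology_graph_clusters,
    identity_distance_matrix,
    source_overlap,
)
from virisome.seq_io import PeptideRecord


def test_identity_distance_examples():
    dm = identity_distance_matrix(["a", "b", "c"], ["AAAA", "AAAT", "AAAA"])
    assert dm.value("a", "c") == 0.0
    assert dm.value("a", "b") == pytest.approx(0.25)


def test_identity_distance_matches_bruteforce_recount(rng):
    """Independent per-pair recount over anchored columns."""
    alphabet = "ACDE-"
    ids = [f"p{i}" for i in range(8)]
    rows = [
        "".join(rng.choice(list(alphabet), size=30)).replace("--", "A-")
        for _ in ids
    ]
    rows = [r if set(r) != {"-"} else "A" * 30 for r in rows]
    dm = identity_distance_matrix(ids, rows)

    def recount(a, b):
        res_a = [i for i, c in enumerate(a) if c != "-"]
        res_b = [i for i, c in enumerate(b) if c != "-"]
        lo, hi = max(res_a[0], res_b[0]), min(res_a[-1], res_b[-1])
        if hi < lo:
            return 1.0
        cols = [i for i in range(lo, hi + 1) if a[i] != "-" or b[i] != "-"]
        if not cols:
            return 1.0
        match = sum(1 for i in cols if a[i] == b[i] and a[i] != "-")
        return 1 - match / len(cols)

    for i, j in itertools.combinations(range(len(dm.ids)), 2):
        a = rows[ids.index(dm.ids[i])]
        b = rows[ids.index(dm.ids[j])]
        assert dm.d[i, j] == pytest.approx(recount(a, b))


def test_furthest_neighbor_three_point_example():
    dm = DistanceMatrix(
        ids=["A", "B", "C"],
        d=np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]]),
    )
    cs = furthest_neighbor_clusters(dm, cutoff=0.25)
    assert sorted(sorted(c) for c in cs.clusters) == [["A", "B"], ["C"]]


def test_furthest_neighbor_degenerate_cases():
    zero = DistanceMatrix(ids=list("ABC"), d=np.zeros((3, 3)))
    assert len(furthest_neighbor_clusters(zero, 0.25)) == 1
    distinct = DistanceMatrix(
        ids=list("ABC"), d=1 - np.eye(3)
    )
    assert len(furthest_neighbor_clusters(distinct, 0.0)) == 3
    with pytest.raises(ValueError):
        furthest_neighbor_clusters(zero, 1.5)


def test_furthest_neighbor_diameter_invariant_and_monotonicity(rng):
    n = 20
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d = d / d.max()
    dm = DistanceMatrix(ids=[f"x{i:02d}" for i in range(n)], d=d)
    previous = None
    for cutoff in [0.0, 0.1, 0.25, 0.5, 1.0]:
        cs = furthest_neighbor_clusters(dm, cutoff)
        for cluster in cs.clusters:
            idx = [dm.ids.index(m) for m in cluster]
            assert d[np.ix_(idx, idx)].max() <= cutoff + 1e-12
        if previous is not None:
            assert len(cs) <= previous
        previous = len(cs)


def test_choose_representative_rules():
    peptides = {
        "a": PeptideRecord(id="a", sequence="M" * 200),
        "b": PeptideRecord(id="b", sequence="M" * 300),
        "c": PeptideRecord(id="c", sequence="M" * 300),
    }
    assert choose_representative(frozenset({"a", "b"}), peptides) == "b"
    assert choose_representative(frozenset({"b", "c"}), peptides) == "b"
    assert choose_representative(frozenset({"a"}), peptides) == "a"


def _partition(shared, a_only, b_only):
    clusters, source_of = [], {}
    k = 0
    for n, members in (
        (shared, ("A", "B")),
        (a_only, ("A",)),
        (b_only, ("B",)),
    ):
        for _ in range(n):
            ids = [f"m{k}_{s}" for s in members]
            clusters.append(frozenset(ids))
            for name, s in zip(ids, members):
                source_of[name] = s
            k += 1
    return ClusterSet(clusters=clusters), source_of


def test_source_overlap_study_arithmetic():
    """69 shared + 31 a-only + 81 b-only clusters -> 181 total, and the
    shared share of a-containing clusters is 69/100."""
    cs, source_of = _partition(69, 31, 81)
    overlap = source_overlap(cs, source_of, "A", "B")
    assert (overlap.shared, overlap.a_only, overlap.b_only) == (69, 31, 81)
    assert overlap.total == 181
    assert overlap.shared_fraction_of_a == pytest.approx(0.69)


def test_source_overlap_single_source_and_errors():
    cs, source_of = _partition(0, 3, 2)
    overlap = source_overlap(cs, source_of, "A", "B")
    assert overlap.shared == 0 and overlap.total == 5
    with pytest.raises(KeyError):
        source_overlap(cs, {}, "A", "B")


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    n=st.integers(2, 20),
    edge_seed=st.integers(0, 10_000),
)
def test_homology_graph_equals_bruteforce_components(n, edge_seed):
    rng = np.random.default_rng(edge_seed)
    ids = [f"n{i}" for i in range(n)]
    peptides = [PeptideRecord(id=i, sequence="M") for i in ids]
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.15
    ]
    cs = homology_graph_clusters(peptides, precomputed_edges=edges)

    # brute-force reachability oracle
    adjacency = {i: set() for i in ids}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen, components = set(), []
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    assert set(cs.clusters) == set(components)


def test_homology_graph_transitive_closure_and_singletons():
    peptides = [PeptideRecord(id=i, sequence="M") for i in "ABC"]
    cs = homology_graph_clusters(peptides, precomputed_edges=[("A", "B"), ("B", "C")])
    assert cs.clusters == [frozenset("ABC")]
    cs2 = homology_graph_clusters(peptides, precomputed_edges=[])
    assert len(cs2) == 3


def test_homology_graph_with_real_alignments(panel, rng):
    from virisome.synthetic_community import mutate_peptide, random_peptide

    base = panel.by_family("DnaB-like")[0].sequence
    related1 = PeptideRecord(id="r1", sequence=mutate_peptide(base, 0.9, seed=rng))
    related2 = PeptideRecord(id="r2", sequence=mutate_peptide(base, 0.85, seed=rng))
    loner = PeptideRecord(id="lone", sequence=random_peptide(300, seed=rng))
    cs = homology_graph_clusters([related1, related2, loner], e_cutoff=1e-20)
    assert frozenset({"r1", "r2"}) in cs.clusters
    assert frozenset({"lone"}) in cs.clusters


def test_core_clusters_rule_boundaries():
    cs = ClusterSet(
        clusters=[
            frozenset({"g1_a", "g1_b"}),   # on contigs c1, c2 of clade 1 (2/4)
            frozenset({"g2_a"}),           # on contig c5 of clade 2 (1/3)
            frozenset({"g3_a"}),           # on contig c8 (singleton clade)
        ]
    )
    contig_of = {"g1_a": "c1", "g1_b": "c2", "g2_a": "c5", "g3_a": "c8"}
    clade_of = {
        "c1": 1, "c2": 1, "c3": 1, "c4": 1,
        "c5": 2, "c6": 2, "c7": 2,
        "c8": 3,
    }
    core = core_clusters(cs, contig_of, clade_of, fraction=0.5)
    assert core[1] == [frozenset({"g1_a", "g1_b"})]   # 2 of 4 -> core
    assert core[2] == []                               # 1 of 3 -> not core
    assert core[3] == [frozenset({"g3_a"})]            # singleton clade
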