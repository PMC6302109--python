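"""NJ trees, bootstrap supports, anchored stacking, clade assignment."""

import numpy as np
import pytest

from virisome.clustering import DistanceMatrix
from virisome.phylogeny import (
    AnchoredMSA,
    PhyloTree,
    assign_clade,
    bootstrap_support,
    concatenate_markers,
    concatenated_msa,
    neighbor_joining,
    p_distance,
    resolve_clades_by_tree,
    stack_anchored_alignment,
)
from virisome.seq_io import PeptideRecord


from conftest import random_additive_matrix


def _patristic(tree: PhyloTree):
    return tree.leaf_distances()


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(
        ids=["a", "b", "c"],
        d=np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
    )
    tree = neighbor_joining(dm)
    dist = _patristic(tree)
    assert dist[("a", "b")] == pytest.approx(0.4)
    assert dist[("a", "c")] == pytest.approx(0.6)
    assert dist[("b", "c")] == pytest.approx(0.8)


def test_nj_requires_three_taxa():
    dm = DistanceMatrix(ids=["a", "b"], d=np.array([[0, 0.1], [0.1, 0]]))
    with pytest.raises(ValueError):
        neighbor_joining(dm)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices_exactly(n_taxa):
    """NJ reproduces random additive matrices (topology and path lengths)."""
    rng = np.random.default_rng(n_taxa)
    for _ in range(12):
        true_tree, dm = random_additive_matrix(n_taxa, rng)
        nj = neighbor_joining(dm)
        dist = _patristic(nj)
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1 :]:
                assert dist[(a, b)] == pytest.approx(dm.value(a, b), abs=1e-9)


def test_newick_round_trip_preserves_everything():
    dm = DistanceMatrix(
        ids=["a", "b", "c", "d"],
        d=np.array(
            [
                [0.0, 0.3, 0.7, 0.8],
                [0.3, 0.0, 0.6, 0.7],
                [0.7, 0.6, 0.0, 0.5],
                [0.8, 0.7, 0.5, 0.0],
            ]
        ),
    )
    tree = neighbor_joining(dm)
    back = PhyloTree.from_newick(tree.to_newick())
    assert back.leaf_ids == tree.leaf_ids
    assert back.bipartitions() == tree.bipartitions()
    d0, d1 = _patristic(tree), _patristic(back)
    for key in d0:
        assert d1[key] == pytest.approx(d0[key], abs=1e-9)


def test_p_distance_counts_shared_columns():
    msa = AnchoredMSA(
        ids=["a", "b"],
        rows=["A" * 90 + "C" * 10, "A" * 90 + "G" * 10],
    )
    dm = p_distance(msa)
    assert dm.value("a", "b") == pytest.approx(0.10)
    with pytest.raises(ValueError, match="share no columns"):
        p_distance(AnchoredMSA(ids=["a", "b"], rows=["A---", "---C"]))


def test_stacking_on_anchor_window(pola_anchor):
    rec = PeptideRecord(id="anchor", sequence=pola_anchor.peptide)
    msa = stack_anchored_alignment([rec], pola_anchor, "partial")
    assert msa.n_columns == 125
    assert "-" not in msa.rows[0]
    start, end = pola_anchor.named_windows["partial"]
    assert msa.rows[0] == pola_anchor.peptide[start - 1 : end]


def test_stacking_marks_deletions_as_gaps(pola_anchor):
    ref = pola_anchor.peptide
    query = PeptideRecord(id="d", sequence=ref[:699] + ref[704:])  # del 700-704
    msa = stack_anchored_alignment([query], pola_anchor, "partial")
    start, _ = pola_anchor.named_windows["partial"]
    cols = [700 - start, 701 - start, 702 - start, 703 - start, 704 - start]
    assert all(msa.rows[0][c] == "-" for c in cols)
    assert msa.rows[0].count("-") == 5


def test_bootstrap_supports_separate_clear_groups():
    rows = (
        ["A" * 60 + "C" * 60] * 2
        + ["G" * 60 + "T" * 60] * 2
    )
    msa = AnchoredMSA(ids=["a1", "a2", "b1", "b2"], rows=rows)
    tree = bootstrap_support(msa, n_reps=10, seed=3)
    labelled = [
        node.label
        for node in tree.tree.preorder_node_iter()
        if node.label is not None and not node.is_leaf()
    ]
    assert labelled and all(float(l) == 1.0 for l in labelled)


def test_bootstrap_is_seed_deterministic():
    rng = np.random.default_rng(5)
    rows = ["".join(rng.choice(list("ACDE"), size=40)) for _ in range(5)]
    msa = AnchoredMSA(ids=[f"s{i}" for i in range(5)], rows=rows)
    t1 = bootstrap_support(msa, n_reps=5, seed=11).to_newick()
    t2 = bootstrap_support(msa, n_reps=5, seed=11).to_newick()
    assert t1 == t2


def test_concatenation_length_and_membership(pola_anchor, nrda_anchor):
    pola_block = pola_anchor.peptide[783:926]  # concat window, 143 aa
    rnr_block = nrda_anchor.peptide[436:625]   # rnr region, 189 aa
    records = concatenate_markers(
        {"c1": pola_block, "c2": pola_block}, {"c1": rnr_block}
    )
    assert [r.id for r in records] == ["c1"]  # c2 lacks RNR -> excluded
    assert len(records[0].sequence) == 332
    msa = concatenated_msa(
        AnchoredMSA(ids=["c1"], rows=[pola_block]),
        AnchoredMSA(ids=["c1"], rows=[rnr_block]),
    )
    assert msa.n_columns == 332
    assert msa.rows[0][:143] == pola_block  # PolA block first, by convention


@pytest.mark.parametrize(
    "rnr,pol,expected",
    [
        ("RNR-I-CyanoSP", "Tyr762", {5}),
        ("RNR-II-RTPR", "Phe762", {7}),
        ("RNR-I-Other", "Tyr762", {2, 3}),
        ("RNR-II-Other", "Tyr762", {1, 8}),
        ("RNR-I-Other", "Leu762", set()),
    ],
)
def test_assign_clade_mapping(rnr, pol, expected):
    assignment = assign_clade(rnr, pol)
    assert set(assignment.candidates) == expected
    if len(expected) == 1:
        assert assignment.clade == next(iter(expected))
    else:
        assert assignment.clade is None


def test_assign_clade_rejects_unknown_labels():
    with pytest.raises(ValueError):
        assign_clade("RNR-IV", "Tyr762")
    with pytest.raises(ValueError):
        assign_clade("RNR-I-Other", "Trp762")


def test_tree_resolution_uses_nearest_labelled_neighbor():
    newick = "((a:0.1,b:0.1):0.5,(c:0.1,d:0.1):0.5,e:0.9);"
    tree = PhyloTree.from_newick(newick)
    assignments = [
        assign_clade("RNR-II-RTPR", "Tyr762", "a"),   # unique clade 6
        assign_clade("RNR-II-RTPR", "Phe762", "c"),   # unique clade 7
        assign_clade("RNR-I-Other", "Tyr762", "b"),   # {2,3}: no labelled candidate
    ]
    resolved = {x.contig_id: x for x in resolve_clades_by_tree(assignments, tree)}
    assert resolved["a"].clade == 6
    assert resolved["b"].clade is None          # stays a candidate set
    assert resolved["b"].candidates == frozenset({2, 3})
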