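"""Distance trees over anchored marker regions and clade assignment.

Marker peptides are stacked into a reference-anchored alignment (one
column per reference window position; query insertions relative to the
reference are discarded), pairwise p-distances are computed over shared
columns, and unrooted trees are built by neighbour joining with optional
bootstrap supports. Concatenating the C-terminal PolA block (reference
positions 784-926, 143 aa) with the RNR region (NrdA 437-625, 189 aa)
gives 332 columns per contig and resolves nine clades defined by the
combination of RNR class and PolA 762-type.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .reference_anchoring import CoordinateMap, ReferenceAnchor
from .seq_io import PeptideRecord

#: Fig-style clade mapping from (RNR class, PolA 762-type); several
#: combinations are topologically split into more than one clade and are
#: returned as a candidate set for tree-based resolution.
CLADE_MAP: dict[tuple[str, str], frozenset[int]] = {
    ("RNR-I-Other", "Tyr762"): frozenset({2, 3}),
    ("RNR-I-Other", "Phe762"): frozenset({4}),
    ("RNR-I-CyanoSP", "Tyr762"): frozenset({5}),
    ("RNR-II-RTPR", "Tyr762"): frozenset({6}),
    ("RNR-II-RTPR", "Phe762"): frozenset({7}),
    ("RNR-II-Other", "Tyr762"): frozenset({1, 8}),
    ("RNR-II-Other", "Phe762"): frozenset({1, 9}),
    ("RNR-II-Other", "Leu762"): frozenset({1}),
}

RNR_LABELS = {"RNR-I-Other", "RNR-I-CyanoSP", "RNR-II-Other", "RNR-II-RTPR"}
POL_LABELS = {"Phe762", "Tyr762", "Leu762", "Other", "Unresolved"}


@dataclass
class AnchoredMSA:
    """Fixed-width alignment: one column per reference window position."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class CladeAssignment:
    contig_id: str
    clade: int | None
    candidates: frozenset[int]
    rnr_class: str
    pol_type: str
    resolution: str  # "unique" | "tree" | "unresolved"


def stack_anchored_alignment(
    peptides: list[PeptideRecord],
    anchor: ReferenceAnchor,
    window_label: str,
    coord_maps: dict[str, CoordinateMap] | None = None,
) -> AnchoredMSA:
    """Stack query residues column-by-column onto a reference window.

    Column j holds each query's residue mapped to reference position
    window.start + j - 1, or a gap where that position is deleted or
    uncovered. Insertions relative to the reference are discarded, fixing
    column homology without a multiple-alignment step.
    """
    if not peptides:
        raise ValueError("cannot stack an empty peptide list")
    from .reference_anchoring import anchor_map

    start, end = anchor.named_windows[window_label]
    ids, rows = [], []
    for pep in peptides:
        cmap = coord_maps[pep.id] if coord_maps else anchor_map(pep.sequence, anchor)
        chars = []
        for ref_pos in range(start, end + 1):
            qpos = cmap.lookup(ref_pos)
            chars.append(pep.sequence[qpos - 1] if qpos is not None else "-")
        ids.append(pep.id)
        rows.append("".join(chars))
    return AnchoredMSA(ids=ids, rows=rows)


def p_distance(msa: AnchoredMSA):
    """Pairwise mismatch fraction over columns where both rows have residues."""
    from .clustering import DistanceMatrix

    if len(msa) < 2:
        raise ValueError("need at least two rows")
    gap = ord("-")
    enc = np.array([[ord(c) for c in row] for row in msa.rows], dtype=np.int16)
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != gap) & (enc[j] != gap)
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no columns"
                )
            mism = int((enc[i][both] != enc[j][both]).sum())
            d[i, j] = d[j, i] = mism / shared
    return DistanceMatrix(ids=list(msa.ids), d=d)


class PhyloTree:
    """An unrooted tree with branch lengths and optional edge supports.

    Thin wrapper over a dendropy tree; leaves carry input ids, supports
    sit on internal nodes as labels, and serialisation is standard Newick.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @property
    def leaf_ids(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".9f"
        ).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        tree.is_rooted = False
        return cls(tree)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each as the smaller-side leafset
        frozenset (complement-invariant representation)."""
        labels = self.leaf_ids
        out = set()
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is None or edge.head_node.is_leaf():
                continue
            if edge.tail_node is None:
                continue
            side = frozenset(
                leaf.taxon.label for leaf in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(labels) - 1:
                other = frozenset(labels - side)
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        pdm = self.tree.phylogenetic_distance_matrix()
        out = {}
        taxa = list(self.tree.taxon_namespace)
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                d = pdm.patristic_distance(t1, t2)
                out[(t1.label, t2.label)] = d
                out[(t2.label, t1.label)] = d
        return out


def neighbor_joining(D) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    The pair with the smallest Q criterion is joined at each step; ties go
    to the lexicographically smallest (id, id) pair. Negative branch
    lengths are clamped to zero. An additive distance matrix is recovered
    exactly (up to the clamp).
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    taxon_ns = dendropy.TaxonNamespace(sorted(D.ids))
    nodes: dict[str, dendropy.Node] = {}
    for name in D.ids:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(name)
        nodes[name] = node
    # active distance store keyed by frozenset pairs of working-node names
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((D.ids[i], D.ids[j]))] = float(D.d[i, j])
    active = sorted(D.ids)
    fresh = 0

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        parent_name = f"__nj{fresh}"
        fresh += 1
        parent = dendropy.Node()
        nodes[a].edge.length = max(la, 0.0)
        nodes[b].edge.length = max(lb, 0.0)
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[parent_name] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((parent_name, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted(set(active) - {a, b} | {parent_name})

    a, b, c = active
    root = dendropy.Node()
    nodes[a].edge.length = max(0.5 * (d(a, b) + d(a, c) - d(b, c)), 0.0)
    nodes[b].edge.length = max(0.5 * (d(a, b) + d(b, c) - d(a, c)), 0.0)
    nodes[c].edge.length = max(0.5 * (d(a, c) + d(b, c) - d(a, b)), 0.0)
    for name in (a, b, c):
        root.add_child(nodes[name])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(
    msa: AnchoredMSA,
    build_fn=None,
    n_reps: int = 10,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal edge is the fraction of replicate trees containing
    the same leaf bipartition, written as the internal node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if build_fn is None:
        build_fn = lambda m: neighbor_joining(p_distance(m))
    main = build_fn(msa)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    ncol = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = build_fn(AnchoredMSA(ids=list(msa.ids), rows=rows))
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    labels = main.leaf_ids
    for edge in main.tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.is_leaf() or edge.tail_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in head.leaf_iter())
        if not 1 < len(side) < len(labels) - 1:
            continue
        key = min(side, frozenset(labels - side), key=lambda s: (len(s), sorted(s)))
        head.label = f"{counts.get(key, 0) / n_reps:.3f}"
    return main


def concatenate_markers(
    pola_regions: dict[str, str],
    rnr_regions: dict[str, str],
) -> list[PeptideRecord]:
    """Concatenate per-contig PolA ("concat" window) and RNR region rows.

    Only contigs carrying both markers are included (others are excluded
    and reported by the caller's log); the PolA block always comes first.
    Both inputs must be fixed-width anchored rows (gaps allowed).
    """
    records = []
    for contig_id in sorted(set(pola_regions) & set(rnr_regions)):
        records.append(
            PeptideRecord(
                id=contig_id,
                sequence=(pola_regions[contig_id] + rnr_regions[contig_id]).replace("-", "X") or "X",
            )
        )
    return records


def concatenated_msa(
    pola_msa: AnchoredMSA, rnr_msa: AnchoredMSA
) -> AnchoredMSA:
    """Column-wise concatenation over the contigs present in both MSAs."""
    pola = dict(zip(pola_msa.ids, pola_msa.rows))
    rnr = dict(zip(rnr_msa.ids, rnr_msa.rows))
    shared = sorted(set(pola) & set(rnr))
    if not shared:
        raise ValueError("no contig carries both markers")
    return AnchoredMSA(ids=shared, rows=[pola[c] + rnr[c] for c in shared])


def assign_clade(rnr_class: str, pol_type: str, contig_id: str = "") -> CladeAssignment:
    """Candidate clades from the RNR-class x 762-type combination table."""
    if rnr_class not in RNR_LABELS:
        raise ValueError(f"unknown RNR class {rnr_class!r}")
    if pol_type not in POL_LABELS:
        raise ValueError(f"unknown PolA type {pol_type!r}")
    candidates = CLADE_MAP.get((rnr_class, pol_type), frozenset())
    clade = next(iter(candidates)) if len(candidates) == 1 else None
    return CladeAssignment(
        contig_id=contig_id,
        clade=clade,
        candidates=candidates,
        rnr_class=rnr_class,
        pol_type=pol_type,
        resolution="unique" if clade is not None else "unresolved",
    )


def resolve_clades_by_tree(
    assignments: list[CladeAssignment], tree: PhyloTree
) -> list[CladeAssignment]:
    """Resolve multi-candidate assignments by nearest labelled neighbour.

    Contigs with a unique clade seed the labels; each unresolved contig
    takes the clade of its closest (patristic distance) labelled leaf
    whose clade lies in the contig's candidate set. Contigs with no such
    neighbour stay unresolved and keep their candidate set.
    """
    distances = tree.leaf_distances()
    labelled = {a.contig_id: a.clade for a in assignments if a.clade is not None}
    out = []
    for a in assignments:
        if a.clade is not None or not a.candidates:
            out.append(a)
            continue
        best = None
        for other, clade in sorted(labelled.items()):
            if clade not in a.candidates:
                continue
            pair = (a.contig_id, other)
            if pair not in distances:
                continue
            key = (distances[pair], other)
            if best is None or key < best[0]:
                best = (key, clade)
        if best is None:
            out.append(a)
        else:
            out.append(
                CladeAssignment(
                    contig_id=a.contig_id,
                    clade=best[1],
                    candidates=a.candidates,
                    rnr_class=a.rnr_class,
                    pol_type=a.pol_type,
                    resolution="tree",
                )
            )
    return out


def clade_rows(assignments: list[CladeAssignment]) -> list[dict]:
    return [
        {
            "contig_id": a.contig_id,
            "rnr_class": a.rnr_class,
            "pol_type": a.pol_type,
            "clade": a.clade if a.clade is not None else "|".join(map(str, sorted(a.candidates))) or "unassigned",
            "resolution_method": a.resolution,
        }
        for a in sorted(assignments, key=lambda x: x.contig_id)
    ]
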