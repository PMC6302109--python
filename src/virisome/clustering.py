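"""Percent-identity and homology-graph clustering of marker peptides.

Two clustering modes are used: furthest-neighbour (complete-linkage)
clustering of reference-anchored PolA regions at 75% amino-acid identity
(AAI), which defines the marker "clusters" reported throughout; and
single-linkage connected-component clustering of a significant-hit graph
over all peptides of a contig set, which defines gene clusters for the
core-gene analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .marker_screen import e_value, local_score
from .seq_io import PeptideRecord


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # square symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


@dataclass
class ClusterSet:
    clusters: list[frozenset[str]]
    cutoff: float | None = None
    representatives: dict[frozenset[str], str] = field(default_factory=dict)

    @property
    def ids(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()

    def cluster_of(self, member: str) -> frozenset[str]:
        for c in self.clusters:
            if member in c:
                return c
        raise KeyError(member)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class SourceOverlap:
    shared: int
    a_only: int
    b_only: int

    @property
    def total(self) -> int:
        return self.shared + self.a_only + self.b_only

    @property
    def shared_fraction_of_a(self) -> float:
        """Shared clusters as a fraction of clusters containing source a."""
        a_containing = self.shared + self.a_only
        if a_containing == 0:
            raise ZeroDivisionError("no cluster contains source a")
        return self.shared / a_containing


def _pair_identity(row_a: np.ndarray, row_b: np.ndarray, gap_code: int) -> float:
    """Identity over reference-anchored columns for one pair.

    Columns outside the intersection of the two sequences' aligned spans
    (terminal gaps) are excluded; within the span, every column where at
    least one sequence has a residue counts, and an internal gap opposite
    a residue counts as a difference.
    """
    res_a = row_a != gap_code
    res_b = row_b != gap_code
    if not res_a.any() or not res_b.any():
        return np.nan
    lo = max(res_a.argmax(), res_b.argmax())
    hi = min(
        len(row_a) - 1 - res_a[::-1].argmax(),
        len(row_b) - 1 - res_b[::-1].argmax(),
    )
    if hi < lo:
        return np.nan
    a = row_a[lo : hi + 1]
    b = row_b[lo : hi + 1]
    considered = (a != gap_code) | (b != gap_code)
    n_cols = int(considered.sum())
    if n_cols == 0:
        return np.nan
    matches = int(((a == b) & (a != gap_code)).sum())
    return matches / n_cols


def identity_distance_matrix(msa_ids: list[str], msa_rows: list[str]) -> DistanceMatrix:
    """Pairwise AAI distances (1 - identity) over anchored alignment rows.

    Rows must come from the same reference window so columns are
    homologous. Rows with zero residues are rejected.
    """
    if len(msa_ids) < 2:
        raise ValueError("need at least two peptides")
    lengths = {len(r) for r in msa_rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    gap_code = ord("-")
    enc = np.array([[ord(c) for c in row] for row in msa_rows], dtype=np.int16)
    keep = [i for i in range(len(msa_ids)) if (enc[i] != gap_code).any()]
    dropped = [msa_ids[i] for i in range(len(msa_ids)) if i not in set(keep)]
    if dropped:
        import warnings

        warnings.warn(f"excluding zero-coverage rows: {dropped}")
    ids = [msa_ids[i] for i in keep]
    enc = enc[keep]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = _pair_identity(enc[i], enc[j], gap_code)
            if np.isnan(ident):
                ident = 0.0  # disjoint spans: treat as fully distinct
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(ids=ids, d=d)


def furthest_neighbor_clusters(D: DistanceMatrix, cutoff: float = 0.25) -> ClusterSet:
    """Complete-linkage agglomerative clustering cut at ``cutoff``.

    Clusters merge only while the merged cluster's maximum pairwise
    distance stays at or below the cutoff, so every output cluster's
    diameter is <= cutoff. A 75% AAI threshold corresponds to
    cutoff = 0.25.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be within [0, 1]")
    n = len(D.ids)
    if n == 1:
        return ClusterSet(clusters=[frozenset(D.ids)], cutoff=cutoff)
    condensed = squareform(D.d, checks=False)
    Z = linkage(condensed, method="complete")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    groups: dict[int, set[str]] = {}
    for name, lab in zip(D.ids, labels):
        groups.setdefault(int(lab), set()).add(name)
    clusters = sorted((frozenset(g) for g in groups.values()), key=lambda c: sorted(c))
    return ClusterSet(clusters=clusters, cutoff=cutoff)


def choose_representative(
    cluster: frozenset[str], peptides: dict[str, PeptideRecord]
) -> str:
    """Longest member; ties broken by lexicographically smallest id."""
    if not cluster:
        raise ValueError("empty cluster")
    return min(cluster, key=lambda pid: (-len(peptides[pid].sequence), pid))


def assign_representatives(
    clusterset: ClusterSet, peptides: dict[str, PeptideRecord]
) -> None:
    for cluster in clusterset.clusters:
        clusterset.representatives[cluster] = choose_representative(cluster, peptides)


def source_overlap(
    clusterset: ClusterSet,
    source_of: dict[str, str],
    source_a: str,
    source_b: str,
) -> SourceOverlap:
    """Count clusters containing only source a, only source b, or both."""
    shared = a_only = b_only = 0
    for cluster in clusterset.clusters:
        sources = set()
        for member in cluster:
            if member not in source_of:
                raise KeyError(f"no source recorded for member {member!r}")
            sources.add(source_of[member])
        has_a, has_b = source_a in sources, source_b in sources
        if has_a and has_b:
            shared += 1
        elif has_a:
            a_only += 1
        elif has_b:
            b_only += 1
    return SourceOverlap(shared=shared, a_only=a_only, b_only=b_only)


def homology_graph_clusters(
    peptides: list[PeptideRecord],
    e_cutoff: float = 1e-20,
    precomputed_edges: list[tuple[str, str]] | None = None,
) -> ClusterSet:
    """Single-linkage clusters of the significant-hit graph.

    Nodes are peptides; an undirected edge joins two peptides when their
    local alignment is significant at ``e_cutoff`` in either direction
    (the E-value is computed both ways because it depends on which peptide
    plays the query). Clusters are the connected components, matching a
    nearest-neighbour hit-merging script.
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    graph = nx.Graph()
    graph.add_nodes_from(p.id for p in peptides)
    if precomputed_edges is not None:
        graph.add_edges_from(precomputed_edges)
    else:
        for i in range(len(peptides)):
            for j in range(i + 1, len(peptides)):
                a, b = peptides[i], peptides[j]
                score = local_score(a.sequence, b.sequence)
                ev = min(
                    e_value(score, len(a.sequence), len(b.sequence)),
                    e_value(score, len(b.sequence), len(a.sequence)),
                )
                if ev <= e_cutoff:
                    graph.add_edge(a.id, b.id)
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c),
    )
    return ClusterSet(clusters=clusters, cutoff=None)


def core_clusters(
    clusterset: ClusterSet,
    contig_of: dict[str, str],
    clade_of: dict[str, int | str],
    fraction: float = 0.5,
) -> dict[int | str, list[frozenset[str]]]:
    """Per-clade clusters present on at least ``fraction`` of clade contigs.

    A cluster is core for a clade when its members cover at least
    ceil(fraction * n_contigs) of the clade's contigs. Contigs without a
    clade assignment are ignored.
    """
    contigs_by_clade: dict[int | str, set[str]] = {}
    for contig, clade in clade_of.items():
        contigs_by_clade.setdefault(clade, set()).add(contig)
    result: dict[int | str, list[frozenset[str]]] = {}
    for clade, contigs in sorted(contigs_by_clade.items(), key=lambda kv: str(kv[0])):
        if not contigs:
            import warnings

            warnings.warn(f"clade {clade!r} has no contigs; skipped")
            continue
        need = ceil(fraction * len(contigs))
        core = []
        for cluster in clusterset.clusters:
            present_on = {
                contig_of[m] for m in cluster if contig_of.get(m) in contigs
            }
            if len(present_on) >= need:
                core.append(cluster)
        result[clade] = core
    return result


def cluster_rows(clusterset: ClusterSet, source_of: dict[str, str] | None = None) -> list[dict]:
    rows = []
    for idx, cluster in enumerate(clusterset.clusters, start=1):
        rep = clusterset.representatives.get(cluster)
        for member in sorted(cluster):
            rows.append(
                {
                    "cluster_id": idx,
                    "member_id": member,
                    "is_representative": int(member == rep),
                    "source": source_of.get(member, "") if source_of else "",
                }
            )
    return rows
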