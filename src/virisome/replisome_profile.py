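"""Per-contig replisome profiles, gene prevalence, and read-mass estimates.

A contig carrying a verified PolA is summarised by the replication-gene
families found on it: helicases (ring-shaped Gp4-like/DnaB-like versus
non-ring UvrD/RecB/SNF2/RecA families), at most one ribonucleotide
reductase (RNR) class, and accessory replication genes (DnaG primase,
MazG). The primary statistic is contig-level presence -- the percentage of
a group's contigs containing each gene -- with a separate adjacency
statistic (within a rank window of the PolA gene) reported as advisory
only. Abundance of each PolA-plus-gene arrangement is estimated from the
share of reads recruited to contigs carrying that arrangement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .marker_screen import ACCESSORY_FAMILIES, HELICASE_FAMILIES, RNR_FAMILIES
from .reference_anchoring import PolAClassification
from .seq_io import ContigRecord, reverse_complement

#: advisory adjacency window (gene ranks either side of the PolA gene)
ADJACENCY_WINDOW = 5


@dataclass
class ReplisomeProfile:
    contig_id: str
    pola: PolAClassification
    helicases: frozenset[str] = frozenset()
    rnr_class: str | None = None
    accessory: frozenset[str] = frozenset()
    gene_order: list[tuple[int, str]] = field(default_factory=list)
    group: str = "Unassigned"  # set by the field guide / clade context

    @property
    def combination(self) -> tuple[str, ...]:
        """Canonical sorted arrangement key over helicases plus the RNR
        class, accessory genes excluded. Used to aggregate read-mass
        estimates."""
        parts = set(self.helicases)
        if self.rnr_class:
            parts.add(self.rnr_class)
        return tuple(sorted(parts))

    def genes_present(self) -> frozenset[str]:
        extra = {self.rnr_class} if self.rnr_class else set()
        return frozenset(self.helicases | self.accessory | extra)


@dataclass(frozen=True)
class PrevalenceRow:
    group: str
    gene_or_combination: str
    percent: float
    contig_count: int
    group_size: int


@dataclass
class AbundanceEstimate:
    rows: list[tuple[str, float]]  # (combination label, fraction of reads)
    total_reads: int

    def fraction(self, label: str) -> float:
        for lab, frac in self.rows:
            if lab == label:
                return frac
        return 0.0


def profile_contig(
    contig_id: str,
    family_by_rank: dict[int, str],
    pola_rank: int,
    pola_classification: PolAClassification,
    rnr_scores: dict[int, float] | None = None,
) -> ReplisomeProfile:
    """Summarise the labelled replication genes on one PolA contig.

    ``family_by_rank`` maps gene rank -> assigned family label (ambiguous
    and unlabelled genes omitted). If several genes carry RNR labels, the
    class of the best-scoring one (via ``rnr_scores``, rank -> score) is
    kept; without scores the lowest-rank RNR wins.
    """
    if pola_classification is None:
        raise ValueError(f"contig {contig_id!r} has no verified PolA; screen first")
    helicases = set()
    accessory = set()
    rnr_candidates: list[tuple[int, str]] = []
    gene_order = []
    for rank in sorted(family_by_rank):
        family = family_by_rank[rank]
        gene_order.append((rank, family))
        if family in HELICASE_FAMILIES:
            helicases.add(family)
        elif family in RNR_FAMILIES:
            rnr_candidates.append((rank, family))
        elif family in ACCESSORY_FAMILIES:
            accessory.add(family)
    rnr_class = None
    if rnr_candidates:
        if rnr_scores:
            rank, rnr_class = max(
                rnr_candidates, key=lambda rc: (rnr_scores.get(rc[0], 0.0), -rc[0])
            )
        else:
            rnr_class = rnr_candidates[0][1]
    return ReplisomeProfile(
        contig_id=contig_id,
        pola=pola_classification,
        helicases=frozenset(helicases),
        rnr_class=rnr_class,
        accessory=frozenset(accessory),
        gene_order=gene_order,
    )


def _group_key(profile: ReplisomeProfile, by: str) -> str:
    return profile.group if by == "group" else profile.pola.pol_type


def group_gene_prevalence(
    profiles: list[ReplisomeProfile],
    by: str = "pol_type",
    pairs: list[tuple[str, str]] | None = None,
) -> list[PrevalenceRow]:
    """Percentage of each group's contigs containing each gene.

    ``pairs`` adds co-occurrence rows ("geneA+geneB") giving the
    percentage of contigs containing both. RNR pair members may be the
    generic label "RNR" (any class).
    """
    groups: dict[str, list[ReplisomeProfile]] = {}
    for p in profiles:
        groups.setdefault(_group_key(p, by), []).append(p)
    rows: list[PrevalenceRow] = []

    def has(profile: ReplisomeProfile, gene: str) -> bool:
        if gene == "RNR":
            return profile.rnr_class is not None
        return gene in profile.genes_present()

    for group in sorted(groups):
        members = groups[group]
        if not members:
            continue
        genes = sorted({g for p in members for g in p.genes_present()})
        if any(p.rnr_class for p in members):
            genes.append("RNR")
        for gene in genes:
            count = sum(1 for p in members if has(p, gene))
            rows.append(
                PrevalenceRow(
                    group=group,
                    gene_or_combination=gene,
                    percent=100.0 * count / len(members),
                    contig_count=count,
                    group_size=len(members),
                )
            )
        for a, b in pairs or []:
            count = sum(1 for p in members if has(p, a) and has(p, b))
            rows.append(
                PrevalenceRow(
                    group=group,
                    gene_or_combination=f"{a}+{b}",
                    percent=100.0 * count / len(members),
                    contig_count=count,
                    group_size=len(members),
                )
            )
    return rows


def adjacency_prevalence(
    profiles: list[ReplisomeProfile],
    pola_rank_of: dict[str, int],
    by: str = "pol_type",
    window: int = ADJACENCY_WINDOW,
) -> list[PrevalenceRow]:
    """Advisory statistic: gene presence within ``window`` ranks of PolA."""
    groups: dict[str, list[ReplisomeProfile]] = {}
    for p in profiles:
        groups.setdefault(_group_key(p, by), []).append(p)
    rows = []
    for group in sorted(groups):
        members = groups[group]
        near: Counter[str] = Counter()
        for p in members:
            pola_rank = pola_rank_of[p.contig_id]
            families = {
                fam
                for rank, fam in p.gene_order
                if rank != pola_rank and abs(rank - pola_rank) <= window
            }
            near.update(families)
        for gene in sorted(near):
            rows.append(
                PrevalenceRow(
                    group=group,
                    gene_or_combination=gene,
                    percent=100.0 * near[gene] / len(members),
                    contig_count=near[gene],
                    group_size=len(members),
                )
            )
    return rows


def recruit_reads_exact(
    reads: list[ContigRecord], contigs: list[ContigRecord]
) -> dict[str, str | None]:
    """Assign each read to the unique contig containing it exactly.

    A read maps to a contig when the read or its reverse complement occurs
    as an exact substring. Reads matching more than one contig are left
    unassigned (None), mirroring the ambiguity handling of a best-hit
    mapper without depending on one. Deterministic and independent of
    input order.
    """
    lengths = sorted({len(r.sequence) for r in reads})
    wanted: dict[str, set[str]] = {}
    for read in reads:
        for seq in (read.sequence, reverse_complement(read.sequence)):
            wanted.setdefault(seq, set())
    for contig in contigs:
        cseq = contig.sequence
        for L in lengths:
            for i in range(len(cseq) - L + 1):
                sub = cseq[i : i + L]
                hits = wanted.get(sub)
                if hits is not None:
                    hits.add(contig.id)
    assignment: dict[str, str | None] = {}
    for read in reads:
        contig_hits = wanted[read.sequence] | wanted[reverse_complement(read.sequence)]
        assignment[read.id] = next(iter(contig_hits)) if len(contig_hits) == 1 else None
    return assignment


def combination_label(group: str, combination: tuple[str, ...]) -> str:
    genes = "+".join(combination) if combination else "none"
    return f"{group}|{genes}"


def combination_abundance(
    profiles: list[ReplisomeProfile],
    assignment: dict[str, str | None],
    by: str = "group",
) -> AbundanceEstimate:
    """Share of recruited reads per (group x gene arrangement).

    The denominator is reads uniquely assigned to profiled PolA contigs;
    ambiguous and unassigned reads are dropped. Fractions over all
    arrangements sum to one.
    """
    profile_by_contig = {p.contig_id: p for p in profiles}
    counts: Counter[str] = Counter()
    total = 0
    for read_id in sorted(assignment):
        contig = assignment[read_id]
        if contig is None:
            continue
        if contig not in profile_by_contig:
            raise KeyError(f"read {read_id!r} assigned to unprofiled contig {contig!r}")
        p = profile_by_contig[contig]
        counts[combination_label(_group_key(p, by), p.combination)] += 1
        total += 1
    if total == 0:
        raise ValueError("zero reads assigned to profiled contigs")
    rows = sorted(
        ((label, n / total) for label, n in counts.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return AbundanceEstimate(rows=rows, total_reads=total)


def prevalence_rows(rows: list[PrevalenceRow]) -> list[dict]:
    return [
        {
            "group": r.group,
            "gene_or_combination": r.gene_or_combination,
            "percent": f"{r.percent:.1f}",
            "contig_count": r.contig_count,
            "group_size": r.group_size,
        }
        for r in rows
    ]


def abundance_rows(est: AbundanceEstimate) -> list[dict]:
    return [
        {"combination": label, "read_fraction": f"{frac:.4f}", "total_reads": est.total_reads}
        for label, frac in est.rows
    ]
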