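"""PolA candidate screening and replication-gene family assignment.

Candidate marker genes are found by Smith-Waterman local alignment against
a small panel of family exemplars (one to a few peptides per replication
gene family), with significance judged by a Karlin-Altschul E-value
E = K * m * n * exp(-lambda * S). The decision rule mirrors a BLASTp
screen (E <= 1e-5, length >= 200 aa for PolA; best family below cutoff for
annotation) but E-values are computed against the panel, not a large
database, so only the rule's structure -- not absolute E-values -- carries
over. A confirmation requirement of >= 30% coverage of the panel exemplar
takes the place of a domain-database check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import PeptideRecord

#: closed vocabulary of replication-gene families used throughout
FAMILY_LABELS = (
    "PolA",
    "Gp4-like",
    "DnaB-like",
    "UvrD-like",
    "RecB-like",
    "SNF2-like",
    "RecA-like",
    "RNR-I-Other",
    "RNR-I-CyanoSP",
    "RNR-II-Other",
    "RNR-II-RTPR",
    "DnaG",
    "MazG",
)

HELICASE_FAMILIES = frozenset(
    {"Gp4-like", "DnaB-like", "UvrD-like", "RecB-like", "SNF2-like", "RecA-like"}
)
RNR_FAMILIES = frozenset(
    {"RNR-I-Other", "RNR-I-CyanoSP", "RNR-II-Other", "RNR-II-RTPR"}
)
ACCESSORY_FAMILIES = frozenset({"DnaG", "MazG"})

# Karlin-Altschul parameters for gapped BLOSUM62 (gap 11/1); pinned so the
# E-value scale is reproducible across runs.
KA_LAMBDA = 0.267
KA_K = 0.041

#: two top families scoring within this relative margin -> "ambiguous"
AMBIGUITY_MARGIN = 0.05

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ScreenHit:
    peptide_id: str
    family_label: str
    score: float
    e_value_estimate: float
    coverage: float  # fraction of the panel exemplar spanned by the local hit


class MarkerPanel:
    """Family-labelled exemplar peptides used as alignment targets."""

    def __init__(self, entries: list[tuple[str, PeptideRecord]]):
        for label, _ in entries:
            if label not in FAMILY_LABELS:
                raise ValueError(f"unknown family label {label!r}")
        self.entries = list(entries)

    def by_family(self, family: str) -> list[PeptideRecord]:
        return [p for label, p in self.entries if label == family]

    @property
    def families(self) -> list[str]:
        seen = []
        for label, _ in self.entries:
            if label not in seen:
                seen.append(label)
        return seen

    @classmethod
    def from_fasta(cls, records: list[PeptideRecord]) -> "MarkerPanel":
        """Panel from FASTA records whose ids end in '|<family_label>'."""
        entries = []
        for rec in records:
            if "|" not in rec.id:
                raise ValueError(f"panel record {rec.id!r} lacks a '|family' suffix")
            label = rec.id.rsplit("|", 1)[1]
            entries.append((label, rec))
        return cls(entries)


_local_aligner: list[Align.PairwiseAligner] = []


def _aligner() -> Align.PairwiseAligner:
    if not _local_aligner:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.mode = "local"
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        _local_aligner.append(a)
    return _local_aligner[0]


def e_value(score: float, query_len: int, target_len: int) -> float:
    """Karlin-Altschul expect value for a raw local-alignment score."""
    return KA_K * query_len * target_len * math.exp(-KA_LAMBDA * score)


def local_score(query: str, target: str) -> float:
    return float(_aligner().score(target, query))


def _best_hit_vs_family(
    peptide: PeptideRecord, exemplars: list[PeptideRecord]
) -> tuple[float, PeptideRecord]:
    best_score, best_ex = -math.inf, None
    for ex in exemplars:
        s = local_score(peptide.sequence, ex.sequence)
        if s > best_score:
            best_score, best_ex = s, ex
    return best_score, best_ex


def _coverage(peptide: PeptideRecord, exemplar: PeptideRecord) -> float:
    aln = _aligner().align(exemplar.sequence, peptide.sequence)[0]
    target_blocks = aln.aligned[0]
    spanned = int(target_blocks[-1][1] - target_blocks[0][0]) if len(target_blocks) else 0
    return spanned / len(exemplar.sequence)


def screen_hit(
    peptide: PeptideRecord, panel: MarkerPanel, family: str
) -> ScreenHit | None:
    exemplars = panel.by_family(family)
    if not exemplars:
        raise ValueError(f"panel has no {family} entry")
    score, exemplar = _best_hit_vs_family(peptide, exemplars)
    ev = e_value(score, len(peptide.sequence), len(exemplar.sequence))
    cov = _coverage(peptide, exemplar)
    return ScreenHit(
        peptide_id=peptide.id,
        family_label=family,
        score=score,
        e_value_estimate=ev,
        coverage=cov,
    )


def screen_pola(
    peptides: list[PeptideRecord],
    panel: MarkerPanel,
    e_cutoff: float = 1e-5,
    min_len: int = 200,
) -> list[PeptideRecord]:
    """Keep peptides with a significant PolA hit and length >= ``min_len``.

    Tightening either cutoff can only shrink the output (filter
    monotonicity); with min_len = 0 and an infinite cutoff every peptide
    with any positive-scoring PolA alignment is returned.
    """
    if not panel.by_family("PolA"):
        raise ValueError("panel contains no PolA entry")
    exemplars = panel.by_family("PolA")
    kept = []
    for pep in peptides:
        if len(pep.sequence) < min_len:
            continue
        score, exemplar = _best_hit_vs_family(pep, exemplars)
        if e_value(score, len(pep.sequence), len(exemplar.sequence)) <= e_cutoff:
            kept.append(pep)
    return kept


def assign_family(
    peptide: PeptideRecord,
    panel: MarkerPanel,
    e_cutoff: float = 1e-5,
    min_coverage: float = 0.30,
) -> str | None:
    """Best-scoring family at or below the E cutoff, or None.

    If the two best families score within 5% of each other the call is
    "ambiguous" and excluded from prevalence statistics downstream.
    """
    scored: list[tuple[float, str, PeptideRecord]] = []
    for family in panel.families:
        score, exemplar = _best_hit_vs_family(peptide, panel.by_family(family))
        scored.append((score, family, exemplar))
    scored.sort(key=lambda t: (-t[0], t[1]))
    best_score, best_family, best_ex = scored[0]
    ev = e_value(best_score, len(peptide.sequence), len(best_ex.sequence))
    if ev > e_cutoff:
        return None
    if _coverage(peptide, best_ex) < min_coverage:
        return None
    if len(scored) > 1 and best_score > 0:
        runner_score = scored[1][0]
        if (best_score - runner_score) / best_score < AMBIGUITY_MARGIN:
            return AMBIGUOUS
    return best_family


def hit_rows(hits: list[ScreenHit]) -> list[dict]:
    return [
        {
            "peptide_id": h.peptide_id,
            "family": h.family_label,
            "score": f"{h.score:.1f}",
            "e_value": f"{h.e_value_estimate:.3e}",
            "coverage": f"{h.coverage:.3f}",
        }
        for h in hits
    ]


# ---------------------------------------------------------------------------
# Summary arithmetic for marker-count tables
# ---------------------------------------------------------------------------

def count_by_type(classifications) -> dict[str, int]:
    """Counts of resolved 762 types (Phe762/Tyr762/Leu762) plus a total."""
    counts = {"Phe762": 0, "Tyr762": 0, "Leu762": 0}
    for c in classifications:
        if c.pol_type in counts:
            counts[c.pol_type] += 1
    counts["Total"] = sum(counts.values())
    return counts


def per_million(marker_count: int, peptides_millions: float) -> int:
    """Markers per million predicted peptides, rounded to the nearest integer
    (half away from zero), as printed in library-normalised count tables."""
    if peptides_millions <= 0:
        raise ValueError("peptides_millions must be positive")
    value = marker_count / peptides_millions
    return int(math.floor(value + 0.5))
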