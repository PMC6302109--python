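"""Reference-anchored coordinate mapping and PolA 762-typing.

Virioplankton PolA peptides are numbered by alignment to the *E. coli*
IAI39 PolA protein, so that "position 762" means the query residue aligned
to reference position 762 rather than the 762nd residue of the query. The
same machinery anchors ribonucleotide-reductase (RNR) peptides to an NrdA
reference. Anchoring uses pairwise global alignment with free end gaps
(BLOSUM62, affine gaps), which fixes the query-to-reference column
correspondence without a multiple-alignment heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import PeptideRecord, read_fasta, read_table

DELETED = "deleted"

#: alignment parameters pinned for reproducibility: BLOSUM62, affine gap
#: with a length-L gap costing GAP_OPEN + (L-1) * GAP_EXTEND, end gaps free
#: on both sequences so partial peptides and flanking sequence are not
#: penalised.
GAP_OPEN = -12.0
GAP_EXTEND = -1.0

POL_TYPE_BY_RESIDUE = {"F": "Phe762", "Y": "Tyr762", "L": "Leu762"}

GROUPS = ("Tyr762", "Phe762-I", "Phe762-II", "Leu762-I", "Leu762-II", "Unassigned")


@dataclass(frozen=True)
class ReferenceAnchor:
    """A reference peptide with named positions and analysis windows.

    The bundled PolA anchor carries the 762 site ("pos762") and three
    windows: "partial" (675-799, the 125-aa region used for the global
    diversity tree), "full_domain" (547-926) and "concat" (784-926, the
    block concatenated with RNR). The NrdA anchor carries "rnr_region"
    (437-625, 189 aa).
    """

    name: str
    peptide: str
    named_positions: dict[str, int] = field(default_factory=dict)
    named_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.peptide)
        for label, pos in self.named_positions.items():
            if not 1 <= pos <= n:
                raise ValueError(f"position {label}={pos} outside anchor (1..{n})")
        for label, (start, end) in self.named_windows.items():
            if not (1 <= start <= end <= n):
                raise ValueError(f"window {label}=({start},{end}) outside anchor")

    def window_length(self, label: str) -> int:
        start, end = self.named_windows[label]
        return end - start + 1


@dataclass(frozen=True)
class PairwiseAlignment:
    query_aligned: str
    ref_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.query_aligned) != len(self.ref_aligned):
            raise ValueError("aligned strings must have equal length")

    @property
    def query(self) -> str:
        return self.query_aligned.replace("-", "")

    @property
    def ref(self) -> str:
        return self.ref_aligned.replace("-", "")


@dataclass(frozen=True)
class CoordinateMap:
    """Reference position -> query position (1-based) or "deleted".

    ``query_span`` is the (first, last) reference position aligned to a
    query residue; reference positions outside it are unaligned overhang,
    distinct from internal deletions.
    """

    ref_to_query: dict[int, int | str]
    query_span: tuple[int, int]

    def lookup(self, ref_pos: int) -> int | None:
        """Query position for a reference position, or None if deleted or
        outside the aligned span."""
        first, last = self.query_span
        if not first <= ref_pos <= last:
            return None
        hit = self.ref_to_query.get(ref_pos, DELETED)
        return None if hit == DELETED else hit


@dataclass(frozen=True)
class PolAClassification:
    peptide_id: str
    residue762: str
    pol_type: str
    group: str = "Unassigned"
    coverage: float = 0.0


_aligner_cache: dict[int, Align.PairwiseAligner] = {}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_internal_gap_score = GAP_OPEN
    aligner.extend_internal_gap_score = GAP_EXTEND
    aligner.end_gap_score = 0.0
    return aligner


def global_align(query: str, anchor_peptide: str) -> PairwiseAlignment:
    """Optimal global alignment with free end gaps on both sequences.

    Ties between equally scoring tracebacks are broken by the aligner's
    fixed enumeration order, so output is deterministic for a given input.
    """
    if not query or not anchor_peptide:
        raise ValueError("cannot align an empty sequence")
    key = 0
    if key not in _aligner_cache:
        _aligner_cache[key] = _make_aligner()
    aligner = _aligner_cache[key]
    alignment = aligner.align(anchor_peptide, query)[0]
    return PairwiseAlignment(
        query_aligned=str(alignment[1]),
        ref_aligned=str(alignment[0]),
        score=float(alignment.score),
    )


def build_coordinate_map(alignment: PairwiseAlignment) -> CoordinateMap:
    """Map each reference position to its aligned query position."""
    ref_to_query: dict[int, int | str] = {}
    ref_pos = 0
    query_pos = 0
    first = last = None
    for r, q in zip(alignment.ref_aligned, alignment.query_aligned):
        if r != "-":
            ref_pos += 1
        if q != "-":
            query_pos += 1
        if r != "-":
            if q != "-":
                ref_to_query[ref_pos] = query_pos
                if first is None:
                    first = ref_pos
                last = ref_pos
            else:
                ref_to_query[ref_pos] = DELETED
    if first is None:
        raise ValueError("alignment has no aligned residue pair")
    return CoordinateMap(ref_to_query=ref_to_query, query_span=(first, last))


def anchor_map(query: str, anchor: ReferenceAnchor) -> CoordinateMap:
    """Convenience: align ``query`` to the anchor and build the map."""
    return build_coordinate_map(global_align(query, anchor.peptide))


def classify_762(
    peptide: PeptideRecord,
    anchor: ReferenceAnchor,
    coord_map: CoordinateMap | None = None,
) -> PolAClassification:
    """Report the query residue anchored at reference position 762.

    The wild type is phenylalanine (Phe762); tyrosine and leucine
    substitutions define the Tyr762 and Leu762 types. A peptide whose
    alignment does not cover position 762 (deletion or truncation) is
    Unresolved. Group assignment (e.g. Phe762-I vs -II) needs replisome or
    tree context and is left Unassigned here.
    """
    if "pos762" not in anchor.named_positions:
        raise ValueError(f"anchor {anchor.name!r} lacks named position 'pos762'")
    if coord_map is None:
        coord_map = anchor_map(peptide.sequence, anchor)
    pos = anchor.named_positions["pos762"]
    qpos = coord_map.lookup(pos)
    first, last = coord_map.query_span
    coverage = (last - first + 1) / len(anchor.peptide)
    if qpos is None:
        return PolAClassification(
            peptide_id=peptide.id,
            residue762="unresolved",
            pol_type="Unresolved",
            coverage=coverage,
        )
    residue = peptide.sequence[qpos - 1]
    pol_type = POL_TYPE_BY_RESIDUE.get(residue, "Other")
    return PolAClassification(
        peptide_id=peptide.id, residue762=residue, pol_type=pol_type, coverage=coverage
    )


def extract_window(
    peptide: PeptideRecord,
    anchor: ReferenceAnchor,
    window_label: str,
    coord_map: CoordinateMap | None = None,
) -> tuple[str, float]:
    """Query residues mapped to a named reference window, in window order.

    Deleted positions are omitted, so the returned region is at most the
    window length; the coverage flag is the fraction of window positions
    mapped to a query residue. Callers filter on coverage (the pipeline
    default keeps regions covering >= 80% of the window).
    """
    if window_label not in anchor.named_windows:
        raise ValueError(f"anchor {anchor.name!r} has no window {window_label!r}")
    if coord_map is None:
        coord_map = anchor_map(peptide.sequence, anchor)
    start, end = anchor.named_windows[window_label]
    residues = []
    for ref_pos in range(start, end + 1):
        qpos = coord_map.lookup(ref_pos)
        if qpos is not None:
            residues.append(peptide.sequence[qpos - 1])
    coverage = len(residues) / (end - start + 1)
    return "".join(residues), coverage


def load_anchor_panel(
    fasta_path: str | Path, sidecar_path: str | Path
) -> dict[str, ReferenceAnchor]:
    """Load anchors from FASTA plus a sidecar TSV of named positions/windows.

    Sidecar columns: anchor_name, label, start, end. A row with start == end
    and a label beginning "pos" defines a named position; otherwise a window.
    """
    peptides = {rec.id: rec.sequence for rec in read_fasta(fasta_path, "amino-acid")}
    positions: dict[str, dict[str, int]] = {name: {} for name in peptides}
    windows: dict[str, dict[str, tuple[int, int]]] = {name: {} for name in peptides}
    for row in read_table(sidecar_path):
        name = row["anchor_name"]
        if name not in peptides:
            raise ValueError(f"sidecar names unknown anchor {name!r}")
        start, end = int(row["start"]), int(row["end"])
        if row["label"].startswith("pos") and start == end:
            positions[name][row["label"]] = start
        else:
            windows[name][row["label"]] = (start, end)
    return {
        name: ReferenceAnchor(
            name=name,
            peptide=seq,
            named_positions=positions[name],
            named_windows=windows[name],
        )
        for name, seq in peptides.items()
    }


def classification_rows(classifications) -> list[dict]:
    return [
        {
            "peptide_id": c.peptide_id,
            "residue762": c.residue762,
            "pol_type": c.pol_type,
            "coverage": f"{c.coverage:.4f}",
        }
        for c in classifications
    ]
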