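"""Sequence and table I/O plus a six-frame ORF finder.

All coordinates in this package are 1-based and inclusive, matching the
residue-numbering convention used for reference-anchored positions such as
the PolA 762 site. FASTA parsing and writing go through Biopython; this
module adds the strict validation the pipeline relies on (unique ids,
restricted alphabets, uppercase normalisation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = set("ACGTN")
AMINO_ACID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: complement table for reverse_complement
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide contig with a free-form source tag (library name)."""

    id: str
    sequence: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class PeptideRecord:
    """An amino-acid sequence, optionally tied to a (contig, gene rank)."""

    id: str
    sequence: str
    parent: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r} has an empty sequence")
        if "*" in self.sequence:
            raise ValueError(f"peptide {self.id!r} contains an internal stop")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCall:
    """A called gene on a contig.

    ``start``/``end`` are 1-based inclusive forward-strand positions with
    start <= end regardless of strand. ``rank`` orders genes left to right
    along the forward strand (1-based), again regardless of strand, so that
    adjacency statistics have a single frame of reference.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    peptide: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(
                f"invalid span {self.start}..{self.end} on {self.contig_id}"
            )
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("gene span length must be divisible by 3")

    @property
    def peptide_id(self) -> str:
        return f"{self.contig_id}_{self.rank}"


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(codons: str) -> str:
    """Translate a nucleotide string with the standard genetic code."""
    return str(Seq(codons).translate(table=1))


def _validate(seq_id: str, sequence: str, alphabet: str) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else AMINO_ACID_ALPHABET
    for pos, ch in enumerate(sequence, start=1):
        if ch not in allowed:
            raise ValueError(
                f"record {seq_id!r}: character {ch!r} at position {pos} "
                f"not in {alphabet} alphabet"
            )


def read_fasta(path: str | Path, alphabet: str = "amino-acid") -> list:
    """Read a FASTA file into contig or peptide records.

    Headers are split at the first whitespace to obtain the id; sequences
    are uppercased. Duplicate ids, empty sequences and characters outside
    the declared alphabet (other than the ambiguity codes N/X) are errors.
    """
    if alphabet not in {"nucleotide", "amino-acid"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        _validate(rec.id, seq, alphabet)
        if alphabet == "nucleotide":
            records.append(ContigRecord(id=rec.id, sequence=seq))
        else:
            records.append(PeptideRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with .id and .sequence) wrapped at ``width``."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a tab-separated table with a header row into dict rows."""
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def write_table(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write dict rows as a tab-separated table with a header row."""
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from an empty table")
        columns = list(rows[0])
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def _forward_orfs(sequence: str, frame: int, min_len_aa: int):
    """Maximal ATG..stop ORFs in one forward frame (0/1/2).

    For each stop codon the leftmost in-frame ATG after the previous stop
    is taken, so nested ORFs sharing a stop are not re-reported.
    """
    n = len(sequence)
    orfs = []
    start_candidate = None
    pos = frame
    while pos + 3 <= n:
        codon = sequence[pos : pos + 3]
        if codon in STOP_CODONS:
            if start_candidate is not None:
                aa_len = (pos - start_candidate) // 3
                if aa_len >= min_len_aa:
                    orfs.append((start_candidate, pos + 3))
                start_candidate = None
        elif codon == "ATG" and start_candidate is None:
            start_candidate = pos
        pos += 3
    return orfs


def find_orfs(contig: ContigRecord, min_len_aa: int = 1) -> list[GeneCall]:
    """Scan all six frames for ATG-initiated, stop-terminated ORFs.

    The reported peptide includes the initiator methionine and excludes the
    stop. Only maximal ORFs (leftmost ATG per stop, per frame) are emitted;
    ORFs overlapping across frames or strands are all reported. Ranks are
    assigned by leftmost forward-strand coordinate, ties by start position
    then strand.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = contig.sequence
    rc = reverse_complement(seq)
    n = len(seq)
    raw: list[tuple[int, int, str, str]] = []  # (start1, end1, strand, peptide)
    for frame in range(3):
        for s, e in _forward_orfs(seq, frame, min_len_aa):
            peptide = translate(seq[s : e - 3])
            raw.append((s + 1, e, "+", peptide))
        for s, e in _forward_orfs(rc, frame, min_len_aa):
            # map reverse-complement coordinates back to the forward strand
            peptide = translate(rc[s : e - 3])
            raw.append((n - e + 1, n - s, "-", peptide))
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        GeneCall(
            contig_id=contig.id,
            start=s,
            end=e,
            strand=strand,
            peptide=pep,
            rank=i,
        )
        for i, (s, e, strand, pep) in enumerate(raw, start=1)
    ]


def gene_calls_to_rows(calls: Sequence[GeneCall]) -> list[dict]:
    """Deterministic TSV rows (1-based inclusive coordinates)."""
    ordered = sorted(calls, key=lambda c: (c.contig_id, c.rank))
    return [
        {
            "contig_id": c.contig_id,
            "rank": c.rank,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "peptide_id": c.peptide_id,
        }
        for c in ordered
    ]
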