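"""Synthetic virioplankton communities with a known truth table.

The generator emits contigs that each carry one PolA gene of a controlled
762-type plus replisome genes drawn from group-specific arrangement
probabilities, peptides at a controlled amino-acid divergence from group
templates, error-free reads whose mass follows a configured
arrangement-abundance vector, and a truth table recording every property
the pipeline is expected to recover. Templates derive from the bundled
synthetic anchor scaffolds, so no external sequence database is needed.

Reads are error-free by design, pairing with exact-substring recruitment;
an optional uniform substitution-error mode exists for robustness
experiments but is off by default.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .marker_screen import MarkerPanel, RNR_FAMILIES
from .reference_anchoring import ReferenceAnchor, load_anchor_panel
from .seq_io import (
    ContigRecord,
    GeneCall,
    PeptideRecord,
    reverse_complement,
    write_fasta,
    write_table,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: standard-code codon choices per amino acid (stop excluded)
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

GROUP_RESIDUE = {
    "Tyr762": "Y",
    "Phe762-I": "F",
    "Phe762-II": "F",
    "Leu762-I": "L",
    "Leu762-II": "L",
}

#: canonical truth clade for each (RNR class, 762 residue) combination
TRUTH_CLADE = {
    ("RNR-I-Other", "Y"): 2,
    ("RNR-I-Other", "F"): 4,
    ("RNR-I-CyanoSP", "Y"): 5,
    ("RNR-II-RTPR", "Y"): 6,
    ("RNR-II-RTPR", "F"): 7,
    ("RNR-II-Other", "Y"): 8,
    ("RNR-II-Other", "F"): 9,
    ("RNR-II-Other", "L"): 1,
}

POS_762 = 762

#: fixed seeds for the de novo group templates; these are "biology", not
#: part of the community draw, so they do not move with the user seed.
_TEMPLATE_SEED_BASE = 90210


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("virisome") / "data" / name)


def default_anchor_panel() -> dict[str, ReferenceAnchor]:
    return load_anchor_panel(
        _data_path("anchors_synthetic.fasta"),
        _data_path("anchor_windows_synthetic.tsv"),
    )


def default_marker_panel() -> MarkerPanel:
    from .seq_io import read_fasta

    return MarkerPanel.from_fasta(
        read_fasta(_data_path("marker_panel_synthetic.fasta"), "amino-acid")
    )


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mutate_peptide(
    template: str,
    target_identity: float,
    frozen_positions: frozenset[int] | set[int] = frozenset(),
    seed=0,
) -> str:
    """Substitute residues to reach ``target_identity`` (within 0.02).

    The number of substituted positions is round((1 - target) * length);
    positions are drawn uniformly without replacement among non-frozen
    positions and each substitution picks a different residue, so the
    realised identity equals 1 - k/length exactly. Frozen positions
    (1-based) are never touched.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = _as_rng(seed)
    length = len(template)
    k = round((1 - target_identity) * length)
    mutable = [i for i in range(length) if (i + 1) not in frozen_positions]
    if k > len(mutable):
        raise ValueError(
            f"cannot place {k} substitutions with {length - len(mutable)} frozen positions"
        )
    chosen = rng.choice(len(mutable), size=k, replace=False) if k else []
    residues = list(template)
    for idx in chosen:
        pos = mutable[int(idx)]
        options = [aa for aa in AA20 if aa != template[pos]]
        residues[pos] = options[int(rng.integers(0, len(options)))]
    return "".join(residues)


def reverse_translate(peptide: str, seed=0) -> str:
    """ATG-initiated, TAA-terminated ORF encoding ``peptide``.

    Codons are drawn uniformly among synonymous options; translating the
    ORF (minus stop) recovers the peptide exactly. The peptide must start
    with methionine so the ORF starts with ATG.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if peptide[0] != "M":
        raise ValueError("peptide must start with M for an ATG-initiated ORF")
    rng = _as_rng(seed)
    codons = []
    for aa in peptide:
        options = CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons) + "TAA"


def random_peptide(length: int, seed=0, start_with_met: bool = True) -> str:
    rng = _as_rng(seed)
    core = "".join(AA20[int(i)] for i in rng.integers(0, 20, size=length))
    return ("M" + core[1:]) if start_with_met else core


# ---------------------------------------------------------------------------
# Community specification
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Gene-content model for one PolA group.

    Either ``arrangements`` (an explicit categorical over helicase/RNR
    sets, allowing controlled co-occurrence) or ``genes`` (independent
    per-gene presence probabilities) describes the replisome draw. The
    placeholder "RNR" resolves to a concrete class via ``rnr_classes``,
    a conditional distribution over the four classes.
    """

    count: int
    arrangements: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    genes: dict[str, float] = field(default_factory=dict)
    rnr_classes: dict[str, float] = field(default_factory=dict)
    accessory: dict[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if self.count < 0:
            raise ValueError(f"group {name}: negative contig count")
        if self.arrangements:
            total = sum(p for _, p in self.arrangements)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {name}: arrangement probabilities sum to {total}")
        for gene, p in {**self.genes, **self.accessory}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"group {name}: probability for {gene} outside [0,1]")
        if self.rnr_classes:
            total = sum(self.rnr_classes.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {name}: rnr_classes sum to {total}")


@dataclass
class CommunitySpec:
    groups: dict[str, GroupSpec]
    seed: int
    within_group_identity: float = 0.90
    template_divergence: float = 0.35
    gene_identity: float = 0.90
    abundance: list[tuple[str, tuple[str, ...], float]] = field(default_factory=list)
    read_length: int = 150
    total_reads: int = 100_000
    read_error_rate: float = 0.0
    spacer_range: tuple[int, int] = (20, 100)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, group in self.groups.items():
            if name not in GROUP_RESIDUE:
                raise ValueError(f"unknown group {name!r}")
            group.validate(name)
        share = sum(s for _, _, s in self.abundance)
        if share > 1 + 1e-9:
            raise ValueError("abundance shares exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "CommunitySpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        groups = {}
        for name, g in raw["groups"].items():
            arrangements = [
                (tuple(a["genes"]), float(a["p"])) for a in g.get("arrangements", [])
            ]
            groups[name] = GroupSpec(
                count=int(g["count"]),
                arrangements=arrangements,
                genes={k: float(v) for k, v in g.get("genes", {}).items()},
                rnr_classes={k: float(v) for k, v in g.get("rnr_classes", {}).items()},
                accessory={k: float(v) for k, v in g.get("accessory", {}).items()},
            )
        abundance = [
            (a["group"], tuple(sorted(a["genes"])), float(a["share"]))
            for a in raw.get("abundance", [])
        ]
        spec = cls(
            groups=groups,
            seed=int(raw["seed"]) if seed is None else int(seed),
            within_group_identity=float(raw.get("within_group_identity", 0.90)),
            template_divergence=float(raw.get("template_divergence", 0.35)),
            gene_identity=float(raw.get("gene_identity", 0.90)),
            abundance=abundance,
            read_length=int(raw.get("read_length", 150)),
            total_reads=int(raw.get("total_reads", 100_000)),
            read_error_rate=float(raw.get("read_error_rate", 0.0)),
        )
        spec.validate()
        return spec


def load_bundled_spec(name: str = "serc_fig2", seed: int | None = None) -> CommunitySpec:
    """Load a spec shipped with the package (default: the arrangement and
    abundance percentages of the study community)."""
    return CommunitySpec.from_yaml(_data_path(f"{name}.yaml"), seed=seed)


@dataclass
class TruthRow:
    contig_id: str
    group: str
    residue762: str
    genes: tuple[str, ...]
    rnr_class: str | None
    accessory: tuple[str, ...]
    clade: int | None
    read_weight: float
    n_reads: int


@dataclass
class Community:
    contigs: list[ContigRecord]
    gene_calls: list[GeneCall]
    peptides: list[PeptideRecord]
    reads: list[ContigRecord]
    truth: list[TruthRow]
    spec: CommunitySpec

    def truth_rows(self) -> list[dict]:
        return [
            {
                "contig_id": t.contig_id,
                "group": t.group,
                "residue762": t.residue762,
                "genes": ";".join(t.genes) or "none",
                "rnr_class": t.rnr_class or "none",
                "accessory": ";".join(t.accessory) or "none",
                "clade": t.clade if t.clade is not None else "none",
                "read_weight": f"{t.read_weight:.6g}",
                "n_reads": t.n_reads,
            }
            for t in self.truth
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fasta")
        write_fasta(self.peptides, outdir / "peptides.fasta")
        write_fasta(self.reads, outdir / "reads.fasta")
        from .seq_io import gene_calls_to_rows

        write_table(gene_calls_to_rows(self.gene_calls), outdir / "gene_calls.tsv")
        write_table(self.truth_rows(), outdir / "truth.tsv")


def group_templates(
    anchor: ReferenceAnchor, template_divergence: float = 0.35
) -> dict[str, str]:
    """De novo PolA group templates around the anchor scaffold.

    Each template diverges from the anchor by ``template_divergence``
    (substitution-only, position 762 frozen) under a fixed per-group seed,
    then carries its group's 762 residue. Independent divergence makes the
    between-group identity roughly the square of the per-template
    identity, keeping groups well separated.
    """
    templates = {}
    for i, (group, residue) in enumerate(sorted(GROUP_RESIDUE.items())):
        t = mutate_peptide(
            anchor.peptide,
            1 - template_divergence,
            frozen_positions={1, POS_762},
            seed=np.random.default_rng(_TEMPLATE_SEED_BASE + i),
        )
        templates[group] = t[: POS_762 - 1] + residue + t[POS_762:]
    return templates


def _draw_genes(group: GroupSpec, rng: np.random.Generator) -> tuple[list[str], str | None]:
    """Draw helicase labels and an optional concrete RNR class."""
    labels: list[str] = []
    if group.arrangements:
        probs = np.array([p for _, p in group.arrangements])
        idx = int(rng.choice(len(group.arrangements), p=probs / probs.sum()))
        labels = list(group.arrangements[idx][0])
    else:
        for gene in sorted(group.genes):
            if rng.random() < group.genes[gene]:
                labels.append(gene)
    rnr_class = None
    if "RNR" in labels:
        labels.remove("RNR")
        classes = sorted(group.rnr_classes)
        probs = np.array([group.rnr_classes[c] for c in classes])
        rnr_class = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    return labels, rnr_class


def _random_spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    """Intergenic spacer that cannot extend a neighbouring ORF.

    Drawn over {A,C,T} (no G, hence no ATG start codon inside or across
    the junction) and terminated with TAA so the following gene's frame
    sees a stop immediately before its start codon; gene ORFs are then
    exactly maximal.
    """
    length = int(rng.integers(lo, hi + 1))
    return "".join("ACT"[int(b)] for b in rng.integers(0, 3, size=length)) + "TAA"


def generate_community(spec: CommunitySpec) -> Community:
    """Generate contigs, peptides, reads, and the truth table.

    Each contig carries one PolA ORF (group template mutated at the
    within-group divergence with the 762 residue frozen) followed by its
    drawn replisome ORFs, separated by random intergenic spacers. Reads
    are exact substrings; each configured arrangement receives its share
    of total read mass split equally among the contigs realising it, and
    remaining contigs split the leftover mass.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    anchors = default_anchor_panel()
    pola_anchor = anchors["PolA_anchor"]
    panel = default_marker_panel()
    templates = group_templates(pola_anchor, spec.template_divergence)
    family_template = {
        label: panel.by_family(label)[0].sequence for label in panel.families
    }

    contigs: list[ContigRecord] = []
    gene_calls: list[GeneCall] = []
    peptides: list[PeptideRecord] = []
    truth: list[TruthRow] = []

    lo, hi = spec.spacer_range
    for group_name in sorted(spec.groups):
        group = spec.groups[group_name]
        residue = GROUP_RESIDUE[group_name]
        for i in range(group.count):
            contig_id = f"{group_name}_c{i:04d}"
            pola_pep = mutate_peptide(
                templates[group_name],
                spec.within_group_identity,
                frozen_positions={1, POS_762},
                seed=rng,
            )
            helicases, rnr_class = _draw_genes(group, rng)
            accessory = [
                gene
                for gene in sorted(group.accessory)
                if rng.random() < group.accessory[gene]
            ]
            gene_labels = list(helicases)
            if rnr_class:
                gene_labels.append(rnr_class)
            gene_labels.extend(accessory)
            gene_peps = [pola_pep]
            for label in gene_labels:
                gene_peps.append(
                    mutate_peptide(
                        family_template[label],
                        spec.gene_identity,
                        frozen_positions={1},
                        seed=rng,
                    )
                )
            parts = [_random_spacer(rng, lo, hi)]
            spans = []
            for pep in gene_peps:
                orf = reverse_translate(pep, seed=rng)
                start = sum(len(p) for p in parts) + 1
                spans.append((start, start + len(orf) - 1, pep))
                parts.append(orf)
                parts.append(_random_spacer(rng, lo, hi))
            sequence = "".join(parts)
            contigs.append(ContigRecord(id=contig_id, sequence=sequence, source_tag="synthetic"))
            for rank, (start, end, pep) in enumerate(spans, start=1):
                call = GeneCall(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                    peptide=pep,
                    rank=rank,
                )
                gene_calls.append(call)
                peptides.append(
                    PeptideRecord(id=call.peptide_id, sequence=pep, parent=(contig_id, rank))
                )
            truth.append(
                TruthRow(
                    contig_id=contig_id,
                    group=group_name,
                    residue762=residue,
                    genes=tuple(sorted(helicases + ([rnr_class] if rnr_class else []))),
                    rnr_class=rnr_class,
                    accessory=tuple(sorted(accessory)),
                    clade=TRUTH_CLADE.get((rnr_class, residue)) if rnr_class else None,
                    read_weight=0.0,
                    n_reads=0,
                )
            )

    _allocate_reads(spec, contigs, truth, rng)
    reads = _sample_reads(spec, contigs, truth, rng)
    return Community(
        contigs=contigs,
        gene_calls=gene_calls,
        peptides=peptides,
        reads=reads,
        truth=truth,
        spec=spec,
    )


def _allocate_reads(
    spec: CommunitySpec,
    contigs: list[ContigRecord],
    truth: list[TruthRow],
    rng: np.random.Generator,
) -> None:
    """Set per-contig read weights from the arrangement-abundance vector."""
    named: dict[tuple[str, tuple[str, ...]], list[int]] = {}
    for key in [(g, genes) for g, genes, _ in spec.abundance]:
        named[key] = []
    rest: list[int] = []
    for idx, t in enumerate(truth):
        key = (t.group, t.genes)
        if key in named:
            named[key].append(idx)
        else:
            rest.append(idx)
    weights = np.zeros(len(truth))
    leftover = 1.0
    for group, genes, share in spec.abundance:
        members = named[(group, genes)]
        if members:
            leftover -= share
            for idx in members:
                weights[idx] = share / len(members)
    if rest and leftover > 0:
        for idx in rest:
            weights[idx] = leftover / len(rest)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no contig received read mass; check the abundance vector")
    weights /= total
    for idx, t in enumerate(truth):
        t.read_weight = float(weights[idx])


def _sample_reads(
    spec: CommunitySpec,
    contigs: list[ContigRecord],
    truth: list[TruthRow],
    rng: np.random.Generator,
) -> list[ContigRecord]:
    weights = np.array([t.read_weight for t in truth])
    counts = rng.multinomial(spec.total_reads, weights)
    reads: list[ContigRecord] = []
    for contig, t, n in zip(contigs, truth, counts):
        t.n_reads = int(n)
        seq = contig.sequence
        max_start = len(seq) - spec.read_length
        if max_start < 0:
            raise ValueError(f"contig {contig.id} shorter than the read length")
        starts = rng.integers(0, max_start + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for j, (s, flip) in enumerate(zip(starts, strands)):
            read = seq[int(s) : int(s) + spec.read_length]
            if flip:
                read = reverse_complement(read)
            if spec.read_error_rate > 0:
                read = _add_errors(read, spec.read_error_rate, rng)
            reads.append(
                ContigRecord(
                    id=f"{contig.id}_r{j:06d}", sequence=read, source_tag="read"
                )
            )
    return reads


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    bases = list(read)
    for i in range(len(bases)):
        if rng.random() < rate:
            bases[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(bases)
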