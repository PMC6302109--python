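"""End-to-end orchestration: screen -> classify -> cluster -> profile ->
tree -> field guide, with every intermediate artifact written to disk.

The stages mirror the marker-gene workflow: PolA candidates are screened
from predicted peptides, 762-typed against the PolA anchor, clustered at
75% AAI over the anchored partial region, profiled for replisome gene
content, placed on distance trees (partial-region and concatenated
PolA+RNR), assigned to clades, and finally run through the field-guide
key. Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import (
    clustering,
    field_guide,
    marker_screen,
    phylogeny,
    replisome_profile,
    reference_anchoring,
)
from .marker_screen import MarkerPanel
from .reference_anchoring import ReferenceAnchor, anchor_map
from .seq_io import ContigRecord, PeptideRecord, read_fasta, write_fasta, write_table
from .synthetic_community import default_anchor_panel, default_marker_panel

logger = logging.getLogger("virisome")


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run.

    Defaults follow the screening and clustering rules the analysis is
    built on: PolA screen at E <= 1e-5 and >= 200 aa, homology graph at
    E <= 1e-20, 75% AAI (distance cutoff 0.25), core-gene fraction 0.5,
    and an 80% window-coverage requirement for anchored regions.
    """

    peptides: str = ""
    contigs: str = ""
    reads: str = ""
    outdir: str = "virisome_out"
    anchor_fasta: str = ""
    anchor_sidecar: str = ""
    panel_fasta: str = ""
    e_cutoff_screen: float = 1e-5
    e_cutoff_graph: float = 1e-20
    min_len: int = 200
    aai_cutoff: float = 0.75
    core_fraction: float = 0.5
    window_coverage: float = 0.8
    bootstrap_reps: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.aai_cutoff <= 1:
            raise ValueError("aai_cutoff must be in (0, 1]")
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must be in (0, 1]")
        if not 0 <= self.window_coverage <= 1:
            raise ValueError("window_coverage must be in [0, 1]")
        if self.e_cutoff_screen <= 0 or self.e_cutoff_graph <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls(**yaml.safe_load(handle))


@dataclass
class PipelineResult:
    classifications: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    predictions: list = field(default_factory=list)
    clusterset: object = None
    clades: list = field(default_factory=list)
    prevalence: list = field(default_factory=list)
    abundance: object = None
    core: dict = field(default_factory=dict)
    partial_tree: object = None
    concat_tree: object = None


def _stage(name: str, start: float, **counts) -> None:
    extras = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %-12s %6.2fs  %s", name, time.monotonic() - start, extras)


def _contig_of(peptide: PeptideRecord) -> str:
    if peptide.parent:
        return peptide.parent[0]
    return peptide.id.rsplit("_", 1)[0]


def _rank_of(peptide: PeptideRecord) -> int:
    if peptide.parent:
        return peptide.parent[1]
    try:
        return int(peptide.id.rsplit("_", 1)[1])
    except ValueError:
        return 0


def run_pipeline(
    config: RunConfig,
    peptides: list[PeptideRecord] | None = None,
    contigs: list[ContigRecord] | None = None,
    reads: list[ContigRecord] | None = None,
) -> PipelineResult:
    """Run every stage and write the report bundle under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    if peptides is None:
        if not config.peptides:
            raise ValueError("no peptide input provided")
        peptides = read_fasta(config.peptides, "amino-acid")
    if not peptides:
        raise ValueError(
            f"screen stage: peptide input {config.peptides or '<memory>'} is empty"
        )
    if contigs is None and config.contigs:
        contigs = read_fasta(config.contigs, "nucleotide")
    if reads is None and config.reads:
        reads = read_fasta(config.reads, "nucleotide")

    if config.anchor_fasta:
        anchors = reference_anchoring.load_anchor_panel(
            config.anchor_fasta, config.anchor_sidecar
        )
    else:
        anchors = default_anchor_panel()
    pola_anchor = anchors["PolA_anchor"]
    nrda_anchor = anchors["NrdA_anchor"]
    if config.panel_fasta:
        panel = MarkerPanel.from_fasta(read_fasta(config.panel_fasta, "amino-acid"))
    else:
        panel = default_marker_panel()

    # -- screen ------------------------------------------------------------
    t0 = time.monotonic()
    pola_peptides = marker_screen.screen_pola(
        peptides, panel, e_cutoff=config.e_cutoff_screen, min_len=config.min_len
    )
    pola_ids = {p.id for p in pola_peptides}
    _stage("screen", t0, peptides=len(peptides), pola=len(pola_peptides))
    if not pola_peptides:
        raise ValueError("screen stage: no PolA candidate passed the filters")

    # -- classify ----------------------------------------------------------
    t0 = time.monotonic()
    coord_maps = {p.id: anchor_map(p.sequence, pola_anchor) for p in pola_peptides}
    classifications = [
        reference_anchoring.classify_762(p, pola_anchor, coord_maps[p.id])
        for p in pola_peptides
    ]
    result.classifications = classifications
    write_table(
        reference_anchoring.classification_rows(classifications),
        outdir / "pola_classification.tsv",
    )
    _stage("classify", t0, classified=len(classifications))

    # -- annotate remaining genes -----------------------------------------
    t0 = time.monotonic()
    family_by_contig_rank: dict[str, dict[int, str]] = {}
    rnr_scores: dict[str, dict[int, float]] = {}
    for pep in peptides:
        if pep.id in pola_ids:
            continue
        family = marker_screen.assign_family(
            pep, panel, e_cutoff=config.e_cutoff_screen
        )
        if family is None or family == marker_screen.AMBIGUOUS or family == "PolA":
            continue
        contig = _contig_of(pep)
        rank = _rank_of(pep)
        family_by_contig_rank.setdefault(contig, {})[rank] = family
        if family in marker_screen.RNR_FAMILIES:
            score = max(
                marker_screen.local_score(pep.sequence, ex.sequence)
                for ex in panel.by_family(family)
            )
            rnr_scores.setdefault(contig, {})[rank] = score
    _stage(
        "annotate",
        t0,
        labelled=sum(len(v) for v in family_by_contig_rank.values()),
    )

    # -- profile -----------------------------------------------------------
    t0 = time.monotonic()
    classification_by_contig = {}
    pola_rank_of = {}
    for pep, cls in zip(pola_peptides, classifications):
        contig = _contig_of(pep)
        classification_by_contig[contig] = cls
        pola_rank_of[contig] = _rank_of(pep)
    profiles = []
    for contig in sorted(classification_by_contig):
        profiles.append(
            replisome_profile.profile_contig(
                contig,
                family_by_contig_rank.get(contig, {}),
                pola_rank_of[contig],
                classification_by_contig[contig],
                rnr_scores.get(contig),
            )
        )
    result.profiles = profiles
    _stage("profile", t0, contigs=len(profiles))

    # -- field guide (needed early: groups feed prevalence/abundance) ------
    t0 = time.monotonic()
    predictions = [field_guide.predict(p) for p in profiles]
    for profile, pred in zip(profiles, predictions):
        profile.group = pred.predicted_group
    result.predictions = predictions
    write_table(
        field_guide.prediction_rows(predictions), outdir / "field_guide_predictions.tsv"
    )
    _stage("guide", t0, predictions=len(predictions))

    # -- prevalence --------------------------------------------------------
    t0 = time.monotonic()
    prevalence = replisome_profile.group_gene_prevalence(
        profiles, by="group", pairs=[("Gp4-like", "RNR")]
    )
    result.prevalence = prevalence
    write_table(
        replisome_profile.prevalence_rows(prevalence), outdir / "gene_prevalence.tsv"
    )
    _stage("prevalence", t0, rows=len(prevalence))

    # -- abundance ---------------------------------------------------------
    if reads and contigs:
        t0 = time.monotonic()
        profiled = {p.contig_id for p in profiles}
        assignment = replisome_profile.recruit_reads_exact(
            reads, [c for c in contigs if c.id in profiled]
        )
        abundance = replisome_profile.combination_abundance(
            profiles, assignment, by="group"
        )
        result.abundance = abundance
        write_table(
            replisome_profile.abundance_rows(abundance),
            outdir / "combination_abundance.tsv",
        )
        _stage("abundance", t0, assigned=abundance.total_reads)

    # -- cluster (partial window, 75% AAI) ---------------------------------
    t0 = time.monotonic()
    partial_regions = {}
    for pep in pola_peptides:
        region, coverage = reference_anchoring.extract_window(
            pep, pola_anchor, "partial", coord_maps[pep.id]
        )
        if coverage >= config.window_coverage:
            partial_regions[pep.id] = pep
    if len(partial_regions) >= 2:
        msa = phylogeny.stack_anchored_alignment(
            list(partial_regions.values()), pola_anchor, "partial", coord_maps
        )
        dm = clustering.identity_distance_matrix(msa.ids, msa.rows)
        clusterset = clustering.furthest_neighbor_clusters(
            dm, cutoff=1 - config.aai_cutoff
        )
        peptide_index = {p.id: p for p in pola_peptides}
        clustering.assign_representatives(clusterset, peptide_index)
        result.clusterset = clusterset
        write_table(
            clustering.cluster_rows(clusterset), outdir / "pola_clusters.tsv"
        )
        _stage("cluster", t0, clusters=len(clusterset))

        # -- partial-region representative tree ----------------------------
        t0 = time.monotonic()
        reps = sorted(clusterset.representatives.values())
        if len(reps) >= 3:
            rep_msa = phylogeny.AnchoredMSA(
                ids=reps, rows=[msa.rows[msa.ids.index(r)] for r in reps]
            )
            tree = phylogeny.bootstrap_support(
                rep_msa, n_reps=config.bootstrap_reps, seed=config.seed
            )
            result.partial_tree = tree
            (outdir / "partial_region_tree.nwk").write_text(tree.to_newick() + "\n")
            _stage("tree", t0, leaves=len(reps))

    # -- concatenated PolA+RNR tree and clades ------------------------------
    t0 = time.monotonic()
    rnr_peptides: dict[str, PeptideRecord] = {}
    for pep in peptides:
        contig = _contig_of(pep)
        fam = family_by_contig_rank.get(contig, {}).get(_rank_of(pep))
        if fam in marker_screen.RNR_FAMILIES and contig in classification_by_contig:
            rnr_peptides.setdefault(contig, pep)
    concat_ids = sorted(set(rnr_peptides) & set(classification_by_contig))
    clade_assignments = []
    if concat_ids:
        pola_by_contig = {_contig_of(p): p for p in pola_peptides}
        pola_rows, rnr_rows, kept = {}, {}, []
        for contig in concat_ids:
            pola_pep = pola_by_contig[contig]
            region_msa = phylogeny.stack_anchored_alignment(
                [pola_pep], pola_anchor, "concat", coord_maps
            )
            rnr_pep = rnr_peptides[contig]
            rnr_msa = phylogeny.stack_anchored_alignment(
                [rnr_pep], nrda_anchor, "rnr_region"
            )
            cov_p = 1 - region_msa.rows[0].count("-") / region_msa.n_columns
            cov_r = 1 - rnr_msa.rows[0].count("-") / rnr_msa.n_columns
            if cov_p >= config.window_coverage and cov_r >= config.window_coverage:
                pola_rows[contig] = region_msa.rows[0]
                rnr_rows[contig] = rnr_msa.rows[0]
                kept.append(contig)
            else:
                logger.info("concat: contig %s excluded (coverage)", contig)
        for contig in kept:
            fam_map = family_by_contig_rank.get(contig, {})
            rnr_fams = [f for f in fam_map.values() if f in marker_screen.RNR_FAMILIES]
            clade_assignments.append(
                phylogeny.assign_clade(
                    rnr_fams[0],
                    classification_by_contig[contig].pol_type,
                    contig_id=contig,
                )
            )
        if len(kept) >= 3:
            concat_msa = phylogeny.AnchoredMSA(
                ids=kept, rows=[pola_rows[c] + rnr_rows[c] for c in kept]
            )
            concat_tree = phylogeny.bootstrap_support(
                concat_msa, n_reps=config.bootstrap_reps, seed=config.seed + 1
            )
            result.concat_tree = concat_tree
            (outdir / "concatenated_tree.nwk").write_text(
                concat_tree.to_newick() + "\n"
            )
            clade_assignments = phylogeny.resolve_clades_by_tree(
                clade_assignments, concat_tree
            )
        result.clades = clade_assignments
        write_table(phylogeny.clade_rows(clade_assignments), outdir / "clade_table.tsv")
        _stage("clades", t0, contigs=len(clade_assignments))

        # -- homology-graph gene clusters + core genes ----------------------
        t0 = time.monotonic()
        concat_set = set(kept)
        graph_peptides = [p for p in peptides if _contig_of(p) in concat_set]
        if graph_peptides:
            graph_clusters = clustering.homology_graph_clusters(
                graph_peptides, e_cutoff=config.e_cutoff_graph
            )
            contig_of_map = {p.id: _contig_of(p) for p in graph_peptides}
            clade_of = {
                a.contig_id: a.clade
                for a in clade_assignments
                if a.clade is not None
            }
            core = clustering.core_clusters(
                graph_clusters, contig_of_map, clade_of, fraction=config.core_fraction
            )
            result.core = core
            rows = []
            for clade in sorted(core, key=str):
                for cluster in core[clade]:
                    rows.append(
                        {
                            "clade": clade,
                            "core_cluster_members": ";".join(sorted(cluster)),
                        }
                    )
            if rows:
                write_table(rows, outdir / "core_gene_clusters.tsv")
            _stage(
                "core",
                t0,
                gene_clusters=len(graph_clusters),
                core=sum(len(v) for v in core.values()),
            )

    config.to_yaml(outdir / "run_config.yaml")
    return result
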