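# virisome

Marker-gene analysis of virioplankton contigs built around the viral
family A DNA polymerase (PolA) gene — one of the most widely distributed
genes among dsDNA bacteriophage and a marker whose single residue at the
reference position 762 tracks phage biology.

## The science

Roughly a quarter of known dsDNA phage carry *polA*. Aligning a
virioplankton PolA peptide to the *E. coli* IAI39 PolA protein assigns
every query residue a reference coordinate; the residue anchored at
position 762 (motif B) defines three polymerase types with distinct
biochemistry: the wild-type **Phe762**, the faster **Tyr762**, and the
slower but more faithful **Leu762**. These types, combined with the
replication genes co-residing on a contig — ring-shaped replicative
helicases (Gp4-like, DnaB-like), non-ring helicases (UvrD-, RecB-, SNF2-,
RecA-like), ribonucleotide reductase (RNR) classes, DnaG primase, MazG —
separate phage populations and predict lifestyle: Tyr762 and Phe762
Group I associate with ring helicases and RNRs and a lytic lifecycle,
while the Leu762 groups carry non-ring helicases, rarely an RNR, and lean
temperate.

The package implements, as a tested reusable pipeline:

* **762 typing** — global alignment (BLOSUM62, affine gaps, free end
  gaps) of query peptides onto a PolA anchor, reference-coordinate
  mapping, and classification of the anchored 762 residue;
* **marker screening** — Smith–Waterman search against a small family
  panel with a Karlin–Altschul E-value rule (E ≤ 1e-5, length ≥ 200 aa
  for PolA) replacing a database BLAST;
* **AAI clustering** — furthest-neighbour (complete-linkage) clustering
  of anchored PolA regions at 75% amino-acid identity, cluster
  representatives, and source-overlap summaries;
* **replisome profiling** — per-contig inventories of helicase families,
  RNR class and accessory genes; per-group gene prevalence and
  co-occurrence; read-recruitment-weighted abundance of PolA + gene
  arrangements;
* **phylogeny** — neighbour-joining trees with bootstrap supports over
  anchored regions, including the concatenated PolA (reference 784–926,
  143 aa) + RNR (NrdA 437–625, 189 aa) alignment of 332 columns that
  resolves nine clades defined by RNR class × 762 type;
* **field guide** — a dichotomous key (rules R1–R6) predicting group,
  lifestyle and candidate clade from replisome content, with an
  explainable rule trace and conflict flags;
* **synthetic communities** — a seeded generator emitting contigs,
  peptides, error-free reads and a truth table with configurable group
  sizes, gene co-occurrence probabilities and arrangement read shares,
  so every stage is testable without downloads.

Bundled anchors and panel exemplars are synthetic stand-ins (see
`src/virisome/data/*_synthetic*`); all analyses and tests run entirely
offline.

## Worked example

```python
from virisome import CommunitySpec, generate_community, screen_pola, classify_762
from virisome.synthetic_community import (
    GroupSpec, default_anchor_panel, default_marker_panel,
)

spec = CommunitySpec(
    groups={
        "Tyr762": GroupSpec(count=3, genes={"Gp4-like": 1.0, "RNR": 1.0},
                            rnr_classes={"RNR-I-CyanoSP": 1.0}),
        "Leu762-II": GroupSpec(count=2,
                               arrangements=[(("SNF2-like", "UvrD-like"), 1.0)]),
    },
    seed=11, total_reads=500,
)
community = generate_community(spec)
panel = default_marker_panel()
anchor = default_anchor_panel()["PolA_anchor"]

pola = screen_pola(community.peptides, panel)
print(f"{len(pola)} of {len(community.peptides)} peptides pass the PolA screen")
for pep in pola:
    cls = classify_762(pep, anchor)
    print(pep.id, cls.residue762, cls.pol_type, f"coverage={cls.coverage:.2f}")
```

prints

```
5 of 15 peptides pass the PolA screen
Leu762-II_c0000_1 L Leu762 coverage=1.00
Leu762-II_c0001_1 L Leu762 coverage=1.00
Tyr762_c0000_1 Y Tyr762 coverage=1.00
Tyr762_c0001_1 Y Tyr762 coverage=1.00
Tyr762_c0002_1 Y Tyr762 coverage=1.00
```

Each of the fifteen predicted peptides was screened against the marker
panel; only the five PolA genes pass the E-value and length filters, and
each is typed by its anchored 762 residue. Profiling the same contigs and
running the field guide then yields, per contig, the predicted group,
lifestyle, candidate clade and the rule that fired — e.g. a Tyr762 contig
with a Gp4-like helicase and a Class I Cyano SP RNR is predicted lytic,
clade 5, via rule R1, and a Leu762 contig with SNF2-like + UvrD-like
helicases is predicted temperate Leu762-II via rule R5.

The same stages are available from the shell:

```
virisome generate --outdir community/          # bundled serc_fig2 config
virisome run-all --peptides community/peptides.fasta \
                 --contigs community/contigs.fasta \
                 --reads community/reads.fasta --outdir report/
```

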