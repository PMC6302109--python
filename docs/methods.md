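# Methods

## Reference-anchored coordinates

All residue numbering is defined by pairwise global alignment of a query
peptide to a reference anchor (Needleman–Wunsch, BLOSUM62, affine gaps
with a length-*L* gap costing 12 + (*L*−1)·1, end gaps free on both
sequences). Free end gaps on both sides make classification invariant to
query truncation *and* to unrelated flanking residues, which partial
metagenomic ORFs routinely have. Alignment is delegated to Biopython's
`PairwiseAligner`; ties between equally optimal tracebacks are broken by
its fixed enumeration order, so outputs are deterministic for a given
input and library version. The coordinate map sends each reference
position to the query residue in the same column, or to "deleted"; a
query whose aligned span excludes position 762 is classed Unresolved
rather than guessed.

Anchored "stacking" builds fixed-width alignments with one column per
reference window position, discarding query insertions relative to the
reference. This fixes column homology without a multiple-alignment
heuristic and suits the analysis, whose windows (675–799, 547–926,
784–926 on PolA; 437–625 on NrdA) are defined in reference coordinates.
Regions covering < 80% of a window are excluded from clustering and
trees; the threshold is a package choice (the underlying analysis keeps
as many sequences as possible but states no cutoff).

## Synthetic anchors and marker panel

The real reference proteins are not redistributable here, so the bundled
anchor FASTA and marker panel are *synthetic stand-ins*: seeded random
peptides of realistic lengths (PolA anchor 928 aa with Phe at 762, NrdA
anchor 761 aa) and one exemplar per replication-gene family, with the
four RNR class exemplars derived from the NrdA anchor at 30% divergence
so they share its coordinate system. Nothing in the algorithms depends on
the anchor's actual residues — only on the coordinate frame it defines —
and all tests generate queries from these same scaffolds. Results on real
data require swapping in real anchor/panel FASTAs via the documented
sidecar format.

## Marker screening

Smith–Waterman local alignment against the panel replaces a BLAST search
against a large database. Significance uses the Karlin–Altschul form
E = K·m·n·exp(−λS) with the gapped BLOSUM62 constants (K = 0.041,
λ = 0.267) and the panel entry as the database, so absolute E-values are
not comparable to database E-values; only the decision rule's shape
(E ≤ 1e-5 and ≥ 200 aa for PolA; E ≤ 1e-20 for the gene-cluster graph) is
preserved. Family assignment takes the best-scoring family, requires
≥ 30% coverage of the exemplar (standing in for a domain-database
confirmation), and reports "ambiguous" when the top two families score
within 5% — ambiguous calls are excluded from prevalence statistics.

## Clustering

Marker clustering is furthest-neighbour (complete-linkage) agglomeration
on 1 − AAI distances over anchored columns, cut at 0.25 (75% identity).
Identity counts matching residues over columns where at least one of the
pair has a residue, excluding columns outside the intersection of the two
aligned spans (terminal gaps); an internal gap opposite a residue counts
as a difference. The linkage is computed with scipy's complete-linkage
implementation; cutting the dendrogram at the cutoff yields exactly the
partitions whose cluster diameters stay within the cutoff, and that
invariant is asserted on every output. Cluster representatives are the
longest members (ties to the lexicographically smallest id).

Gene clustering over all peptides of PolA+RNR contigs is single-linkage:
an undirected edge joins two peptides when their local alignment is
significant at E ≤ 1e-20 in either direction, and clusters are connected
components. Core clusters of a clade are those present on at least
⌈0.5·n⌉ of the clade's contigs.

## Trees and clades

Trees are Saitou–Nei neighbour joining on p-distances (mismatches over
shared non-gap columns), with negative branch lengths clamped to zero and
deterministic pair selection (smallest Q, ties by lexicographic id pair).
NJ provably reproduces additive matrices, which the test suite exercises
on random trees. Bootstrap supports resample columns with replacement
(default 10 replicates, seeded) and report the fraction of replicate
trees containing each internal bipartition. Distance/NJ stands in for
maximum-likelihood inference deliberately: the clade structure of
interest rests on marker combinations, which NJ resolves on the data the
package targets, and NJ is exactly specifiable and testable.

Clade assignment maps (RNR class, 762 type) to clades 1–9; combinations
split across several clades ({2,3}, {1,8}, {1,9}) are returned as
candidate sets and resolved, when a concatenated tree is available, by
the nearest labelled leaf whose clade lies in the candidate set —
otherwise the set itself is reported rather than forcing a choice.

## Replisome profiles and abundance

"Neighbouring" is operationalised as same-contig presence — the primary
statistic is the percentage of a group's contigs containing each gene —
with an advisory adjacency statistic (within 5 gene ranks of the PolA
gene) reported separately, because contig-level presence is the quantity
the arrangement percentages refer to. At most one RNR class is kept per
contig (best score wins). Read recruitment is exact-substring matching of
error-free reads (either orientation); reads matching more than one
contig are dropped from both numerator and denominator, a fixed and
documented rule standing in for a best-hit mapper. Arrangement abundance
is the share of recruited reads on contigs with each (group × helicase
set × RNR class) combination, accessory genes excluded from the key.

## The synthetic community generator

The generator *is* the study condition, not a tuning dial. Defaults
(`data/serc_fig2.yaml`): per-group contig counts 289 / 124 / 42 / 119 /
247 (Tyr762, Phe762-I, Phe762-II, Leu762-I, Leu762-II), gene draws that
reproduce the printed per-group percentages — including joint draws where
co-occurrence is stated (Tyr762: Gp4 69%, RNR 40%, both 34%; Leu762-I:
RecB 70%, SNF2 55%, both 54%) — and read shares 28.4% / 16.4% / 13.3% for
the three printed arrangements, with the remaining mass spread equally
over all other contigs. For Leu762-II the printed marginals (SNF2 45%,
UvrD 68%) cannot coexist with a strict "UvrD only ever with SNF2"
constraint; the generator keeps the marginals and maximises co-occurrence
(both = 45%). RNR class splits within groups and accessory-gene
probabilities are not printed anywhere; the defaults echo the overall
class mix reported for PolA+RNR contigs and are fixed here once.

Group PolA templates are generated de novo around the anchor scaffold
(35% divergence, fixed internal seeds, 762 frozen to the group residue);
community peptides diverge 10% from their templates, so within-group
identity sits near the 75% clustering threshold's comfortable side while
between-group identity falls near 50%. ORFs use uniformly drawn
synonymous codons; intergenic spacers are drawn over {A,C,T} and end with
an in-frame TAA so each gene's ORF is exactly maximal for the ORF finder.
Reads are error-free 150-mers with contig selection weights from the
arrangement-abundance vector (an optional uniform substitution-error mode
exists, off by default).

What passing tests show — and do not show. The generator emulates the
*statistical* structure the pipeline assumes (frozen marker residues,
family-distinct gene templates, exact reads); it does not emulate
sequencing error, assembly chimerism, codon/GC bias, gene fragments
spanning contig edges, or homology between families. Recovery results
therefore validate the pipeline's logic and its behaviour under
amino-acid divergence, not its robustness to real-world assembly noise.

## Problem sizes and numerical choices

The acceptance computations use 1,000 contigs for prevalence recovery and
the full 821-contig default community with 100,000 reads for abundance
recovery; unit tests use communities of tens of contigs. Binomial noise
at n = 1000 puts a ±3-point band at roughly two standard errors for a
69% gene. Distances live in [0,1]; furthest-neighbour cutoffs compare
with a 1e-12 slack; Newick branch lengths serialise at 9 decimal places.
Degenerate inputs fail loudly: empty FASTA, empty panel, contigs without
a verified PolA, pairs of rows sharing no alignment columns, and NJ on
fewer than three taxa all raise errors naming the offender.

## Known limitations

* E-values are panel-relative; do not compare them to database BLAST runs.
* The 762 classifier reports single residues; it does not model alignment
  uncertainty near the site (at ≤ 40% divergence recovery is exact on
  ≥ 200 seeded trials, which the test suite re-verifies).
* Phe762/Leu762 group membership (I vs II) is defined through replisome
  content, not through manual tree cuts; contigs lacking the diagnostic
  helicases surface as Unassigned instead of being forced.
* The homology-graph stage is quadratic in peptide count and intended for
  the PolA+RNR contig subset, not whole viromes.
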