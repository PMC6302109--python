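"""Anchored alignment, coordinate maps, 762 typing, window extraction."""


import numpy as np
import pytest

from virisome.reference_anchoring import (
    PairwiseAlignment,
    ReferenceAnchor,
    anchor_map,
    build_coordinate_map,
    classify_762,
    extract_window,
    global_align,
)
from virisome.seq_io import PeptideRecord
from virisome.synthetic_community import mutate_peptide, random_peptide

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = -12.0, -1.0


def brute_force_best_score(a: str, b: str) -> float:
    """Enumerate every global alignment of a and b; affine gap scoring with
    free end gaps on both sequences. Exponential: tiny inputs only."""

    best = [-np.inf]

    def score(pairs):
        total, prev_gap = 0.0, None
        runs = []  # (which, start_index, length) gap runs
        for idx, (x, y) in enumerate(pairs):
            if x == "-" or y == "-":
                which = "a" if x == "-" else "b"
                if prev_gap == which:
                    runs[-1][2] += 1
                else:
                    runs.append([which, idx, 1])
                prev_gap = which
            else:
                total += BLOSUM62[x, y]
                prev_gap = None
        for which, start, length in runs:
            end = start + length
            if start == 0 or end == len(pairs):  # terminal run: free
                continue
            total += GAP_OPEN + (length - 1) * GAP_EXTEND
        return total

    def walk(i, j, pairs):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(pairs))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, pairs + [(a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, pairs + [(a[i], "-")])
        if j < len(b):
            walk(i, j + 1, pairs + [("-", b[j])])

    walk(0, 0, [])
    return best[0]


@pytest.mark.parametrize(
    "query,ref",
    [
        ("MKLVAD", "MKLAVHAD"),
        ("ACDEF", "ACDEFGH"),
        ("WNDC", "WQNDCRS"),
    ],
)
def test_global_align_matches_exhaustive_enumeration(query, ref):
    aln = global_align(query, ref)
    assert aln.score == pytest.approx(brute_force_best_score(ref, query))


def test_identical_sequences_align_gapless(pola_anchor):
    aln = global_align(pola_anchor.peptide, pola_anchor.peptide)
    assert "-" not in aln.query_aligned
    cmap = build_coordinate_map(aln)
    n = len(pola_anchor.peptide)
    assert all(cmap.ref_to_query[i] == i for i in range(1, n + 1))
    assert cmap.query_span == (1, n)


def test_internal_deletion_produces_one_gap_run(pola_anchor):
    ref = pola_anchor.peptide
    query = ref[:400] + ref[403:]  # 3-aa internal deletion
    aln = global_align(query, ref)
    gap_runs = [run for run in aln.query_aligned.split("-") if run]
    assert aln.query_aligned.count("-") == 3
    cmap = build_coordinate_map(aln)
    deleted = [i for i in range(1, len(ref) + 1) if cmap.lookup(i) is None
               and cmap.query_span[0] <= i <= cmap.query_span[1]]
    assert deleted == [401, 402, 403]


def test_insertion_shifts_mapping():
    # hand-constructed alignment: 3-residue insertion before ref position 5
    aln = PairwiseAlignment(
        query_aligned="ACDEWWWFGHIK",
        ref_aligned="ACDE---FGHIK",
        score=0.0,
    )
    cmap = build_coordinate_map(aln)
    assert cmap.ref_to_query[4] == 4
    assert cmap.ref_to_query[5] == 8
    assert cmap.ref_to_query[9] == 12


def test_alignment_invariants_recover_sequences(pola_anchor, rng):
    query = mutate_peptide(pola_anchor.peptide, 0.8, seed=rng)[100:600]
    aln = global_align(query, pola_anchor.peptide)
    assert aln.query == query
    assert aln.ref == pola_anchor.peptide
    cmap = build_coordinate_map(aln)
    mapped = [v for v in cmap.ref_to_query.values() if v != "deleted"]
    assert mapped == sorted(mapped)  # strictly increasing


def test_classify_anchor_against_itself_is_phe(pola_anchor):
    cls = classify_762(
        PeptideRecord(id="anchor", sequence=pola_anchor.peptide), pola_anchor
    )
    assert cls.residue762 == "F"
    assert cls.pol_type == "Phe762"


def test_classify_constructed_tyrosine_substitution(pola_anchor):
    seq = pola_anchor.peptide
    mutant = seq[:761] + "Y" + seq[762:]
    cls = classify_762(PeptideRecord(id="y", sequence=mutant), pola_anchor)
    assert cls.pol_type == "Tyr762"


def test_classify_fragment_missing_762_is_unresolved(pola_anchor):
    fragment = pola_anchor.peptide[99:400]  # residues 100-400
    cls = classify_762(PeptideRecord(id="frag", sequence=fragment), pola_anchor)
    assert cls.residue762 == "unresolved"
    assert cls.pol_type == "Unresolved"


def test_classify_invariant_under_flanking_padding(pola_anchor, rng):
    core = mutate_peptide(pola_anchor.peptide, 0.85, frozen_positions={762}, seed=rng)
    padded = random_peptide(40, seed=rng, start_with_met=False) + core + \
        random_peptide(40, seed=rng, start_with_met=False)
    for seq in (core, padded):
        cls = classify_762(PeptideRecord(id="p", sequence=seq), pola_anchor)
        assert cls.pol_type == "Phe762"


@pytest.mark.parametrize("divergence", [0.1, 0.2, 0.3, 0.4])
def test_762_recovery_under_divergence(pola_anchor, divergence):
    """Frozen 762 residues are recovered exactly up to 40% divergence."""
    rng = np.random.default_rng(int(divergence * 100))
    for trial in range(50):
        mutant = mutate_peptide(
            pola_anchor.peptide, 1 - divergence, frozen_positions={762}, seed=rng
        )
        cls = classify_762(PeptideRecord(id=f"m{trial}", sequence=mutant), pola_anchor)
        assert cls.residue762 == "F", f"lost 762 at divergence {divergence}"


def test_window_lengths_on_anchor(pola_anchor, nrda_anchor):
    region, cov = extract_window(
        PeptideRecord(id="a", sequence=pola_anchor.peptide), pola_anchor, "partial"
    )
    assert len(region) == 125 and cov == 1.0
    region, cov = extract_window(
        PeptideRecord(id="n", sequence=nrda_anchor.peptide), nrda_anchor, "rnr_region"
    )
    assert len(region) == 189 and cov == 1.0


def test_window_with_deletion_reports_partial_coverage(pola_anchor):
    ref = pola_anchor.peptide
    # delete residues 700-709 (inside the partial window 675-799)
    query = ref[:699] + ref[709:]
    region, cov = extract_window(
        PeptideRecord(id="d", sequence=query), pola_anchor, "partial"
    )
    assert len(region) == 115
    assert cov == pytest.approx(115 / 125)


def test_extract_window_unknown_label_errors(pola_anchor):
    with pytest.raises(ValueError, match="no window"):
        extract_window(
            PeptideRecord(id="a", sequence=pola_anchor.peptide), pola_anchor, "nope"
        )


def test_anchor_validation_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        ReferenceAnchor(name="x", peptide="MKL", named_positions={"pos762": 10})
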