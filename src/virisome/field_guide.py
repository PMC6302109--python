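"""Dichotomous-key prediction of phage group, lifestyle, and clade.

The key encodes the observed genome-to-phenome associations: ring-shaped
replicative helicases (Gp4-like, DnaB-like) and RNRs travel with the
lytic Tyr762 and Phe762 Group I populations, while the putatively
temperate Leu762 groups carry non-ring helicases (RecB/SNF2 for Group I,
UvrD/SNF2 for Group II) and rarely an RNR. Rules fire in order on
contig-level gene presence; every prediction carries the ordered trace of
fired rules and any conflicts with the expected associations, so a
downstream report can show *why* a contig was classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylogeny import CLADE_MAP, CladeAssignment
from .replisome_profile import ReplisomeProfile

RING_HELICASES = frozenset({"Gp4-like", "DnaB-like"})
NON_RING_HELICASES = frozenset({"RecA-like", "SNF2-like", "RecB-like", "UvrD-like"})

LYTIC = "lytic"
TEMPERATE = "temperate"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FieldGuidePrediction:
    contig_id: str
    predicted_group: str
    lifestyle: str
    clade_candidates: frozenset[int]
    rule_trace: tuple[str, ...]
    conflicts: tuple[str, ...]


def _clade_candidates(profile: ReplisomeProfile) -> frozenset[int]:
    if profile.rnr_class is None:
        return frozenset()
    return CLADE_MAP.get((profile.rnr_class, profile.pola.pol_type), frozenset())


def predict(
    profile: ReplisomeProfile,
    clade_assignment: CladeAssignment | None = None,
) -> FieldGuidePrediction:
    """Apply the dichotomous key to one replisome profile.

    Rules (stable public ids, applied in order):

    * R1  Tyr762 -> group Tyr762, lytic.
    * R2  Phe762 with a DnaB-like helicase -> Phe762-I, lytic.
    * R3  Phe762, no ring helicase, any non-ring helicase -> Phe762-II,
          indeterminate (lytic lifestyle is only asserted for Tyr762 and
          Phe762 Group I).
    * R4  Leu762 with RecB-like and SNF2-like -> Leu762-I, temperate.
    * R5  Leu762 with UvrD-like and SNF2-like -> Leu762-II, temperate.
    * R6  Leu762 otherwise -> group Unassigned, indeterminate
          (temperate-leaning but not forced).

    Conflicts are flagged when a profile contradicts the expected
    associations (an RNR or a Gp4-like helicase on a Leu762 contig), and
    when no rule fires at all.
    """
    trace: list[str] = []
    conflicts: list[str] = []
    pol_type = profile.pola.pol_type
    hel = profile.helicases
    group, lifestyle = "Unassigned", INDETERMINATE

    if pol_type == "Tyr762":
        trace.append("R1")
        group, lifestyle = "Tyr762", LYTIC
    elif pol_type == "Phe762" and "DnaB-like" in hel:
        trace.append("R2")
        group, lifestyle = "Phe762-I", LYTIC
    elif pol_type == "Phe762" and not (hel & RING_HELICASES) and (hel & NON_RING_HELICASES):
        trace.append("R3")
        group, lifestyle = "Phe762-II", INDETERMINATE
    elif pol_type == "Leu762" and {"RecB-like", "SNF2-like"} <= hel:
        trace.append("R4")
        group, lifestyle = "Leu762-I", TEMPERATE
    elif pol_type == "Leu762" and {"UvrD-like", "SNF2-like"} <= hel:
        trace.append("R5")
        group, lifestyle = "Leu762-II", TEMPERATE
    elif pol_type == "Leu762":
        trace.append("R6")
        group, lifestyle = "Unassigned", INDETERMINATE

    if pol_type == "Leu762":
        if profile.rnr_class is not None:
            conflicts.append(f"RNR ({profile.rnr_class}) present on a Leu762 contig")
        if "Gp4-like" in hel:
            conflicts.append("Gp4-like helicase present on a Leu762 contig")
    if not trace:
        conflicts.append(f"no rule fired for pol_type={pol_type}")

    if clade_assignment is not None and clade_assignment.clade is not None:
        clades = frozenset({clade_assignment.clade})
    else:
        clades = _clade_candidates(profile)
    return FieldGuidePrediction(
        contig_id=profile.contig_id,
        predicted_group=group,
        lifestyle=lifestyle,
        clade_candidates=clades,
        rule_trace=tuple(trace),
        conflicts=tuple(conflicts),
    )


def prediction_rows(predictions: list[FieldGuidePrediction]) -> list[dict]:
    return [
        {
            "contig_id": p.contig_id,
            "group": p.predicted_group,
            "lifestyle": p.lifestyle,
            "clades": "|".join(map(str, sorted(p.clade_candidates))) or "none",
            "rules_fired": ";".join(p.rule_trace) or "none",
            "conflicts": ";".join(p.conflicts) or "none",
        }
        for p in sorted(predictions, key=lambda x: x.contig_id)
    ]
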