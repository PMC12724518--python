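"""Differential Nm-site classification across isogenic conditions and orphan
snoRNA target assignment.

The study design compares four isogenic neuron lines: two wild types (CT2,
H9) and their SNORD116-cluster deletion derivatives (CT2-smDEL, H9-smDEL);
CT2 additionally expresses the SNORD113/114 clusters that the other three
lines lack. A site's presence/absence pattern across (CT2, CT2-smDEL, H9,
H9-smDEL) therefore encodes which orphan snoRNA family could have guided it:

    present, absent, absent, absent   ->  SNORD113/114 candidate
    present, absent, present, absent  ->  SNORD116 candidate
    present in all four               ->  shared
    present only in one parental pair ->  cell-line specific

Candidates are then confirmed by a canonical guide scan restricted to the
matching snoRNA family: the site must pair with a family member's antisense
element with the Nm positioned five nucleotides upstream of box D/D'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .caller import NmSite
from .guide import GuideMatch, SnoRNAModel, scan_targets, snorna_family

CANONICAL_CONDITIONS = ("CT2", "CT2-smDEL", "H9", "H9-smDEL")

PRESENT, ABSENT, AMBIGUOUS = "present", "absent", "ambiguous"

CLASSES = (
    "shared",
    "SNORD113114_candidate",
    "SNORD116_candidate",
    "CT2_specific",
    "H9_specific",
    "unclassified",
)

_PATTERN_TO_CLASS = {
    ("P", "A", "A", "A"): "SNORD113114_candidate",
    ("P", "A", "P", "A"): "SNORD116_candidate",
    ("P", "P", "P", "P"): "shared",
    ("P", "P", "A", "A"): "CT2_specific",
    ("A", "A", "P", "P"): "H9_specific",
}


@dataclass
class PresenceMatrix:
    """Per-site presence state and Nm score across the four conditions."""

    conditions: Tuple[str, ...]
    rows: List[Tuple[str, int, str]]  # (contig, pos, strand)
    states: Dict[Tuple[str, int, str], Tuple[str, ...]]
    scores: Dict[Tuple[str, int, str], Tuple[float, ...]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for key in self.rows:
            rec = {"contig": key[0], "pos": key[1], "strand": key[2]}
            for c, st, sc in zip(self.conditions, self.states[key], self.scores[key]):
                rec[f"{c}_state"] = st
                rec[f"{c}_score"] = sc
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass
class DifferentialCall:
    site: Tuple[str, int, str]
    call_class: str
    assigned_snorna: Optional[str] = None
    guide_match: Optional[GuideMatch] = None


def build_matrix(
    site_lists: Sequence[Tuple[str, Sequence[NmSite]]],
    present_min: float = 500,
    absent_max: float = 50,
) -> PresenceMatrix:
    """Presence/absence matrix over the union of called positions.

    ``site_lists`` is an ordered sequence of (condition label, called sites).
    A cell is present when its Nm score reaches ``present_min``, absent at or
    below ``absent_max`` (uncalled positions score 0), and ambiguous in
    between. Positions present in no condition are dropped. Positions are
    compared at single-nucleotide exactness on matching strand.
    """
    if isinstance(site_lists, dict):
        site_lists = list(site_lists.items())
    labels = [lab for lab, _ in site_lists]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    if absent_max >= present_min:
        raise ValueError("absent_max must be below present_min")
    score_maps: List[Dict[Tuple[str, int, str], float]] = []
    for _, sites in site_lists:
        m: Dict[Tuple[str, int, str], float] = {}
        for s in sites:
            key = (s.contig, s.pos, s.strand)
            m[key] = max(m.get(key, 0.0), s.nm_score)
        score_maps.append(m)
    union = sorted({k for m in score_maps for k in m})
    rows, states, scores = [], {}, {}
    for key in union:
        sc = tuple(m.get(key, 0.0) for m in score_maps)
        st = tuple(
            PRESENT if x >= present_min else ABSENT if x <= absent_max else AMBIGUOUS
            for x in sc
        )
        if PRESENT not in st:
            continue
        rows.append(key)
        states[key] = st
        scores[key] = sc
    return PresenceMatrix(tuple(labels), rows, states, scores)


def classify(matrix: PresenceMatrix) -> List[DifferentialCall]:
    """Map each row's presence pattern to a differential class.

    Requires the canonical condition order (CT2, CT2-smDEL, H9, H9-smDEL).
    Rows containing an ambiguous cell, or a pattern outside the recognised
    set, are unclassified. Pure function of the matrix: row order in, row
    order out.
    """
    if matrix.conditions != CANONICAL_CONDITIONS:
        raise ValueError(
            f"classification requires conditions {CANONICAL_CONDITIONS}, "
            f"got {matrix.conditions}"
        )
    calls = []
    for key in matrix.rows:
        st = matrix.states[key]
        if AMBIGUOUS in st:
            cls = "unclassified"
        else:
            pattern = tuple("P" if x == PRESENT else "A" for x in st)
            cls = _PATTERN_TO_CLASS.get(pattern, "unclassified")
        calls.append(DifferentialCall(key, cls))
    return calls


@dataclass
class _Site:
    contig: str
    pos: int
    strand: str


def assign_targets(
    calls: Iterable[DifferentialCall],
    snornas: Iterable[SnoRNAModel],
    reference,
    window: int = 7,
    min_pairs: int = 9,
    max_mismatches: int = 2,
) -> List[DifferentialCall]:
    """Attach the best canonical guide match from the class-matching snoRNA
    family to each candidate call.

    SNORD116 candidates are scanned only against SNORD116 snoRNAs and
    SNORD113/114 candidates only against those two families, so a
    deletion-dependent site can never be "explained" by an unrelated
    snoRNA. Candidates with no canonical match keep their class but stay
    unassigned; all calls are returned.
    """
    by_family: Dict[str, List[SnoRNAModel]] = {}
    for m in snornas:
        fam = m.family or snorna_family(m.id)
        by_family.setdefault(fam, []).append(m)
    family_sets = {
        "SNORD116_candidate": by_family.get("SNORD116", []),
        "SNORD113114_candidate": by_family.get("SNORD113", [])
        + by_family.get("SNORD114", []),
    }
    out = []
    for call in calls:
        pool = family_sets.get(call.call_class)
        if pool:
            site = _Site(*call.site)
            matches = scan_targets(
                pool, [site], reference, window, min_pairs, max_mismatches
            )
            if matches:
                best = matches[0]  # scan_targets sorts by duplex score desc
                call = DifferentialCall(call.site, call.call_class, best.snorna_id, best)
        out.append(call)
    return out


def calls_to_frame(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        gm = c.guide_match
        rows.append(
            {
                "contig": c.site[0],
                "pos": c.site[1],
                "strand": c.site[2],
                "class": c.call_class,
                "assigned_snorna": c.assigned_snorna or "",
                "ase_kind": gm.ase_kind if gm else "",
                "n_pairs": gm.n_pairs if gm else "",
                "n_gu_pairs": gm.n_gu_pairs if gm else "",
                "n_mismatches": gm.n_mismatches if gm else "",
                "duplex_score": gm.duplex_score if gm else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "strand", "class", "assigned_snorna",
            "ase_kind", "n_pairs", "n_gu_pairs", "n_mismatches", "duplex_score",
        ],
    )
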