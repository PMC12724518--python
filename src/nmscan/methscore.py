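"""MethScore computation from alkaline-fragmentation (RiboMeth-seq) end profiles.

Alkaline hydrolysis cleaves RNA 3' of every nucleotide except where the ribose
carries a 2'-O-methyl group, so methylated positions show a *deficit* of read
ends. For position n the end sum is

    S(n) = ends3(n) + ends5(n + 1)

(the two read ends created by a cleavage between n and n+1), and the MethScore
compares S(n) with a weighted summary of the end sums in the +-flank window:

    paper_literal:  1 - S(n) / (0.5 * sum_f w_f S(f) / sum_f w_f)
    mean_mode:      1 - S(n) / (sum_f w_f S(f) / sum_f w_f)

``paper_literal`` keeps the halved denominator found in the method's
published description; under it an unprotected position has a raw score of
about -1, hence scores are clamped to [0, 1]. ``mean_mode`` divides by the
plain weighted mean, making the score equal the protection fraction (and
hence the methylation stoichiometry) under uniform cleavage; the two raw
scores obey raw_literal = 2 * raw_mean - 1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import pandas as pd

DENOMINATOR_MODES = ("paper_literal", "mean_mode")


@dataclass
class EndProfile:
    """Per-nucleotide counts of read 5' and 3' ends on one contig/strand."""

    contig: str
    strand: str
    ends5: Dict[int, int] = field(default_factory=dict)
    ends3: Dict[int, int] = field(default_factory=dict)
    replicate_id: str = "rep1"
    contig_length: Optional[int] = None


def end_sum(profile: EndProfile, n: int) -> int:
    """S(n) = 3'-ends at n plus 5'-ends at n+1; absent positions contribute 0."""
    return profile.ends3.get(n, 0) + profile.ends5.get(n + 1, 0)


def _weighted_flank_mean(
    profile: EndProfile, n: int, flank: int, weights: Optional[Sequence[float]]
) -> Optional[float]:
    positions = list(range(n - flank, n)) + list(range(n + 1, n + flank + 1))
    if weights is None:
        weights = [1.0] * len(positions)
    if len(weights) != len(positions):
        raise ValueError(f"need {len(positions)} weights for flank={flank}")
    sums = [end_sum(profile, p) for p in positions]
    if all(s == 0 for s in sums):
        return None
    return sum(w * s for w, s in zip(weights, sums)) / sum(weights)


def methscore(
    profile: EndProfile,
    n: int,
    flank: int = 2,
    weights: Optional[Sequence[float]] = None,
    denominator_mode: str = "paper_literal",
    clamp: bool = True,
) -> Optional[float]:
    """MethScore at position n, or None where it is undefined.

    Undefined when the flank window extends past the contig (if the profile
    knows its contig length) or when every flanking end sum is zero. Weights
    default to uniform and run 5' to 3' over the 2*flank flanking positions.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    if n - flank < 0:
        return None
    if profile.contig_length is not None and n + flank >= profile.contig_length:
        return None
    m = _weighted_flank_mean(profile, n, flank, weights)
    if m is None:
        return None
    denom = 0.5 * m if denominator_mode == "paper_literal" else m
    raw = 1.0 - end_sum(profile, n) / denom
    return min(1.0, max(0.0, raw)) if clamp else raw


def methscore_track(
    profiles: Iterable[EndProfile],
    flank: int = 2,
    weights: Optional[Sequence[float]] = None,
    denominator_mode: str = "paper_literal",
) -> pd.DataFrame:
    """Per-position mean and sample SD of the MethScore across replicates.

    ``profiles`` are replicate EndProfiles for one contig/strand. Missing
    (undefined) replicate scores are skipped; positions undefined in every
    replicate are omitted. SD is NaN with fewer than two defined replicates.
    Returns a DataFrame with columns contig, pos, strand, methscore_mean,
    methscore_sd, n_replicates.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one replicate profile")
    contig, strand = profiles[0].contig, profiles[0].strand
    for p in profiles:
        if (p.contig, p.strand) != (contig, strand):
            raise ValueError("all replicate profiles must share contig and strand")
    observed = set()
    for p in profiles:
        observed.update(p.ends3)
        observed.update(q - 1 for q in p.ends5)
    # a fully protected position has no ends of its own; score any position
    # within flank reach of observed signal so such gaps are not silently lost
    positions = set()
    for q in observed:
        positions.update(range(q - flank, q + flank + 1))
    rows = []
    for n in sorted(positions):
        if n < 0:
            continue
        scores = [
            s
            for p in profiles
            if (s := methscore(p, n, flank, weights, denominator_mode)) is not None
        ]
        if not scores:
            continue
        k = len(scores)
        mean = sum(scores) / k
        if k > 1:
            sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / (k - 1))
        else:
            sd = float("nan")
        rows.append((contig, n, strand, mean, sd, k))
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "strand", "methscore_mean", "methscore_sd", "n_replicates"],
    )
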