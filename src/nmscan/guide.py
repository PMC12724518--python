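"""Box C/D snoRNA guide analysis: motif location, duplex scoring, target prediction.

Box C/D snoRNAs carry C (RUGAUGA) and D (CUGA) motifs, often with internal C'
and D' copies. The 10-15 nt antisense element (ASE) immediately 5' of box D
(or D') base-pairs with the target RNA, and the target nucleotide paired with
the snoRNA position five nucleotides upstream of the box D start is the one
that gets 2'-O-methylated (the "D+5" rule).

Index convention used throughout (worked example): for an ASE of length L
ending at box start d, ASE offsets run [d-L, d). Pairing is antiparallel and
ungapped, so the ASE's 3'-most nucleotide (offset d-1) pairs the 5'-most base
of the target window [t, t+L); offset d-1-k pairs t+k; hence the guide
nucleotide d-5 pairs t+4, and a perfect guide places the Nm site at the fifth
base of the target window. With L=12 and t=1000 the predicted site is 1004.

Duplex scoring is a simplified additive scheme (Watson-Crick +2, G:U wobble
+1, mismatch -2) designed for ranking candidate guides and enforcing the
canonical geometry; scores are unitless and are not folding energies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import to_rna

BOX_C_PATTERN = re.compile("(?=([AG]UGAUGA))")
BOX_D_PATTERN = re.compile("(?=(CUGA))")

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
SCORE_WC = 2
SCORE_GU = 1
SCORE_MISMATCH = -2

MIN_ASE_LENGTH = 10
MAX_ASE_LENGTH = 15


@dataclass(frozen=True)
class BoxMotif:
    kind: str  # C | Cprime | D | Dprime
    start: int  # 0-based offset in the snoRNA
    seq: str


@dataclass(frozen=True)
class AntisenseElement:
    box_kind: str  # D | Dprime (the box this ASE abuts)
    start: int
    end: int  # == box start
    seq: str


@dataclass
class SnoRNAModel:
    """A snoRNA sequence with located boxes and antisense elements.

    ``target`` records the (contig, pos, strand) a designed snoRNA was built
    against (None for natural sequences); ``family`` groups paralogs
    (e.g. SNORD116) for family-restricted target assignment.
    """

    id: str
    seq: str  # RNA alphabet, 5'->3'
    boxes: List[BoxMotif] = field(default_factory=list)
    ases: List[AntisenseElement] = field(default_factory=list)
    target: Optional[Tuple[str, int, str]] = None
    family: Optional[str] = None

    def box(self, kind: str) -> Optional[BoxMotif]:
        for b in self.boxes:
            if b.kind == kind:
                return b
        return None


def snorna_family(snorna_id: str) -> str:
    """Family prefix of a snoRNA id: 'SNORD116-7' -> 'SNORD116'."""
    return snorna_id.split("-")[0].split("_")[0]


def find_boxes(seq: str) -> List[BoxMotif]:
    """Locate box C/D motifs and assign the canonical architecture.

    The 5'-most RUGAUGA is box C and the 3'-most CUGA box D; the 5'-most
    internal CUGA (between C and D) is the D' candidate and an RUGAUGA
    following it the C' candidate, matching the C...D'...C'...D layout.
    Returns an empty list (with a diagnostic warning) when no C or no D can
    be assigned in the right order. T is read as U.
    """
    s = to_rna(seq)
    if len(s) < 20:
        raise ValueError("sequence too short to be a box C/D snoRNA (< 20 nt)")
    c_hits = [m.start() for m in BOX_C_PATTERN.finditer(s)]
    d_hits = [m.start() for m in BOX_D_PATTERN.finditer(s)]
    if not c_hits or not d_hits:
        warnings.warn("no box C or box D motif found; no canonical assignment")
        return []
    c_start = c_hits[0]
    d_start = d_hits[-1]
    if d_start <= c_start + 7:
        warnings.warn("box D does not lie 3' of box C; no canonical assignment")
        return []
    boxes = [
        BoxMotif("C", c_start, s[c_start : c_start + 7]),
        BoxMotif("D", d_start, s[d_start : d_start + 4]),
    ]
    internal_d = [p for p in d_hits if c_start + 7 <= p and p + 4 <= d_start]
    if internal_d:
        dp = internal_d[0]
        boxes.append(BoxMotif("Dprime", dp, s[dp : dp + 4]))
        internal_c = [p for p in c_hits if dp + 4 <= p and p + 7 <= d_start]
        if internal_c:
            cp = internal_c[0]
            boxes.append(BoxMotif("Cprime", cp, s[cp : cp + 7]))
    return sorted(boxes, key=lambda b: b.start)


def extract_ases(model: SnoRNAModel, ase_length: int = 12) -> SnoRNAModel:
    """Attach the antisense element(s): the ``ase_length`` nucleotides ending
    at the start of box D (and D' if present), truncated at the snoRNA 5' end
    down to a minimum of 10 nt; boxes closer than 10 nt to the 5' end get no
    ASE."""
    if not (MIN_ASE_LENGTH <= ase_length <= MAX_ASE_LENGTH):
        raise ValueError(f"ase_length must be in [{MIN_ASE_LENGTH}, {MAX_ASE_LENGTH}]")
    if not model.boxes:
        raise ValueError("boxes not assigned; run find_boxes first")
    s = to_rna(model.seq)
    ases = []
    for kind in ("D", "Dprime"):
        box = model.box(kind)
        if box is None:
            continue
        start = max(0, box.start - ase_length)
        if box.start - start < MIN_ASE_LENGTH:
            continue
        ases.append(AntisenseElement(kind, start, box.start, s[start : box.start]))
    model.ases = ases
    return model


@dataclass
class DuplexResult:
    """An ungapped antiparallel alignment of two equal-length sequences.

    ``pairing`` maps guide index i to target index L-1-i for the positions
    that actually pair (Watson-Crick or G:U); mismatched positions are absent.
    """

    pairing: Dict[int, int]
    n_pairs: int
    n_gu_pairs: int
    n_mismatches: int
    score: int


def duplex_score(ase_seq: str, target_seq: str) -> DuplexResult:
    """Score an antiparallel ungapped duplex between two equal-length windows
    (both given 5'->3'): WC pair +2, G:U wobble +1, anything else -2."""
    a = to_rna(ase_seq)
    t = to_rna(target_seq)
    if len(a) != len(t):
        raise ValueError("duplex windows must have equal length")
    L = len(a)
    pairing: Dict[int, int] = {}
    n_gu = n_mm = score = 0
    for i in range(L):
        pair = (a[i], t[L - 1 - i])
        if pair in WC_PAIRS:
            pairing[i] = L - 1 - i
            score += SCORE_WC
        elif pair in GU_PAIRS:
            pairing[i] = L - 1 - i
            n_gu += 1
            score += SCORE_GU
        else:
            n_mm += 1
            score += SCORE_MISMATCH
    return DuplexResult(pairing, len(pairing), n_gu, n_mm, score)


@dataclass
class GuideMatch:
    snorna_id: str
    ase_kind: str  # D | Dprime
    contig: str
    strand: str
    target_start: int  # genomic, half-open interval of the paired window
    target_end: int
    pairing: Dict[int, int]  # snoRNA offset -> target genomic position
    n_pairs: int
    n_gu_pairs: int
    n_mismatches: int
    duplex_score: int
    predicted_nm_pos: Optional[int]
    observed_pos: Optional[int] = None


def predict_nm_position(match: GuideMatch, box_start: int) -> Optional[int]:
    """The target position paired with snoRNA offset box_start - 5 (D+5 rule),
    or None when that offset is not part of the pairing."""
    return match.pairing.get(box_start - 5)


def _sense_context(
    sequence: str, pos: int, strand: str, up: int, down: int
) -> Optional[Tuple[str, List[int]]]:
    """Sequence read in transcript orientation around ``pos`` with ``up`` nt
    5' and ``down`` nt 3' of it, plus the genomic position of each base.
    None when the window runs off the contig."""
    from ._util import revcomp

    if strand == "+":
        lo, hi = pos - up, pos + down + 1
        if lo < 0 or hi > len(sequence):
            return None
        return sequence[lo:hi].upper(), list(range(lo, hi))
    lo, hi = pos - down, pos + up + 1
    if lo < 0 or hi > len(sequence):
        return None
    return revcomp(sequence[lo:hi]).upper(), list(range(hi - 1, lo - 1, -1))


def scan_targets(
    snornas: Iterable[SnoRNAModel],
    nm_sites: Sequence,
    reference,
    window: int = 7,
    min_pairs: int = 9,
    max_mismatches: int = 2,
) -> List[GuideMatch]:
    """Find canonical guide matches between snoRNA ASEs and Nm site regions.

    Each ASE slides (ungapped, antiparallel) over the +-``window`` nt region
    around every site; a placement qualifies when it has at least
    ``min_pairs`` paired positions, at most ``max_mismatches`` mismatches,
    and the D+5 rule puts the predicted Nm exactly at the observed site.
    Matches are returned sorted by duplex score, descending.
    """
    snornas = list(snornas)
    matches: List[GuideMatch] = []
    for site in nm_sites:
        contig_seq = reference.contigs.get(site.contig)
        if contig_seq is None:
            warnings.warn(f"contig {site.contig} not in reference; site skipped")
            continue
        max_ase = max(
            (a.end - a.start for m in snornas for a in m.ases), default=0
        )
        if max_ase == 0:
            continue
        ctx = _sense_context(
            contig_seq, site.pos, site.strand, up=window + 4, down=window + max_ase
        )
        if ctx is None:
            warnings.warn(
                f"site {site.contig}:{site.pos} too close to contig edge; skipped"
            )
            continue
        sense, genomic = ctx
        center = window + 4  # sense index of the site itself
        for model in snornas:
            for ase in model.ases:
                L = ase.end - ase.start
                d = ase.end  # box start in snoRNA offsets
                for s in range(center - 4 - window, center - 4 + window + 1):
                    if s < 0 or s + L > len(sense):
                        continue
                    target_window = sense[s : s + L]
                    if "N" in target_window:
                        continue
                    res = duplex_score(ase.seq, target_window)
                    if res.n_pairs < min_pairs or res.n_mismatches > max_mismatches:
                        continue
                    # lift pairing to snoRNA offsets and genomic positions
                    pairing = {
                        ase.start + i: genomic[s + j] for i, j in res.pairing.items()
                    }
                    m = GuideMatch(
                        snorna_id=model.id,
                        ase_kind=ase.box_kind,
                        contig=site.contig,
                        strand=site.strand,
                        target_start=min(genomic[s], genomic[s + L - 1]),
                        target_end=max(genomic[s], genomic[s + L - 1]) + 1,
                        pairing=pairing,
                        n_pairs=res.n_pairs,
                        n_gu_pairs=res.n_gu_pairs,
                        n_mismatches=res.n_mismatches,
                        duplex_score=res.score,
                        predicted_nm_pos=None,
                        observed_pos=site.pos,
                    )
                    m.predicted_nm_pos = predict_nm_position(m, d)
                    if m.predicted_nm_pos == site.pos:
                        matches.append(m)
    matches.sort(key=lambda m: (-m.duplex_score, m.snorna_id, m.contig, m.observed_pos))
    return matches


def _pair_score_matrix(a: str, b: str) -> np.ndarray:
    """score[i, j] for pairing a[i] with b[j] under the additive scheme."""
    lut = {}
    for x in "ACGUN":
        for y in "ACGUN":
            if (x, y) in WC_PAIRS:
                lut[(x, y)] = SCORE_WC
            elif (x, y) in GU_PAIRS:
                lut[(x, y)] = SCORE_GU
            else:
                lut[(x, y)] = SCORE_MISMATCH
    return np.array([[lut[(x, y)] for y in b] for x in a], dtype=np.int64)


def _best_run(scores: np.ndarray, min_len: int) -> Optional[int]:
    """Maximum sum over contiguous runs of length >= min_len, or None."""
    n = len(scores)
    if n < min_len:
        return None
    pref = np.concatenate([[0], np.cumsum(scores)])
    best = None
    min_pref = pref[0]
    for e in range(min_len, n + 1):
        min_pref = min(min_pref, pref[e - min_len])
        cand = pref[e] - min_pref
        if best is None or cand > best:
            best = cand
    return int(best)


def best_duplex_anywhere(sno_seq: str, region_seq: str, min_len: int = 8) -> Optional[int]:
    """Best additive duplex score over all ungapped antiparallel placements of
    any snoRNA subsequence of length >= ``min_len`` against the region.

    Antiparallel ungapped alignments pair snoRNA index i with region index j
    along anti-diagonals i + j = const, so the search reduces to a best
    minimum-length run per anti-diagonal.
    """
    a = to_rna(sno_seq)
    b = to_rna(region_seq)
    if "N" in b or len(b) < min_len or len(a) < min_len:
        return None
    mat = _pair_score_matrix(a, b)
    best = None
    S, R = len(a), len(b)
    for t in range(S + R - 1):
        i_lo = max(0, t - R + 1)
        i_hi = min(S - 1, t)
        diag = mat[np.arange(i_lo, i_hi + 1), t - np.arange(i_lo, i_hi + 1)]
        cand = _best_run(diag, min_len)
        if cand is not None and (best is None or cand > best):
            best = cand
    return best


def mfe_windows(
    snornas: Iterable[SnoRNAModel],
    nm_sites: Sequence,
    reference,
    window: int = 7,
    min_len: int = 8,
) -> pd.DataFrame:
    """Best duplex score of each snoRNA against each site's +-window region,
    with no canonical-offset requirement (supports ranking noncanonical
    guides such as U3/U8/U13 per site). Regions containing N, or sites too
    close to a contig edge, yield NaN."""
    rows = []
    for site in nm_sites:
        contig_seq = reference.contigs.get(site.contig)
        ctx = (
            _sense_context(contig_seq, site.pos, site.strand, window, window)
            if contig_seq is not None
            else None
        )
        region = ctx[0] if ctx is not None else None
        for model in snornas:
            score = (
                best_duplex_anywhere(model.seq, region, min_len)
                if region is not None
                else None
            )
            rows.append(
                {
                    "snorna_id": model.id,
                    "contig": site.contig,
                    "pos": site.pos,
                    "strand": site.strand,
                    "best_score": float("nan") if score is None else score,
                }
            )
    return pd.DataFrame(rows, columns=["snorna_id", "contig", "pos", "strand", "best_score"])


def shuffled_ase_decoy(
    model: SnoRNAModel, rng: np.random.Generator, suffix: str = "decoy"
) -> SnoRNAModel:
    """A decoy snoRNA: same boxes, ASE nucleotides randomly permuted.

    Used to estimate the false-hit rate of the canonical guide scan. The
    decoy keeps the original ASE interval, so box annotation is inherited
    rather than recomputed.
    """
    if not model.ases:
        raise ValueError("model has no ASE to shuffle")
    seq = list(to_rna(model.seq))
    ases = []
    for ase in model.ases:
        piece = seq[ase.start : ase.end]
        rng.shuffle(piece)
        seq[ase.start : ase.end] = piece
        ases.append(
            AntisenseElement(ase.box_kind, ase.start, ase.end, "".join(piece))
        )
    return SnoRNAModel(
        id=f"{model.id}-{suffix}",
        seq="".join(seq),
        boxes=list(model.boxes),
        ases=ases,
        target=None,
        family=model.family,
    )
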