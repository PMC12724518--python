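"""Transcript-region annotation of Nm sites, metagene summaries and CLASH overlap.

Called 2'-O-methylation sites are assigned to the 5'UTR / CDS / 3'UTR of the
transcript they fall in, summarised on a metagene axis (one unit per region,
so coordinates live in [0, 3)), and optionally intersected with CLASH chimera
fragments that report direct snoRNA-mRNA contacts.

All genomic coordinates are 0-based, half-open (BED convention). GTF input is
1-based inclusive and converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

REGIONS = ("5UTR", "CDS", "3UTR")
N_BINS_PER_REGION = 30


@dataclass
class TranscriptModel:
    """One transcript: sorted exon blocks plus an optional CDS interval.

    UTR segments are derived in transcript orientation: the 5'UTR is the
    transcript sequence upstream of the CDS start codon, which lies on the
    *right* genomic side for minus-strand transcripts.
    """

    id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ValueError(f"{self.id}: empty or inverted exon block ({a},{b})")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise ValueError(f"{self.id}: overlapping exon blocks")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        if self.cds is not None:
            c0, c1 = self.cds
            if not (self.exons[0][0] <= c0 < c1 <= self.exons[-1][1]):
                raise ValueError(f"{self.id}: CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Transcript-orientation offset of a genomic position, or None if intronic."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                plus_off = off + (pos - a)
                if self.strand == "+":
                    return plus_off
                return self.length - 1 - plus_off
            off += b - a
        return None

    def segment_lengths(self) -> tuple[int, int, int]:
        """(len 5'UTR, len CDS, len 3'UTR) in transcript coordinates; (0, 0, 0)-like
        for noncoding transcripts (CDS length 0 means noncoding here)."""
        if self.cds is None:
            return (0, 0, 0)
        c0, c1 = self.cds
        cds_len = 0
        left_len = 0  # exonic length genomically left of CDS
        for a, b in self.exons:
            cds_len += max(0, min(b, c1) - max(a, c0))
            left_len += max(0, min(b, c0) - a)
        right_len = self.length - cds_len - left_len
        if self.strand == "+":
            return (left_len, cds_len, right_len)
        return (right_len, cds_len, left_len)

    @property
    def cds_length(self) -> int:
        return self.segment_lengths()[1]


@dataclass
class RegionAssignment:
    site: object
    region: str  # 5UTR | CDS | 3UTR | noncoding_exon | unassigned
    transcript_id: Optional[str] = None
    metagene_coord: Optional[float] = None


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def load_annotation(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF (exon + CDS features) or BED12 file.

    Format is inferred from the extension (.bed/.bed12 → BED12, else GTF).
    Transcripts whose CDS falls outside their exons are skipped with a warning.
    """
    if str(path).endswith((".bed", ".bed12")):
        return _load_bed12(path)
    return _load_gtf(path)


def _load_gtf(path: str) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            tid = _parse_gtf_attributes(attr).get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: missing transcript_id")
            rec = exons.setdefault(
                tid, {"contig": contig, "strand": strand, "exons": [], "cds": []}
            )
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            rec["exons" if feature == "exon" else "cds"].append(iv)
    out = []
    for tid, rec in exons.items():
        cds = None
        if rec["cds"]:
            cds = (min(a for a, _ in rec["cds"]), max(b for _, b in rec["cds"]))
        try:
            out.append(
                TranscriptModel(tid, rec["contig"], rec["strand"], rec["exons"], cds)
            )
        except ValueError as exc:
            warnings.warn(f"skipping transcript {tid}: {exc}")
    return out


def _load_bed12(path: str) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, _end, name, _score, strand = f[:6]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            s = int(start)
            blocks = [(s + off, s + off + ln) for off, ln in zip(starts, sizes)]
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            try:
                out.append(TranscriptModel(name, chrom, strand, blocks, cds))
            except ValueError as exc:
                warnings.warn(f"skipping transcript {name}: {exc}")
    return out


def assign_region(site, transcripts: Sequence[TranscriptModel]) -> RegionAssignment:
    """Map one site (anything with .contig/.pos/.strand) to a transcript region.

    Among transcripts overlapping the site on the same strand, the one with the
    longest CDS wins; intronic or intergenic positions are unassigned. The
    metagene coordinate is region index + fractional position within the
    region, hence lives in [0,1) for 5'UTR, [1,2) for CDS, [2,3) for 3'UTR.
    """
    best: Optional[tuple[int, TranscriptModel, int]] = None
    for tx in transcripts:
        if tx.contig != site.contig or tx.strand != site.strand:
            continue
        tpos = tx.genomic_to_transcript(site.pos)
        if tpos is None:
            continue
        key = tx.cds_length
        if best is None or key > best[0]:
            best = (key, tx, tpos)
    if best is None:
        return RegionAssignment(site, "unassigned")
    _, tx, tpos = best
    if tx.cds is None:
        return RegionAssignment(site, "noncoding_exon", tx.id, None)
    u5, cds, u3 = tx.segment_lengths()
    if tpos < u5:
        region, idx, frac = "5UTR", 0, tpos / u5
    elif tpos < u5 + cds:
        region, idx, frac = "CDS", 1, (tpos - u5) / cds
    else:
        region, idx, frac = "3UTR", 2, (tpos - u5 - cds) / u3
    return RegionAssignment(site, region, tx.id, idx + frac)


def metagene_summary(assignments: Iterable[RegionAssignment]) -> dict:
    """Region proportions and a binned metagene density.

    Proportions are over sites assigned to 5'UTR/CDS/3'UTR (summing to 1);
    noncoding and unassigned sites are counted separately. The density uses
    30 bins per region over the [0,3) metagene axis.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments supplied")
    counts = {r: 0 for r in REGIONS}
    n_noncoding = n_unassigned = 0
    coords = []
    for a in assignments:
        if a.region in counts:
            counts[a.region] += 1
            coords.append(a.metagene_coord)
        elif a.region == "noncoding_exon":
            n_noncoding += 1
        else:
            n_unassigned += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sites assigned to mRNA regions")
    nbins = 3 * N_BINS_PER_REGION
    density = [0] * nbins
    for c in coords:
        density[min(int(c * N_BINS_PER_REGION), nbins - 1)] += 1
    return {
        "proportions": {r: counts[r] / total for r in REGIONS},
        "counts": counts,
        "n_noncoding": n_noncoding,
        "n_unassigned": n_unassigned,
        "bin_width": 1.0 / N_BINS_PER_REGION,
        "density": density,
    }


@dataclass
class ClashFragment:
    """One chimera-derived genomic fragment tagged with its snoRNA of origin."""

    contig: str
    start: int
    end: int
    snorna_id: str
    strand: str = "."


def read_clash_bed(path: str) -> list[ClashFragment]:
    """BED of chimera fragments; column 4 (name) carries the snoRNA id."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer interval") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            strand = f[5] if len(f) >= 6 else "."
            out.append(ClashFragment(f[0], start, end, f[3], strand))
    return out


def intersect_clash(
    sites: Sequence,
    chimera_bed: Union[str, Iterable[ClashFragment]],
    require_strand: bool = False,
) -> pd.DataFrame:
    """Overlap sites with CLASH chimera fragments (half-open intervals).

    A site at position p overlaps a fragment [start, end) iff start <= p < end
    on the same contig. Strand is ignored by default (chimera strand
    conventions vary between pipelines); pass ``require_strand=True`` to
    enforce the match. One output row per (site, fragment) pair.
    """
    frags = read_clash_bed(chimera_bed) if isinstance(chimera_bed, str) else list(chimera_bed)
    trees: dict[str, IntervalTree] = {}
    for fr in frags:
        if fr.end == fr.start:
            continue
        trees.setdefault(fr.contig, IntervalTree()).addi(fr.start, fr.end, fr)
    rows = []
    for site in sites:
        tree = trees.get(site.contig)
        if tree is None:
            continue
        for iv in sorted(tree.at(site.pos)):
            fr = iv.data
            if require_strand and fr.strand in "+-" and fr.strand != site.strand:
                continue
            rows.append(
                {
                    "contig": site.contig,
                    "pos": site.pos,
                    "strand": site.strand,
                    "fragment_start": fr.start,
                    "fragment_end": fr.end,
                    "snorna_id": fr.snorna_id,
                    "fragment_strand": fr.strand,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "strand",
            "fragment_start", "fragment_end", "snorna_id", "fragment_strand",
        ],
    )
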