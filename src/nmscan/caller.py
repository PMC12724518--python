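"""Nm site calling from aligned 3'-end records.

In RibOxi-style libraries, iterative periodate oxidation removes unmethylated
3'-terminal nucleotides so that only fragments ending on a 2'-O-methylated
(Nm) ribose can be ligated and sequenced. After UMI deduplication, Nm sites
therefore appear as sharp single-nucleotide pile-ups of read 3' ends.

The pipeline is: filter_records -> dedupe_umis -> end3_coverage -> call_sites.
The Nm score normalizes the deduplicated 3'-end count to counts per 2x10^7
deduplicated library reads, so scores are comparable across libraries of
different depth; calling additionally requires local enrichment over the
flanking background so that plateaus in very highly expressed transcripts are
not reported as sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

NM_SCORE_SCALE = 2e7  # score = dedup count per 2e7 deduplicated reads


@dataclass(frozen=True)
class AlignedEndRecord:
    """One aligned read observation: where its 3'-terminal transcribed base maps."""

    contig: str
    strand: str
    end3: int  # 0-based position of the 3'-terminal transcribed nucleotide
    umi: str
    read_length: int
    mean_quality: float


@dataclass
class EndCoverage:
    """Deduplicated single-nucleotide 3'-end counts, keyed by (contig, strand)."""

    counts: Dict[Tuple[str, str], Dict[int, int]] = field(default_factory=dict)
    library_size: int = 0

    def get(self, contig: str, strand: str, pos: int) -> int:
        return self.counts.get((contig, strand), {}).get(pos, 0)


@dataclass
class NmSite:
    contig: str
    pos: int
    strand: str
    dedup_count: int
    nm_score: float
    sample: str = ""


def filter_records(
    records: Iterable[AlignedEndRecord],
    min_length: int = 20,
    min_quality: float = 20,
) -> List[AlignedEndRecord]:
    """Keep reads longer than ``min_length`` nt with mean quality above
    ``min_quality`` (both strict inequalities)."""
    if min_length < 0 or min_quality < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        r
        for r in records
        if r.read_length > min_length and r.mean_quality > min_quality
    ]


def dedupe_umis(records: Iterable[AlignedEndRecord]) -> List[AlignedEndRecord]:
    """Collapse PCR duplicates: one record per (contig, strand, end3, UMI) key.

    Exact-match collapse only; the first record in input order is retained,
    so the operation is deterministic and idempotent.
    """
    seen = set()
    out = []
    for r in records:
        key = (r.contig, r.strand, r.end3, r.umi)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def end3_coverage(records: Iterable[AlignedEndRecord]) -> EndCoverage:
    """Single-nucleotide 3'-end counts per (contig, strand), plus library size."""
    cov = EndCoverage()
    n = 0
    for r in records:
        d = cov.counts.setdefault((r.contig, r.strand), {})
        d[r.end3] = d.get(r.end3, 0) + 1
        n += 1
    cov.library_size = n
    return cov


def nm_score(coverage: EndCoverage, contig: str, strand: str, pos: int) -> float:
    """Depth-normalized score: dedup count per 2x10^7 deduplicated reads,
    reported to one decimal. Positions with no records score 0."""
    count = coverage.get(contig, strand, pos)
    if count == 0:
        return 0.0
    if coverage.library_size == 0:
        raise ValueError("library_size is 0")
    return round(count * (NM_SCORE_SCALE / coverage.library_size), 1)


def _flank_median(counts: Dict[int, int], pos: int, flank: int) -> float:
    window = [counts.get(p, 0) for p in range(pos - flank, pos + flank + 1) if p != pos]
    window.sort()
    n = len(window)
    mid = n // 2
    return window[mid] if n % 2 else (window[mid - 1] + window[mid]) / 2


def call_sites(
    coverage: EndCoverage,
    score_threshold: float = 500,
    enrichment_fold: float = 10,
    flank: int = 50,
    sample: str = "",
) -> List[NmSite]:
    """Call Nm sites: positions whose Nm score reaches ``score_threshold`` and
    whose dedup count is at least ``enrichment_fold`` times the median count
    over the +-``flank`` nt window (absent positions count 0; a zero median is
    treated as 1 for the ratio). Output sorted by (contig, pos)."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    sites = []
    for (contig, strand), counts in coverage.counts.items():
        for pos, count in counts.items():
            score = nm_score(coverage, contig, strand, pos)
            if score < score_threshold:
                continue
            med = _flank_median(counts, pos, flank)
            if count >= enrichment_fold * max(med, 1):
                sites.append(NmSite(contig, pos, strand, count, score, sample))
    sites.sort(key=lambda s: (s.contig, s.pos, s.strand))
    return sites


def top_k(sites: List[NmSite], k: int = 500) -> List[NmSite]:
    """The k highest-scoring sites; ties at the boundary break by (contig, pos)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sites):
        warnings.warn(f"requested top {k} of {len(sites)} sites; returning all")
        k = len(sites)
    ranked = sorted(sites, key=lambda s: (-s.nm_score, s.contig, s.pos, s.strand))
    return ranked[:k]
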