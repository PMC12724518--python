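"""Readers and writers for the pipeline's on-disk formats.

Everything on disk is plain text in standard genomics formats: FASTA
(reference, snoRNAs), GTF (annotation), BED6 (aligned 3'-end records, called
sites), bedGraph (end profiles, coverage) and TSV (truth tables, scores).
All interval output is 0-based half-open; GTF is written 1-based inclusive
as the format requires.

Aligned records are stored as the read's genomic span, so the 3'-end
position and the read length both survive a round trip: on the + strand the
3' end is span end - 1, on the - strand it is the span start. The BED name
column carries the UMI and the score column the mean base quality.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
import tempfile
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import AlignedEndRecord, EndCoverage, NmSite
from .guide import SnoRNAModel, extract_ases, find_boxes
from .metagene import TranscriptModel
from .methscore import EndProfile
from .simulate import TruthSet, TruthSite


def _open_text(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def atomic_write(path: str, write_fn) -> None:
    """Write via a temp file in the target directory, then rename, so a
    failure never leaves a partial file behind."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- FASTA ------------------------------------------------------------------

def write_fasta(contigs: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_snornas_fasta(snornas: Iterable[SnoRNAModel], path: str) -> None:
    records = [SeqRecord(Seq(m.seq), id=m.id, description="") for m in snornas]
    SeqIO.write(records, path, "fasta")


def read_snornas_fasta(path: str, ase_length: int = 12) -> List[SnoRNAModel]:
    """Load snoRNAs (T or U accepted) and annotate boxes and ASEs."""
    from .guide import snorna_family

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        model = SnoRNAModel(id=rec.id, seq=str(rec.seq).upper().replace("T", "U"))
        model.family = snorna_family(rec.id)
        model.boxes = find_boxes(model.seq)
        if model.boxes:
            extract_ases(model, ase_length)
        out.append(model)
    return out


# -- GTF --------------------------------------------------------------------

def write_gtf(annotation: Sequence[TranscriptModel], path: str) -> None:
    def emit(fh):
        for tx in annotation:
            attrs = f'gene_id "{tx.id}"; transcript_id "{tx.id}";'
            for a, b in tx.exons:
                fh.write(
                    f"{tx.contig}\tnmscan\texon\t{a + 1}\t{b}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds is not None:
                c0, c1 = tx.cds
                fh.write(
                    f"{tx.contig}\tnmscan\tCDS\t{c0 + 1}\t{c1}\t.\t{tx.strand}\t.\t{attrs}\n"
                )

    atomic_write(path, emit)


# -- aligned 3'-end records (BED6) ------------------------------------------

def write_records_bed(records: Iterable[AlignedEndRecord], path: str) -> None:
    """BED6 of read spans: name = UMI, score = mean base quality. Supports a
    .gz suffix for gzip output."""
    with _open_text(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                start, end = r.end3 - r.read_length + 1, r.end3 + 1
            else:
                start, end = r.end3, r.end3 + r.read_length
            fh.write(
                f"{r.contig}\t{start}\t{end}\t{r.umi}\t{r.mean_quality}\t{r.strand}\n"
            )


def read_records_bed(path: str) -> List[AlignedEndRecord]:
    out = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
                qual = float(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED fields") from exc
            strand = f[5]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            end3 = end - 1 if strand == "+" else start
            out.append(
                AlignedEndRecord(f[0], strand, end3, f[3], end - start, qual)
            )
    return out


# -- truth table ------------------------------------------------------------

TRUTH_COLUMNS = ["contig", "pos", "strand", "fraction", "dependency", "guide", "tandem", "cell"]


def write_truth_tsv(truth: TruthSet, path: str) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "strand": s.strand,
            "fraction": s.fraction,
            "dependency": s.dependency,
            "guide": s.guide_snorna or "",
            "tandem": int(s.tandem),
            "cell": s.cell or "",
        }
        for s in truth.sites
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_truth_tsv(
    path: str, conditions=None, expressed_snornas=None
) -> TruthSet:
    from .simulate import DEFAULT_CONDITIONS, default_expression_map

    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    sites = [
        TruthSite(
            contig=row["contig"],
            pos=int(row["pos"]),
            strand=row["strand"],
            fraction=float(row["fraction"]),
            dependency=row["dependency"],
            guide_snorna=row["guide"] or None,
            tandem=bool(int(row["tandem"])),
            cell=row["cell"] or None,
        )
        for _, row in df.iterrows()
    ]
    conditions = tuple(conditions or DEFAULT_CONDITIONS)
    if expressed_snornas is None:
        # reconstruct from guide ids using the default genotype table
        class _Stub:
            def __init__(self, sid):
                self.id = sid
                self.family = None

        guides = sorted({s.guide_snorna for s in sites if s.guide_snorna})
        expressed_snornas = default_expression_map([_Stub(g) for g in guides], conditions)
    return TruthSet(sites, conditions, expressed_snornas)


# -- called sites ------------------------------------------------------------

SITE_COLUMNS = ["contig", "pos", "strand", "dedup_count", "nm_score", "sample"]


def write_sites_tsv(sites: Iterable[NmSite], path: str) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "strand": s.strand,
            "dedup_count": s.dedup_count,
            "nm_score": s.nm_score,
            "sample": s.sample,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> List[NmSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        NmSite(
            row["contig"],
            int(row["pos"]),
            row["strand"],
            int(row["dedup_count"]),
            float(row["nm_score"]),
            str(row["sample"]),
        )
        for _, row in df.iterrows()
    ]


def write_sites_bed(sites: Iterable[NmSite], path: str) -> None:
    """BED6 of called sites; the BED score column is the Nm score clamped to
    the format's integer [0, 1000] range (full precision lives in the TSV)."""
    def emit(fh):
        for s in sites:
            score = int(min(1000, max(0, round(s.nm_score))))
            name = s.sample or "site"
            fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{name}\t{score}\t{s.strand}\n")

    atomic_write(path, emit)


# -- bedGraph ----------------------------------------------------------------

def write_bedgraph(values: Dict[int, float], contig: str, path: str) -> None:
    """Sparse per-position values as single-base bedGraph intervals."""
    def emit(fh):
        for pos in sorted(values):
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{values[pos]}\n")

    atomic_write(path, emit)


def read_bedgraph(path: str) -> Dict[str, Dict[int, float]]:
    """Per-contig position -> value maps; multi-base intervals are expanded."""
    out: Dict[str, Dict[int, float]] = {}
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            start, end, value = int(f[1]), int(f[2]), float(f[3])
            d = out.setdefault(f[0], {})
            for pos in range(start, end):
                d[pos] = value
    return out


def write_profile(profile: EndProfile, path5: str, path3: str) -> None:
    write_bedgraph({k: float(v) for k, v in profile.ends5.items()}, profile.contig, path5)
    write_bedgraph({k: float(v) for k, v in profile.ends3.items()}, profile.contig, path3)


def read_profile(
    path5: str,
    path3: str,
    contig: str,
    strand: str = "+",
    replicate_id: str = "rep1",
    contig_length: Optional[int] = None,
) -> EndProfile:
    ends5 = read_bedgraph(path5).get(contig, {})
    ends3 = read_bedgraph(path3).get(contig, {})
    return EndProfile(
        contig,
        strand,
        {k: int(v) for k, v in ends5.items()},
        {k: int(v) for k, v in ends3.items()},
        replicate_id,
        contig_length,
    )


def write_coverage_bedgraph(coverage: EndCoverage, contig: str, strand: str, path: str) -> None:
    counts = coverage.counts.get((contig, strand), {})
    write_bedgraph({k: float(v) for k, v in counts.items()}, contig, path)


# -- manifest ----------------------------------------------------------------

def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: Sequence[str], path: str) -> None:
    manifest = {os.path.basename(p): file_checksum(p) for p in sorted(paths)}
    atomic_write(path, lambda fh: json.dump(manifest, fh, indent=2, sort_keys=True))


def write_methscore_bedgraph(track: pd.DataFrame, path: str) -> None:
    """Mean MethScore per position as single-base bedGraph intervals."""
    def emit(fh):
        for _, row in track.sort_values(["contig", "pos"]).iterrows():
            fh.write(
                f"{row.contig}\t{int(row.pos)}\t{int(row.pos) + 1}\t"
                f"{round(float(row.methscore_mean), 4)}\n"
            )

    atomic_write(path, emit)


def write_matches_bed12(matches: Iterable, path: str) -> None:
    """Guide matches as BED12-like blocks for browser display: the paired
    target window is the block, the thick interval marks the predicted Nm
    position, and the score column carries the duplex score clamped to the
    BED [0, 1000] range."""
    def emit(fh):
        for m in matches:
            thick_start = m.predicted_nm_pos if m.predicted_nm_pos is not None else m.target_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.contig,
                        m.target_start,
                        m.target_end,
                        f"{m.snorna_id}|{m.ase_kind}",
                        int(min(1000, max(0, m.duplex_score * 10))),
                        m.strand,
                        thick_start,
                        thick_start + 1,
                        "0,0,255",
                        1,
                        m.target_end - m.target_start,
                        0,
                    )
                )
                + "\n"
            )

    atomic_write(path, emit)
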