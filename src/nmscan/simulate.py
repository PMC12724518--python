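"""Synthetic references, designed snoRNAs, planted Nm sites and simulated signal.

The simulator emulates the statistical structure the downstream analysis
assumes, with known ground truth:

* RibOxi-style signal: RNA molecules fragment at uniform positions within
  transcripts, except that cleavage immediately 3' of a 2'-O-methylated
  nucleotide is blocked (the same ribose protection the alkaline-cleavage
  arm relies on). Iterative periodate oxidation/beta-elimination then
  removes one unmethylated 3'-terminal nucleotide per cycle (up to
  ``trim_budget`` cycles) and stops at the first 2'-O-methylated
  nucleotide, which becomes the ligated, sequenced 3' end. Molecules still
  unmethylated at the end are lost, except for a small spurious-ligation
  probability. Each surviving molecule carries a random UMI. This
  reproduces the two signature behaviours of the assay: single-nucleotide
  3'-end peaks at Nm sites, and masking of the 5'-ward (proximal) site of a
  consecutive pair whenever the 3'-ward (distal) site is methylated on that
  molecule — only the most 3' of two consecutive fully methylated sites is
  ever observed.

* RiboMeth-style signal: alkaline cleavage between n and n+1 produces a
  3' end at n and a 5' end at n+1; counts are Poisson with mean
  depth * (1 - methylated fraction at n), so methylation appears as an
  end-sum deficit.

Condition structure follows an isogenic two-cell-line design: the SNORD116
family is expressed only in the wild-type lines (CT2, H9), and the
SNORD113/114 families only in CT2; a site guided by an unexpressed snoRNA
has effective stoichiometry zero in that condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import revcomp_rna, spawn_rng
from .caller import AlignedEndRecord
from .guide import SnoRNAModel, extract_ases, find_boxes, snorna_family
from .metagene import TranscriptModel
from .methscore import EndProfile

DEFAULT_CONDITIONS = ("CT2", "CT2-smDEL", "H9", "H9-smDEL")
_BASES = np.array(list("ACGT"))
_PYRIMIDINES = np.array(list("CU"))


@dataclass
class Reference:
    """Synthetic contigs (uppercase ACGT) plus transcript annotation."""

    contigs: Dict[str, str]
    annotation: List[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name} is empty")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {name} has characters outside ACGTN")


@dataclass
class TruthSite:
    """A planted 2'-O-methylation site with its stoichiometry and dependency."""

    contig: str
    pos: int
    strand: str
    fraction: float
    dependency: str  # constitutive | SNORD113114 | SNORD116 | cell_specific
    guide_snorna: Optional[str] = None
    tandem: bool = False
    cell: Optional[str] = None  # for cell_specific sites: 'CT2' or 'H9'

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        snorna_classes = {"SNORD113114", "SNORD116"}
        if (self.dependency in snorna_classes) != (self.guide_snorna is not None):
            raise ValueError("guide_snorna must be set iff dependency is a snoRNA class")


@dataclass
class TruthSet:
    sites: List[TruthSite]
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS
    expressed_snornas: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")

    def effective_fraction(self, site: TruthSite, condition: str) -> float:
        """Site stoichiometry in one condition: zero when the guide snoRNA is
        not expressed there, or for a cell_specific site in the other line."""
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        if site.guide_snorna is not None:
            expressed = self.expressed_snornas.get(condition, set())
            return site.fraction if site.guide_snorna in expressed else 0.0
        if site.dependency == "cell_specific":
            assert site.cell is not None
            return site.fraction if condition.startswith(site.cell) else 0.0
        return site.fraction


@dataclass
class SimulationConfig:
    """Study conditions for the RibOxi simulator.

    ``depth`` is the expected number of fragmented molecules per contig and
    sample (default 700,000: with ~9 kb of transcribed span per contig and a
    trim_budget-nt capture window upstream of each site, a site at
    stoichiometry 0.5 then expects >= 150 deduplicated records).
    ``background_end_rate`` is the per-molecule probability that a fully
    trimmed, unmethylated terminus still ligates.
    """

    depth: float = 700_000
    background_end_rate: float = 1e-4
    trim_budget: int = 4
    umi_length: int = 10
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.background_end_rate < 0.01:
            raise ValueError("background_end_rate must be in [0, 0.01)")
        if self.trim_budget < 1:
            raise ValueError("trim_budget must be >= 1")


def build_reference(
    contig_lengths: Sequence[int] = (10_000,),
    transcripts_per_contig: int = 5,
    proportions: Tuple[float, float, float] = (0.05, 0.55, 0.40),
    seed: int = 0,
) -> Reference:
    """Random contigs tiled with single-exon transcripts.

    Each transcript is split into 5'UTR/CDS/3'UTR with the requested
    proportions (realised lengths within 1 nt of the exact fractions);
    strands are drawn at random. Proportions must be positive and sum to 1.
    """
    if abs(sum(proportions) - 1.0) > 1e-9 or any(p <= 0 for p in proportions):
        raise ValueError("proportions must be positive and sum to 1")
    if any(L < 1000 for L in contig_lengths):
        raise ValueError("contig lengths must be >= 1000 nt")
    rng = spawn_rng(seed, 0)
    contigs: Dict[str, str] = {}
    annotation: List[TranscriptModel] = []
    for ci, L in enumerate(contig_lengths):
        name = f"chr{ci + 1}"
        contigs[name] = "".join(_BASES[rng.integers(0, 4, L)])
        slot = L // transcripts_per_contig
        margin = max(20, slot // 20)
        for ti in range(transcripts_per_contig):
            start = ti * slot + margin
            end = (ti + 1) * slot - margin
            tlen = end - start
            strand = "+" if rng.random() < 0.5 else "-"
            u5 = int(round(proportions[0] * tlen))
            cds = int(round(proportions[1] * tlen))
            u3 = tlen - u5 - cds
            if strand == "+":
                cds_iv = (start + u5, start + u5 + cds)
            else:  # 5'UTR sits on the right genomic side
                cds_iv = (start + u3, start + u3 + cds)
            annotation.append(
                TranscriptModel(f"{name}.t{ti + 1}", name, strand, [(start, end)], cds_iv)
            )
    return Reference(contigs, annotation)


def _sense_window(contig_seq: str, pos: int, strand: str, length: int) -> str:
    """Transcript-orientation window of ``length`` nt whose fifth base (index 4)
    is the position ``pos`` — the geometry the D+5 rule pairs an ASE against."""
    if strand == "+":
        lo, hi = pos - 4, pos - 4 + length
        if lo < 0 or hi > len(contig_seq):
            raise ValueError("target window runs off the contig")
        return contig_seq[lo:hi].upper()
    hi, lo = pos + 4, pos + 4 - length
    if lo + 1 < 0 or hi + 1 > len(contig_seq):
        raise ValueError("target window runs off the contig")
    window = contig_seq[lo + 1 : hi + 1].upper()
    return window[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def design_snornas(
    reference: Reference,
    n_snornas: int,
    targets: Sequence[Tuple[str, int, str]],
    seed: int = 0,
    guide_length: int = 12,
    family: str = "SNORD000",
) -> List[SnoRNAModel]:
    """Design box C/D snoRNAs whose ASEs guide methylation of the targets.

    Each snoRNA is leader + box C (RUGAUGA) + spacer + ASE + box D (CUGA) +
    tail, with the ASE chosen as the reverse complement of the target window
    placed so that the D+5 rule maps back to the requested position. Leader,
    spacer and tail are pyrimidine-only, which guarantees the designed C and
    D boxes are the canonical (5'-most / 3'-most) motif instances. When
    ``n_snornas`` exceeds the number of targets, targets are reused in
    rotation (several paralogs guiding one site).
    """
    if not (10 <= guide_length <= 15):
        raise ValueError("guide_length must be in [10, 15]")
    if n_snornas == 0:
        return []
    if not targets:
        raise ValueError("no targets supplied")
    rng = spawn_rng(seed, 1)
    models = []
    for k in range(n_snornas):
        contig, pos, strand = targets[k % len(targets)]
        contig_seq = reference.contigs[contig]
        if not 0 <= pos < len(contig_seq):
            raise ValueError(f"target position {pos} outside contig {contig}")
        window = _sense_window(contig_seq, pos, strand, guide_length)
        if "N" in window:
            raise ValueError(f"target window at {contig}:{pos} contains N")
        ase = revcomp_rna(window.replace("T", "U"))
        leader = "".join(_PYRIMIDINES[rng.integers(0, 2, 5)])
        box_c = ("A" if rng.random() < 0.5 else "G") + "UGAUGA"
        spacer = "".join(_PYRIMIDINES[rng.integers(0, 2, 6)])
        tail = "".join(_PYRIMIDINES[rng.integers(0, 2, 5)])
        seq = leader + box_c + spacer + ase + "CUGA" + tail
        model = SnoRNAModel(id=f"{family}-{k + 1}", seq=seq, family=family)
        model.boxes = find_boxes(seq)
        extract_ases(model, ase_length=guide_length)
        model.target = (contig, pos, strand)
        assert model.box("D") is not None and model.ases, "designed snoRNA lost its boxes"
        models.append(model)
    return models


@dataclass
class TruthDesign:
    """How many sites of each dependency class to plant, and with what
    stoichiometry distribution (uniform over ``fraction_range``)."""

    n_constitutive: int = 10
    n_snord116: int = 4
    n_snord113114: int = 4
    n_cell_specific: int = 0
    fraction_range: Tuple[float, float] = (0.3, 1.0)
    tandem_pairs: int = 1
    tandem_distance: int = 1  # consecutive sites: masking of the proximal one is exact
    min_separation: int = 150

    def __post_init__(self) -> None:
        if min(self.n_constitutive, self.n_snord116, self.n_snord113114,
               self.n_cell_specific) < 0:
            raise ValueError("site counts must be >= 0")


def default_expression_map(
    snornas: Iterable[SnoRNAModel],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> Dict[str, Set[str]]:
    """Which snoRNAs each condition expresses, from the deletion genotypes:
    SNORD116 is paternally deleted in both smDEL lines; SNORD113/114 are
    expressed only in CT2; all other families are expressed everywhere."""
    out: Dict[str, Set[str]] = {c: set() for c in conditions}
    for m in snornas:
        fam = m.family or snorna_family(m.id)
        if fam == "SNORD116":
            expressed_in = [c for c in conditions if "smDEL" not in c]
        elif fam in ("SNORD113", "SNORD114"):
            expressed_in = [c for c in conditions if c == "CT2"]
        else:
            expressed_in = list(conditions)
        for c in expressed_in:
            out[c].add(m.id)
    return out


def sample_site_positions(
    reference: Reference,
    n: int,
    rng: np.random.Generator,
    min_separation: int = 150,
    margin: int = 60,
    existing: Sequence[Tuple[str, int]] = (),
) -> List[Tuple[str, int, str]]:
    """Positions inside transcript spans, pairwise separated by at least
    ``min_separation`` nt and at least ``margin`` nt from span edges."""
    spans = [
        (tx.contig, tx.start + margin, tx.end - margin, tx.strand)
        for tx in reference.annotation
        if tx.end - tx.start > 2 * margin
    ]
    if not spans:
        raise ValueError("reference has no usable transcript spans")
    lengths = np.array([e - s for _, s, e, _ in spans])
    taken = {(c, p) for c, p in existing}
    out: List[Tuple[str, int, str]] = []
    for _ in range(20000):
        if len(out) >= n:
            break
        si = rng.choice(len(spans), p=lengths / lengths.sum())
        contig, s, e, strand = spans[si]
        pos = int(rng.integers(s, e))
        if all(c != contig or abs(pos - p) >= min_separation for c, p in taken):
            taken.add((contig, pos))
            out.append((contig, pos, strand))
    if len(out) < n:
        raise ValueError("could not place sites with the requested separation")
    return out


def plant_truth(
    reference: Reference,
    snornas: Sequence[SnoRNAModel],
    design: TruthDesign,
    seed: int = 0,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> TruthSet:
    """Plant ground-truth sites: snoRNA-dependent sites at the positions their
    designed guides target, plus constitutive and cell-specific sites at
    random transcript positions. The first two constitutive sites form a
    tandem pair (``tandem_distance`` nt apart) to exercise oxidation
    masking."""
    rng = spawn_rng(seed, 2)
    by_family: Dict[str, List[SnoRNAModel]] = {}
    for m in snornas:
        fam = m.family or snorna_family(m.id)
        by_family.setdefault(fam, []).append(m)
    guides116 = by_family.get("SNORD116", [])
    guides113114 = by_family.get("SNORD113", []) + by_family.get("SNORD114", [])
    if design.n_snord116 > len(guides116):
        raise ValueError(
            f"{design.n_snord116} SNORD116-dependent sites requested "
            f"but only {len(guides116)} SNORD116 snoRNAs designed"
        )
    if design.n_snord113114 > len(guides113114):
        raise ValueError(
            f"{design.n_snord113114} SNORD113/114-dependent sites requested "
            f"but only {len(guides113114)} SNORD113/114 snoRNAs designed"
        )

    def draw_fraction() -> float:
        lo, hi = design.fraction_range
        return float(rng.uniform(lo, hi))

    sites: List[TruthSite] = []
    for dep, guides, count in (
        ("SNORD116", guides116, design.n_snord116),
        ("SNORD113114", guides113114, design.n_snord113114),
    ):
        for m in guides[:count]:
            if m.target is None:
                raise ValueError(f"snoRNA {m.id} has no recorded target")
            contig, pos, strand = m.target
            sites.append(TruthSite(contig, pos, strand, draw_fraction(), dep, m.id))

    existing = [(s.contig, s.pos) for s in sites]
    n_free = design.n_constitutive + design.n_cell_specific
    free = sample_site_positions(
        reference, n_free, rng, design.min_separation, existing=existing
    )
    n_tandem_flag = min(design.tandem_pairs, design.n_constitutive // 2)
    for i, (contig, pos, strand) in enumerate(free[: design.n_constitutive]):
        tandem = i < 2 * n_tandem_flag
        sites.append(
            TruthSite(contig, pos, strand, draw_fraction(), "constitutive", tandem=tandem)
        )
    for j, (contig, pos, strand) in enumerate(free[design.n_constitutive :]):
        cell = "CT2" if j % 2 == 0 else "H9"
        sites.append(
            TruthSite(contig, pos, strand, draw_fraction(), "cell_specific", cell=cell)
        )
    # convert tandem placeholders into genuine adjacent pairs
    n_tandem = min(design.tandem_pairs, design.n_constitutive // 2)
    for k in range(n_tandem):
        a = design.n_snord116 + design.n_snord113114 + 2 * k
        first, second = sites[a], sites[a + 1]
        shift = design.tandem_distance if first.strand == "+" else -design.tandem_distance
        sites[a + 1] = TruthSite(
            first.contig,
            first.pos + shift,
            first.strand,
            second.fraction,
            "constitutive",
            tandem=True,
        )
    expr = default_expression_map(snornas, conditions)
    return TruthSet(sites, tuple(conditions), expr)


def _umi_strings(rng: np.random.Generator, n: int, length: int) -> List[str]:
    if n == 0:
        return []
    arr = _BASES[rng.integers(0, 4, (n, length))]
    return ["".join(row) for row in arr]


def simulate_riboxi(
    reference: Reference,
    truth: TruthSet,
    cfg: SimulationConfig,
    condition: str,
) -> List[AlignedEndRecord]:
    """Simulate one RibOxi library for one condition.

    Per contig, Poisson(depth) molecules fragment at uniform positions in the
    transcribed spans. A molecule whose cut would fall immediately 3' of a
    methylated nucleotide is discarded (methylation blocks that cleavage, so
    such a fragment never exists); otherwise the 3' terminus is trimmed one
    unmethylated nucleotide per oxidation cycle (at most ``trim_budget``
    cycles), stopping at the first methylated site, whose position is
    recorded. Fully trimmed unmethylated molecules survive only with
    probability ``background_end_rate``. Methylation states are drawn per
    molecule from the site's effective stoichiometry in this condition.
    Bit-reproducible for a fixed seed.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = truth.conditions.index(condition)
    B = cfg.trim_budget
    site_frac: Dict[Tuple[str, str], Dict[int, float]] = {}
    for s in truth.sites:
        f = truth.effective_fraction(s, condition)
        if f > 0:
            site_frac.setdefault((s.contig, s.strand), {})[s.pos] = f

    records: List[AlignedEndRecord] = []
    for ci, (contig, seq) in enumerate(reference.contigs.items()):
        rng = spawn_rng(cfg.seed, 10 + cond_idx, ci)
        spans = [
            (tx.start, tx.end, tx.strand)
            for tx in reference.annotation
            if tx.contig == contig
        ] or [(0, len(seq), "+")]
        span_len = np.array([e - s for s, e, _ in spans])
        cum = np.concatenate([[0], np.cumsum(span_len)])
        n_mol = rng.poisson(cfg.depth)
        u = rng.integers(0, cum[-1], n_mol)
        span_idx = np.searchsorted(cum, u, side="right") - 1
        pos = np.array([spans[i][0] for i in span_idx]) + (u - cum[span_idx])
        strands = np.array([spans[i][2] for i in span_idx])

        kept_pos: List[int] = []
        kept_strand: List[str] = []
        for strand in ("+", "-"):
            mask = strands == strand
            if not mask.any():
                continue
            p = pos[mask]
            fr = site_frac.get((contig, strand), {})
            sites_sorted = np.array(sorted(fr)) if fr else np.empty(0, dtype=int)
            sign = 1 if strand == "+" else -1
            final = p - sign * B
            if sites_sorted.size:
                lo = np.minimum(p, final)
                hi = np.maximum(p, final)
                i_lo = np.searchsorted(sites_sorted, lo, side="left")
                i_hi = np.searchsorted(sites_sorted, hi, side="right")
                has_site = i_hi > i_lo
            else:
                has_site = np.zeros(len(p), dtype=bool)

            # background path: no methylatable site in the trim window
            bg_p = p[~has_site]
            bg_final = bg_p - sign * B
            keep = (rng.random(len(bg_p)) < cfg.background_end_rate) & (
                (bg_final >= 0) & (bg_final < len(seq))
            )
            kept_pos.extend(int(x) for x in bg_final[keep])
            kept_strand.extend(strand for _ in range(int(keep.sum())))

            # molecules whose trim window spans at least one site
            for p0 in p[has_site]:
                q = int(p0)
                recorded = None
                for step in range(B + 1):
                    f = fr.get(q)
                    if f is not None and rng.random() < f:
                        # methylated: at the terminus itself the cut was
                        # blocked (molecule discarded); further 5' it stops
                        # the trimming and is the ligated 3' end
                        recorded = q if step > 0 else None
                        break
                    q -= sign
                else:
                    q += sign  # loop exhausted: terminus is p0 -/+ B
                    if 0 <= q < len(seq) and rng.random() < cfg.background_end_rate:
                        recorded = q
                if recorded is not None:
                    kept_pos.append(recorded)
                    kept_strand.append(strand)

        m = len(kept_pos)
        umis = _umi_strings(rng, m, cfg.umi_length)
        lengths = rng.integers(18, 81, m)
        quals = np.clip(rng.normal(34, 3, m), 2, 41)
        for i in range(m):
            records.append(
                AlignedEndRecord(
                    contig=contig,
                    strand=kept_strand[i],
                    end3=int(kept_pos[i]),
                    umi=umis[i],
                    read_length=int(lengths[i]),
                    mean_quality=float(round(quals[i], 1)),
                )
            )
    return records


def simulate_ribometh(
    reference: Reference,
    truth: TruthSet,
    depth: float = 1000,
    replicates: int = 3,
    seed: int = 0,
    condition: str = "CT2",
) -> List[EndProfile]:
    """Simulate RiboMeth-style end profiles (one EndProfile per contig, strand
    and replicate). Cleavage 3' of position n yields a 3' end at n and a 5'
    end at n+1, each Poisson with mean depth * (1 - effective fraction at n);
    replicates use distinct deterministic sub-seeds."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = truth.conditions.index(condition)
    strands_by_contig: Dict[str, Set[str]] = {c: set() for c in reference.contigs}
    for tx in reference.annotation:
        strands_by_contig[tx.contig].add(tx.strand)
    for s in truth.sites:
        strands_by_contig[s.contig].add(s.strand)
    profiles: List[EndProfile] = []
    for rep in range(replicates):
        for ci, (contig, seq) in enumerate(reference.contigs.items()):
            L = len(seq)
            for strand in sorted(strands_by_contig[contig] or {"+"}):
                rng = spawn_rng(seed, 100 + cond_idx, rep, ci, 0 if strand == "+" else 1)
                mean = np.full(L, float(depth))
                for s in truth.sites:
                    if s.contig == contig and s.strand == strand:
                        mean[s.pos] = depth * (1.0 - truth.effective_fraction(s, condition))
                ends3 = rng.poisson(mean)
                ends5_next = rng.poisson(mean)  # 5' ends at n+1 from cleavage at n
                profile = EndProfile(
                    contig=contig,
                    strand=strand,
                    ends5={n + 1: int(v) for n, v in enumerate(ends5_next) if v},
                    ends3={n: int(v) for n, v in enumerate(ends3) if v},
                    replicate_id=f"rep{rep + 1}",
                    contig_length=L,
                )
                profiles.append(profile)
    return profiles


@dataclass
class Study:
    """A fully wired synthetic study: reference, designed snoRNAs, truth."""

    reference: Reference
    snornas: List[SnoRNAModel]
    truth: TruthSet
    config: SimulationConfig


def make_study(
    seed: int = 0,
    contig_lengths: Sequence[int] = (10_000, 10_000),
    transcripts_per_contig: int = 5,
    design: Optional[TruthDesign] = None,
    config: Optional[SimulationConfig] = None,
    guide_length: int = 12,
) -> Study:
    """Build reference → choose guide targets → design snoRNA families →
    plant truth, all from one seed. This is the composition the individual
    operations assume; snoRNA-dependent sites end up exactly at the positions
    their designed guides target."""
    design = design or TruthDesign()
    config = config or SimulationConfig(seed=seed)
    reference = build_reference(
        contig_lengths, transcripts_per_contig, seed=seed
    )
    rng = spawn_rng(seed, 3)
    n_guided = design.n_snord116 + design.n_snord113114
    targets = sample_site_positions(
        reference, n_guided, rng, design.min_separation
    )
    t116 = targets[: design.n_snord116]
    t113114 = targets[design.n_snord116 :]
    n113 = (design.n_snord113114 + 1) // 2
    snornas = (
        design_snornas(reference, design.n_snord116, t116, seed, guide_length, "SNORD116")
        if design.n_snord116
        else []
    )
    if n113:
        snornas += design_snornas(
            reference, n113, t113114[:n113], seed + 1, guide_length, "SNORD113"
        )
    if design.n_snord113114 - n113:
        snornas += design_snornas(
            reference,
            design.n_snord113114 - n113,
            t113114[n113:],
            seed + 2,
            guide_length,
            "SNORD114",
        )
    truth = plant_truth(reference, snornas, design, seed)
    return Study(reference, snornas, truth, config)
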