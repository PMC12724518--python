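# Methods

This note documents the models behind `nmscan`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## 1. Generative model for RibOxi-style 3′-end libraries

Each simulated library is built per contig from `depth` expected molecules
(the realised count is Poisson). A molecule's 3′ terminus is placed
uniformly over the union of annotated transcript spans (strand taken from
the transcript). Fragment length is not modelled: every downstream statistic
depends only on 3′-end positions, and read lengths are drawn independently
(uniform 18–80 nt) purely so that the quality filter has realistic work to
do; mean base qualities are Normal(34, 3) clipped to [2, 41].

Methylation is drawn per molecule: each planted site within reach is
methylated with probability equal to its *effective* stoichiometry in the
simulated condition (zero when the guiding snoRNA is not expressed there).
Two rules then decide the molecule's fate:

1. **Cleavage protection.** A cut immediately 3′ of a methylated nucleotide
   cannot occur; molecules whose sampled terminus lands on a
   methylated-in-this-molecule site are discarded. This is the same ribose
   protection that underlies the alkaline-cleavage assay, applied
   consistently to fragmentation.
2. **Iterative trimming.** Oxidation/β-elimination removes one unmethylated
   3′-terminal nucleotide per cycle, up to `trim_budget` = 4 cycles
   (matching a protocol of an initial cycle plus three repeats, with a final
   blocking oxidation). Trimming stops at the first methylated nucleotide,
   which becomes the recorded, ligated 3′ end. A molecule still unmethylated
   after the budget ligates spuriously with probability
   `background_end_rate` (default 10⁻⁴, a flat per-molecule Bernoulli with
   no sequence bias), recorded at the fully trimmed terminus.

Consequences worth knowing:

* A site collects termini from the `trim_budget` positions strictly 3′ of
  it, each surviving with probability equal to the site's stoichiometry, so
  expected dedup counts are `depth × trim_budget × fraction / span_length`.
  The default `depth` = 700,000 molecules/contig makes this ≥ 150 for a
  half-methylated site on a ~9 kb transcribed span.
* **Tandem masking is exact for consecutive sites.** With sites at p and
  p+1 (transcript orientation) and the distal one fully methylated, no
  molecule can record the proximal site: cleavage between them is blocked
  and trimming from further 3′ stops at the distal site first. When the
  distal site is methylated at fraction f, the proximal count scales as
  (1 − f) — partially modified distal sites "leak". For planted pairs
  further apart than one nucleotide, termini landing between the sites
  record the proximal site regardless, so masking is only partial; the
  generator therefore plants its tandem pair at distance 1.
* Each record carries a uniform random UMI of `umi_length` = 10 nt; UMI
  collisions occur at their natural 4⁻¹⁰ rate and are not corrected.

## 2. Site calling

The caller is deliberately simple and fully deterministic: strict quality
filters (length > 20 nt, mean quality > 20 — both strict inequalities),
exact-key UMI deduplication on (contig, strand, 3′-end, UMI) keeping the
first record (idempotent, order-stable), per-strand single-nucleotide 3′-end
coverage, and two calling criteria:

* **Score threshold.** Nm score = dedup count × 2×10⁷ / library size,
  reported to one decimal; default threshold 500. The normalisation makes
  thresholds transferable across library depths and puts typical
  high-confidence sites in the hundreds-to-thousands range at
  tens-of-millions-read depth.
* **Local enrichment.** Count ≥ 10× the median count over the ±50 nt flank
  (absent positions count 0; a zero median is treated as 1). A bare score
  threshold would call every position of a plateau in a very highly
  expressed transcript; genuine oxidation peaks are single-nucleotide.

Strands are never merged; all coordinates are 0-based half-open in file
output, with the 3′ end defined as the last transcribed base.

## 3. MethScore

For cleavage profiles, S(n) = 3′-ends(n) + 5′-ends(n+1) counts the two read
ends created by a cut between n and n+1. Two denominator conventions are
implemented because the halved-denominator phrasing in circulation yields
−1 (not 0) for an unmethylated position:

* `paper_literal` (default): 1 − S(n)/(½·weighted flank mean), clamped to
  [0, 1]. Honors the halved form; fully cleaved positions clamp to 0.
* `mean_mode`: 1 − S(n)/(weighted flank mean). Equals the protection
  fraction under uniform cleavage, hence recovers stoichiometry directly;
  the raw scores obey raw_literal = 2·raw_mean − 1 exactly.

Weights default to uniform over the ±2 nt flank (no published weighting to
adopt). Scores are undefined (reported missing, never imputed) when the
flank extends past the contig or every flanking end sum is zero. Replicate
aggregation reports the per-position mean and sample SD (ddof = 1, NaN for
a single replicate); positions with zero own-signal but flanking signal are
scored, since full protection is exactly the interesting case. The
simulator draws both end categories independently as
Poisson(depth × (1 − fraction)), so at depth 1000 with 3 replicates the
mean-mode score recovers planted fractions to ±0.05 comfortably (observed
worst-case error ≈ 0.015).

## 4. Guide prediction

`find_boxes` assigns the 5′-most RUGAUGA as box C and the 3′-most CUGA as
box D; the 5′-most internal CUGA (and a following internal RUGAUGA) become
D′/C′ candidates, matching the C…D′…C′…D architecture. The ASE is the
`ase_length` (default 12, allowed 10–15) nucleotides ending at the box
start, truncated down to minimum 10 at the snoRNA 5′ end.

Index convention, written out once because published D+5 countings differ:
for an ASE of length L ending at box start d, paired antiparallel and
ungapped with target window [t, t+L), snoRNA offset d−1 pairs t and offset
d−1−k pairs t+k; the guide nucleotide is offset d−5, pairing t+4 — the
fifth base of the target window. The designed-snoRNA generator and the
scanner invert each other exactly under this convention (tested on 100
random designs on both strands).

Duplex scoring is a simplified additive scheme — Watson–Crick +2, G:U
wobble +1, mismatch −2, ungapped, antiparallel — chosen because the
scorer's role here is ranking and canonical filtering, not thermodynamics;
scores are unitless and must not be read as kcal/mol. Canonical matches
require ≥ 9 paired positions and ≤ 2 mismatches (configurable), and the
predicted position must equal the observed site exactly. Shuffled-ASE
decoys yield ≤ 2 false canonical matches per 100 decoys at these defaults.

For noncanonical guides (U3/U8/U13-style), `mfe_windows` reports the best
duplex score of *any* snoRNA subsequence ≥ 8 nt against the site's ±7 nt
region with no positional constraint. The search runs per anti-diagonal of
the pairing matrix as a maximum-sum run with minimum length 8, which is
exhaustive over ungapped antiparallel placements; the test suite checks it
against brute-force enumeration.

## 5. Differential classification

Presence is score ≥ 500; absence is score ≤ 50 (10% of the presence
threshold) with the band between reported as ambiguous — absence needs a
numeric rule even though visual genome-browser comparisons treat it
qualitatively. Position matching is exact single-nucleotide on matching
strand. The pattern table over (CT2, CT2-smDEL, H9, H9-smDEL) is:
PAAA → SNORD113/114 candidate, PAPA → SNORD116 candidate, PPPP → shared,
PPAA / AAPP → cell-line specific; any row containing an ambiguous cell is
unclassified rather than guessed. Assignment scans candidates only against
the class-matching snoRNA family so a deletion-dependent pattern cannot be
"explained" by an unrelated snoRNA; the best duplex score wins. Replicate
libraries are not modelled at this stage: the comparison operates on one
merged site list per condition.

## 6. Metagene and CLASH

GTF (1-based, converted on load) and BED12 transcripts are reduced to
5′UTR/CDS/3′UTR segments in transcript orientation; a site maps to the
overlapping same-strand transcript, ties resolved by longest CDS (no
standard isoform policy exists; longest-CDS is deterministic and favours
the principal product). The metagene coordinate is region index plus
fractional position, binned 30 bins/region over [0, 3). CLASH chimera
fragments intersect sites as half-open intervals, strand-agnostic by
default because fragment strand conventions differ between pipelines (a
strict flag is available); each unique genomic site is counted once.

## 7. Synthetic-study design and what passing tests do not show

The default study plants 18 sites (10 constitutive including one
consecutive tandem pair, 4 SNORD116-dependent, 4 SNORD113/114-dependent)
with stoichiometries uniform on [0.3, 1.0] and ≥ 150 nt separation, on two
10 kb contigs tiled with single-exon transcripts (5%/55%/40%
UTR5/CDS/UTR3). The genotype table expresses SNORD116 in both wild types
only and SNORD113/114 in CT2 only. The generator reproduces the signal
structure the analysis relies on — single-nucleotide peaks, stoichiometric
scaling, deletion-dependent loss, tandem masking, cleavage protection — but
not sequencing error, alignment ambiguity, PCR bias beyond duplicate UMIs,
transcript-abundance heterogeneity, or multi-isoform annotation. Passing
recovery tests therefore demonstrates correctness of the analysis logic
under the assay's idealised statistics, not performance on real libraries.

Problem sizes used by the automated checks (a few seconds in total on one
CPU): 50-site / three-contig studies at 700k molecules per contig for
caller recovery; depth-1000 three-replicate profiles for MethScore
recovery; 100 decoys for scan specificity; 10,000 records and 1,000×1,000
intervals for the brute-force oracle comparisons.

## 8. Degenerate inputs and tie-breaks

Empty record sets produce empty (not missing) outputs; a zero library size
raises rather than dividing by zero. `top_k` breaks score ties by (contig,
position) so rankings are reproducible. N-containing target windows are
skipped in duplex scanning and snoRNA design refuses them. BED/bedGraph
parsers report the offending file and line number on malformed input.
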