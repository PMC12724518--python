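"""Quantify Nm stoichiometry with MethScores from simulated cleavage profiles.

Alkaline fragmentation cleaves 3' of every unprotected nucleotide, so a
methylated position shows a deficit of read ends. The MethScore compares a
position's end sum S(n) = 3'-ends(n) + 5'-ends(n+1) with its +-2 nt flanks;
in mean mode the score estimates the methylated fraction directly.
"""

from nmscan.methscore import methscore_track
from nmscan.simulate import Reference, TruthSet, TruthSite, simulate_ribometh

reference = Reference({"chr1": "A" * 4000})
fractions = {500: 0.0, 1500: 0.3, 2500: 0.7, 3500: 1.0}
truth = TruthSet(
    [TruthSite("chr1", p, "+", f, "constitutive") for p, f in fractions.items()],
    ("CT2",), {},
)
profiles = simulate_ribometh(reference, truth, depth=1000, replicates=3,
                             seed=1, condition="CT2")
track = methscore_track(profiles, denominator_mode="mean_mode")

print(f"{'position':>8} {'planted fraction':>16} {'MethScore (mean)':>16} {'SD':>7}")
for pos, f in fractions.items():
    row = track[track.pos == pos].iloc[0]
    print(f"{pos:>8} {f:>16.2f} {row.methscore_mean:>16.3f} {row.methscore_sd:>7.3f}")

print("\nMean-mode MethScores track the planted stoichiometry to within a "
      "few hundredths at depth 1000 over three replicates.")
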