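"""Design a box C/D snoRNA against a target and recover it with the D+5 rule.

A box C/D snoRNA's antisense element (ASE) is the 10-15 nt immediately 5' of
box D (CUGA); the target nucleotide paired with the snoRNA position five
nucleotides upstream of box D is the one that gets 2'-O-methylated. This
script designs a guide for a chosen position, shows the box architecture and
then recovers the target by scanning the site's +-7 nt region.
"""

from nmscan.guide import scan_targets
from nmscan.simulate import build_reference, design_snornas


class Site:
    def __init__(self, contig, pos, strand):
        self.contig, self.pos, self.strand = contig, pos, strand


reference = build_reference((5000,), seed=2)
target = ("chr1", 2000, "+")
(model,) = design_snornas(reference, 1, [target], seed=2, family="SNORD116")

print(f"designed {model.id} ({len(model.seq)} nt) against {target[0]}:{target[1]}{target[2]}")
print(f"sequence: {model.seq}")
for box in model.boxes:
    print(f"  box {box.kind:<7} at offset {box.start:>3}: {box.seq}")
for ase in model.ases:
    print(f"  ASE ({ase.box_kind}) at [{ase.start}, {ase.end}): {ase.seq}")

matches = scan_targets([model], [Site(*target)], reference)
best = matches[0]
print(f"\nscan of the site's +-7 nt region found {len(matches)} canonical match(es); best:")
print(f"  {best.n_pairs} base pairs ({best.n_gu_pairs} G:U), "
      f"{best.n_mismatches} mismatches, duplex score {best.duplex_score}")
print(f"  predicted Nm position: {best.predicted_nm_pos} "
      f"(observed {best.observed_pos})")
d = model.box("D")
print(f"\nThe guide nucleotide is snoRNA offset {d.start} - 5 = {d.start - 5}, "
      "five nucleotides upstream of box D: its paired target base is the "
      "methylated position.")
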