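"""Metagene distribution of called sites and CLASH chimera overlap.

Assigns simulated Nm sites to 5'UTR/CDS/3'UTR of their transcripts,
summarises the metagene proportions, and intersects the sites with a small
synthetic set of CLASH chimera fragments (snoRNA-mRNA contact intervals).
"""

import numpy as np

from nmscan import caller
from nmscan.metagene import ClashFragment, assign_region, intersect_clash, metagene_summary
from nmscan.simulate import make_study, simulate_riboxi

study = make_study(seed=1)
records = simulate_riboxi(study.reference, study.truth, study.config, "CT2")
deduped = caller.dedupe_umis(caller.filter_records(records))
sites = caller.call_sites(caller.end3_coverage(deduped), sample="CT2")

assignments = [assign_region(s, study.reference.annotation) for s in sites]
summary = metagene_summary(assignments)
print("metagene proportions over", sum(summary["counts"].values()), "assigned sites:")
for region in ("5UTR", "CDS", "3UTR"):
    print(f"  {region:>5}: {summary['proportions'][region]:.2f}")
print(f"  unassigned (intergenic/intronic): {summary['n_unassigned']}")

# synthetic CLASH fragments: 40 nt windows centered on a few called sites,
# plus random decoy intervals elsewhere
rng = np.random.default_rng(1)
frags = [
    ClashFragment(s.contig, s.pos - 20, s.pos + 20, "U3")
    for s in sites[:3]
] + [
    ClashFragment("chr1", int(p := rng.integers(0, 9000)), int(p + 40), "U8")
    for _ in range(5)
]
overlaps = intersect_clash(sites, frags)
print(f"\n{len(overlaps)} site/fragment overlaps:")
print(overlaps.to_string(index=False))
print("\nSites falling inside a chimera fragment are candidate targets of "
      "that fragment's snoRNA.")
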