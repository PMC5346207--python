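"""Place a marker on a template by in-silico PCR and by flank search.

Shows the three-round mismatch escalation (0, 1, 3 substitutions per
primer) and the identity threshold of the flank route.
"""

import numpy as np

from scaffmap.markers import epcr_place, place_by_flank
from scaffmap.seqio import revcomp

rng = np.random.default_rng(0)
template = "".join(rng.choice(list("ACGT"), size=5_000))

# a primer pair around position 2,000 with a 200 bp product
fwd = template[2_000:2_020]
rev = revcomp(template[2_180:2_200])
hits = epcr_place(fwd, rev, {"scaf1": template}, max_mismatches=0)
print("exact primers, round N=0:", [(h.start, h.end, h.strand) for h in hits])

# one substitution in the forward primer: invisible at N=0, found at N=1
mutated = fwd[:9] + ("A" if fwd[9] != "A" else "C") + fwd[10:]
print("mutated primer at N=0:", epcr_place(mutated, rev, {"scaf1": template}, 0))
print(
    "mutated primer at N=1:",
    [(h.start, h.end) for h in epcr_place(mutated, rev, {"scaf1": template}, 1)],
)

# flank route: 150 bp of flanking sequence, reverse-complemented
flank = revcomp(template[3_000:3_150])
(hit,) = place_by_flank(flank, {"scaf1": template})
print(f"flank hit: [{hit.start}, {hit.end}) strand {hit.strand}")
# The product coordinates are 0-based half-open on the scaffold; strand '-'
# means the marker's flank matches the reverse strand at that locus.
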