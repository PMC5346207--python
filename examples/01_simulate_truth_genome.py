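"""Build a small truth genome and inspect its recombination landscape.

Generates two ~150 kb chromosomes with a centromeric recombination
plateau, fragments them into scaffolds with one planted chimera, and
prints the truth ledger entries that downstream stages are scored
against.
"""

import numpy as np

from scaffmap.simulate import (
    FragmentationConfig,
    GenomeConfig,
    fragment_into_scaffolds,
    simulate_truth_genome,
)

truth = simulate_truth_genome(
    GenomeConfig(n_chromosomes=2, length_range=(140_000, 160_000)), seed=7
)
for chrom, seq in truth.chromosomes.items():
    cen = truth.centromere_intervals[chrom]
    total = truth.marey_total_cm[chrom]
    f = truth.marey_functions[chrom]
    mid_rate = (f(cen[1]) - f(cen[0]))
    print(
        f"{chrom}: {len(seq):,} bp, map length {total:.1f} cM, "
        f"centromere {cen[0]:,}-{cen[1]:,} (cM gained inside: {mid_rate:.3f})"
    )

scaffolds = fragment_into_scaffolds(
    truth,
    FragmentationConfig(n_scaffolds=6, n_chimeras=1, n_flipped=1, n_unplaced=0,
                        n_gaps=4),
    seed=1,
)
print(f"\n{len(scaffolds)} scaffolds; planted defects:")
for j in truth.planted_junctions:
    print(f"  chimera junction in {j.scaffold} at {j.position:,} "
          f"({j.left_chrom} | {j.right_chrom})")
for name, strand in truth.scaffold_strand.items():
    if strand == "-":
        print(f"  {name} emitted reverse-complemented")
for g in truth.patchable_gaps:
    print(f"  gap in {g.scaffold} [{g.start:,}, {g.end:,}): "
          f"{g.end - g.start} N replacing {len(g.true_insert)} bp of truth")

# The zero-slope plateau is the synthetic analogue of the recombination
# suppression seen around real centromeres; junctions and gaps carry the
# exact coordinates the pipeline must rediscover.
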