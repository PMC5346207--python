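"""Run the whole map-integration chain on a small synthetic study.

Simulates a genome, places the marker panels, detects and breaks the
planted chimera, orders and orients the scaffolds, and prints the
recovery scores plus the first AGP rows of the resulting
pseudomolecules.
"""

from scaffmap.pipeline import PipelineConfig, run_synthetic_pipeline

cfg = PipelineConfig()
cfg.genome.n_chromosomes = 3
cfg.genome.length_range = (300_000, 400_000)
cfg.fragmentation.n_scaffolds = 12
cfg.fragmentation.n_chimeras = 1
cfg.fragmentation.n_flipped = 2
cfg.fragmentation.n_unplaced = 1
cfg.fragmentation.n_gaps = 8
cfg.maps.markers_per_chromosome = (30, 20)
cfg.variants.n_snps = 10
cfg.variants.n_indels = 8

res = run_synthetic_pipeline(cfg, seed=1)

print("pseudomolecules:", {k: f"{len(v):,} bp" for k, v in res.pseudomolecules.items()})
print("break events:", [(e.scaffold, e.interval, e.chosen_break)
                        for e in res.break_events])
print("\nfirst AGP rows:")
print(res.agp.head(6).to_string(index=False))
print("\nrecovery vs planted truth:")
for key in ("assignment_accuracy", "order_kendall_tau_min",
            "orientation_accuracy", "junction_recall", "false_breaks"):
    print(f"  {key}: {res.evaluation[key]}")
# 1.0 / 1.0 / 1.0 / 1.0 / 0 means every scaffold landed on its true
# chromosome in the true order and orientation, the planted junction was
# bracketed by a break, and no clean scaffold was broken.
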