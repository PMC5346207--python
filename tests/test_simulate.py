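"""Truth-genome generator: determinism, ledger completeness, Marey
construction, planted defects."""

import numpy as np
import pytest

from scaffmap import simulate
from scaffmap.simulate import (
    ConfigError,
    FragmentationConfig,
    GenomeConfig,
    LinkageMapConfig,
    PatchContigConfig,
    VariantConfig,
    fragment_into_scaffolds,
    reassemble_from_ledger,
    simulate_linkage_maps,
    simulate_patch_contigs,
    simulate_truth_genome,
    simulate_variants,
)


def tiny_genome(seed=5, **kw):
    cfg = GenomeConfig(
        n_chromosomes=kw.pop("n_chromosomes", 2),
        length_range=kw.pop("length_range", (120_000, 160_000)),
        **kw,
    )
    return simulate_truth_genome(cfg, seed=seed)


class TestTruthGenome:
    def test_marey_endpoints_forced(self):
        cfg = GenomeConfig(
            n_chromosomes=1,
            length_range=(100_000, 100_000),
            centromere_fraction=0.2,
            map_length_cm=(50.0, 50.0),
        )
        truth = simulate_truth_genome(cfg, seed=7)
        f = truth.marey_functions["chr1"]
        assert float(f(0)) == pytest.approx(0.0, abs=1e-9)
        assert float(f(100_000)) == pytest.approx(50.0, abs=1e-9)

    def test_determinism_byte_identical(self):
        a = tiny_genome(seed=7)
        b = tiny_genome(seed=7)
        assert a.chromosomes == b.chromosomes
        assert a.centromere_intervals == b.centromere_intervals

    def test_different_seeds_differ(self):
        assert tiny_genome(seed=7).chromosomes != tiny_genome(seed=8).chromosomes

    def test_centromeric_plateau_zero_slope(self):
        truth = tiny_genome(seed=3, n_chromosomes=8)
        for chrom, (a, b) in truth.centromere_intervals.items():
            f = truth.marey_functions[chrom]
            grid = np.linspace(a, b, 50)
            slopes = np.diff(f(grid))
            assert np.max(np.abs(slopes)) < 1e-9

    def test_marey_monotone_and_integrates_to_total(self):
        truth = tiny_genome(seed=4)
        for chrom, seq in truth.chromosomes.items():
            f = truth.marey_functions[chrom]
            grid = np.linspace(0, len(seq), 500)
            vals = f(grid)
            assert (np.diff(vals) >= -1e-9).all()
            total = truth.marey_total_cm[chrom]
            assert float(vals[-1]) == pytest.approx(total, rel=1e-6)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="centromere_fraction"):
            simulate_truth_genome(GenomeConfig(centromere_fraction=0.7))
        with pytest.raises(ConfigError, match="n_chromosomes"):
            simulate_truth_genome(GenomeConfig(n_chromosomes=0))
        with pytest.raises(ConfigError, match="length_range"):
            simulate_truth_genome(GenomeConfig(length_range=(500, 600)))


class TestFragmentation:
    def test_no_defects_means_contiguous_plus_strand(self):
        truth = tiny_genome(seed=9)
        cfg = FragmentationConfig(
            n_scaffolds=6, n_chimeras=0, n_flipped=0, n_unplaced=0, n_gaps=0
        )
        scaffolds = fragment_into_scaffolds(truth, cfg, seed=1)
        for name, records in truth.scaffold_provenance.items():
            assert truth.scaffold_strand[name] == "+"
            assert len(records) == 1
            rec = records[0]
            assert (
                scaffolds[name]
                == truth.chromosomes[rec.chrom][rec.start : rec.end]
            )

    def test_chimera_bookkeeping(self):
        truth = tiny_genome(seed=9)
        cfg = FragmentationConfig(
            n_scaffolds=6, n_chimeras=2, n_flipped=0, n_unplaced=0, n_gaps=0
        )
        scaffolds = fragment_into_scaffolds(truth, cfg, seed=1)
        assert len(truth.planted_junctions) == 2
        for j in truth.planted_junctions:
            recs = truth.scaffold_provenance[j.scaffold]
            assert j.left_chrom != j.right_chrom
            left = truth.chromosomes[recs[0].chrom][recs[0].start : recs[0].end]
            right = truth.chromosomes[recs[1].chrom][recs[1].start : recs[1].end]
            assert scaffolds[j.scaffold] == left + right
            assert j.position == len(left)

    def test_ledger_round_trip_byte_identical(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        rebuilt = reassemble_from_ledger(truth, scaffolds)
        assert rebuilt == scaffolds

    def test_ledger_covers_every_truth_base_once(self, small_truth):
        truth, _, _, _ = small_truth
        covered = {c: np.zeros(len(s), dtype=int) for c, s in truth.chromosomes.items()}
        for records in truth.scaffold_provenance.values():
            for rec in records:
                covered[rec.chrom][rec.start : rec.end] += 1
        for c, arr in covered.items():
            assert (arr == 1).all(), f"{c}: coverage multiset violated"

    def test_determinism(self):
        t1 = tiny_genome(seed=9)
        t2 = tiny_genome(seed=9)
        cfg = FragmentationConfig(n_scaffolds=6, n_chimeras=1, n_gaps=3, n_flipped=1,
                                  n_unplaced=0)
        s1 = fragment_into_scaffolds(t1, cfg, seed=2)
        s2 = fragment_into_scaffolds(t2, cfg, seed=2)
        assert s1 == s2

    def test_infeasible_counts_rejected(self):
        truth = tiny_genome(seed=9)
        cfg = FragmentationConfig(n_scaffolds=2, n_chimeras=5)
        with pytest.raises(ConfigError):
            fragment_into_scaffolds(truth, cfg, seed=1)


class TestLinkageMaps:
    def test_zero_noise_monotone_along_truth(self, small_truth):
        truth, _, markers, _ = small_truth
        for (m, lg), grp in markers.groupby(["map_id", "linkage_group"]):
            pos = [truth.marker_truth[i].position for i in grp["marker_id"]]
            order = np.argsort(pos)
            cms = grp["cM"].to_numpy()[order]
            assert (np.diff(cms) >= -1e-9).all()

    def test_bin_fraction_exact_count(self, small_truth):
        truth, scaffolds, _, cfg = small_truth
        mcfg = LinkageMapConfig(
            markers_per_chromosome=(20,), bin_fraction=0.5, min_marker_spacing=500
        )
        markers = simulate_linkage_maps(truth, mcfg, seed=21)
        for lg, grp in markers.groupby("linkage_group"):
            assert (grp["level"] == "bin").sum() == 10

    def test_mismap_ledger_matches_emitted_lg(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        mcfg = LinkageMapConfig(
            markers_per_chromosome=(30,), mismap_rate=0.1, min_marker_spacing=500
        )
        markers = simulate_linkage_maps(truth, mcfg, seed=22)
        chrom_lg = {c: i + 1 for i, c in enumerate(truth.chromosomes)}
        for row in markers.itertuples():
            mt = truth.marker_truth[row.marker_id]
            wrong = row.linkage_group != chrom_lg[mt.chrom]
            assert wrong == mt.mismapped

    def test_markers_avoid_unplaced_scaffolds(self, small_truth):
        truth, _, markers, _ = small_truth
        for mt in truth.marker_truth.values():
            assert mt.scaffold not in truth.unplaced_scaffolds


class TestPatchContigs:
    def test_every_gap_has_spanning_contig_at_fraction_one(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        import copy

        t = copy.deepcopy(truth)
        contigs = simulate_patch_contigs(
            t, scaffolds, PatchContigConfig(fraction_spanning=1.0, n_decoys=0), seed=3
        )
        spanning = {info["gap_index"] for info in t.contig_truth.values()}
        assert spanning == set(range(len(t.patchable_gaps)))
        for cid, info in t.contig_truth.items():
            gap = t.patchable_gaps[info["gap_index"]]
            assert gap.true_insert in contigs[cid]

    def test_one_sided_decoy_lacks_right_flank(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        import copy

        t = copy.deepcopy(truth)
        contigs = simulate_patch_contigs(
            t,
            scaffolds,
            PatchContigConfig(
                fraction_spanning=0.0, n_decoys=3, decoy_classes=("one_sided",)
            ),
            seed=3,
        )
        for cid, info in t.contig_truth.items():
            gap = t.patchable_gaps[info["gap_index"]]
            seq = scaffolds[gap.scaffold]
            right = seq[gap.end : gap.end + 100]
            assert right not in contigs[cid]

    def test_fraction_out_of_range_rejected(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        with pytest.raises(ConfigError):
            simulate_patch_contigs(
                truth, scaffolds, PatchContigConfig(fraction_spanning=1.5), seed=3
            )


class TestVariants:
    def test_single_snp_single_mismatch(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        import copy

        t = copy.deepcopy(truth)
        corrupted, recs = simulate_variants(
            t, scaffolds, VariantConfig(n_snps=1, n_indels=0), seed=5
        )
        diffs = [
            (n, i)
            for n in scaffolds
            for i in range(len(scaffolds[n]))
            if len(corrupted[n]) == len(scaffolds[n]) and corrupted[n][i] != scaffolds[n][i]
        ]
        assert len(diffs) == 1
        assert len(recs) == 1

    def test_indel_changes_length_by_size(self, small_truth):
        truth, scaffolds, _, _ = small_truth
        import copy

        t = copy.deepcopy(truth)
        corrupted, recs = simulate_variants(
            t,
            scaffolds,
            VariantConfig(n_snps=0, n_indels=1, indel_size_range=(3, 4)),
            seed=6,
        )
        (rec,) = recs
        delta = sum(len(corrupted[n]) for n in corrupted) - sum(
            len(s) for s in scaffolds.values()
        )
        assert abs(delta) == 3
        assert delta == len(rec[2]) - len(rec[3])  # REF minus ALT

    def test_sites_respect_spacing_and_avoid_n(self, small_pipeline):
        res = small_pipeline
        by_seq = {}
        for v in res.truth.planted_variants:
            by_seq.setdefault(v.seq_name, []).append(v.position)
            assert "N" not in res.corrupted[v.seq_name][v.position : v.position + 2]
        for positions in by_seq.values():
            positions.sort()
            assert all(b - a >= 10 for a, b in zip(positions, positions[1:]))


class TestOutputs:
    def test_write_outputs_round_trip(self, small_truth, tmp_path):
        import copy
        import json

        from scaffmap.seqio import read_fasta
        from scaffmap.simulate import (
            VariantConfig,
            simulate_variants,
            write_outputs,
        )

        truth, scaffolds, markers, _ = small_truth
        t = copy.deepcopy(truth)
        corrupted, recs = simulate_variants(
            t, scaffolds, VariantConfig(n_snps=3, n_indels=2), seed=9
        )
        write_outputs(tmp_path, t, scaffolds, markers, None, corrupted, recs)
        assert read_fasta(tmp_path / "scaffolds.fasta") == scaffolds
        assert read_fasta(tmp_path / "corrupted.fasta") == corrupted
        ledger = json.loads((tmp_path / "truth_ledger.json").read_text())
        assert set(ledger["scaffold_provenance"]) == set(scaffolds)
        assert len(ledger["planted_variants"]) == 5
        import pandas as pd

        mk = pd.read_csv(tmp_path / "markers.tsv", sep="\t")
        assert len(mk) == len(markers)
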