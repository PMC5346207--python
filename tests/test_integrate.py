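"""Anchoring, chromosome assignment, chimera breaking, ordering and
pseudomolecule construction."""

import numpy as np
import pandas as pd
import pytest

from scaffmap import integrate
from scaffmap.integrate import (
    Anchor,
    AnchorEntry,
    BreakEvent,
    apply_breaks,
    assign_scaffolds_to_chromosomes,
    build_anchors,
    build_pseudomolecules,
    detect_chimeras,
    lift_placements,
    order_and_orient,
    rebuild_from_agp,
)
from scaffmap.markers import Placement


def _maps_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["marker_id", "map_id", "linkage_group", "cM", "level"],
    )


def _anchor(scaffold, entries):
    a = Anchor(scaffold)
    for mid, m, lg, cm, pos, level in entries:
        a.entries.append(AnchorEntry(mid, m, lg, cm, pos, level))
    a.entries.sort(key=lambda e: e.pos)
    return a


class TestBuildAnchors:
    def test_basic_join(self):
        maps = _maps_frame(
            [(f"m{i}", "A", 3, float(i), "full") for i in range(3)]
        )
        placements = [Placement(f"m{i}", "s1", i * 100, i * 100 + 50, "+", "epcr_N0")
                      for i in range(3)]
        anchors, unknown = build_anchors(placements, maps)
        assert len(anchors) == 1 and unknown == []
        assert len(anchors[0].entries) == 3

    def test_duplicate_placements_rejected(self):
        maps = _maps_frame([("m1", "A", 1, 0.0, "full")])
        dup = [
            Placement("m1", "s1", 0, 50, "+", "epcr_N0"),
            Placement("m1", "s2", 0, 50, "+", "epcr_N0"),
        ]
        with pytest.raises(ValueError):
            build_anchors(dup, maps)

    def test_unknown_markers_listed(self):
        maps = _maps_frame([("m1", "A", 1, 0.0, "full")])
        anchors, unknown = build_anchors(
            [Placement("ghost", "s1", 0, 50, "+", "epcr_N0")], maps
        )
        assert anchors == [] and unknown == ["ghost"]


class TestAssignment:
    def test_majority_with_lone_discordant_suspect(self):
        entries = [(f"m{i}", "A", 3, float(i), i * 1000, "full") for i in range(5)]
        entries.append(("odd", "A", 7, 2.0, 2500, "full"))
        calls = assign_scaffolds_to_chromosomes([_anchor("s1", entries)])
        (call,) = calls
        assert call.chromosome == 3 and call.status == "assigned"
        assert call.suspect_markers == {"odd"}

    def test_discordant_block_flags_chimera(self):
        entries = [(f"a{i}", "A", 6, float(i), i * 1000, "full") for i in range(4)]
        entries += [
            (f"b{i}", "A", 2, float(i), 10_000 + i * 1000, "full") for i in range(3)
        ]
        (call,) = assign_scaffolds_to_chromosomes([_anchor("s1", entries)])
        assert call.status == "candidate_chimera"
        assert call.chromosome is None

    def test_single_bin_marker_assigned_but_weak(self):
        (call,) = assign_scaffolds_to_chromosomes(
            [_anchor("s1", [("m1", "A", 4, 1.0, 100, "bin")])]
        )
        assert call.chromosome == 4
        assert call.ordering_support == "insufficient"


class TestDetectChimeras:
    def test_clean_scaffold_no_events(self):
        entries = [(f"m{i}", "A", 1, float(i), i * 1000, "full") for i in range(6)]
        assert detect_chimeras([_anchor("s", entries)], {"s": "A" * 6000}) == []

    def test_lone_discordant_marker_no_event(self):
        entries = [(f"m{i}", "A", 1, float(i), i * 1000, "full") for i in range(6)]
        entries.append(("odd", "A", 5, 3.0, 3500, "full"))
        assert detect_chimeras([_anchor("s", entries)], {"s": "A" * 6000}) == []

    def test_interchromosomal_junction_detected_at_n_run(self):
        seq = "A" * 5000 + "N" * 100 + "C" * 5000
        entries = [(f"a{i}", "A", 1, float(i), i * 1000, "full") for i in range(4)]
        entries += [
            (f"b{i}", "A", 2, float(i), 6000 + i * 1000, "full") for i in range(4)
        ]
        events = detect_chimeras([_anchor("s", entries)], {"s": seq})
        assert len(events) == 1
        ev = events[0]
        assert ev.interval == (3000, 6000)
        assert ev.chosen_break == 5050  # midpoint of the N-run
        assert ev.evidence[0]["linkage_group"] == 1
        assert ev.evidence[1]["linkage_group"] == 2

    def test_cm_jump_within_lg_detected(self):
        entries = [(f"m{i}", "A", 1, float(i), i * 1000, "full") for i in range(4)]
        entries += [
            (f"n{i}", "A", 1, 40.0 + i, 4000 + i * 1000, "full") for i in range(4)
        ]
        events = detect_chimeras(
            [_anchor("s", entries)], {"s": "A" * 8000}, cm_jump=10.0,
            phys_window_frac=0.5,
        )
        assert len(events) == 1
        assert events[0].interval == (3000, 4000)

    def test_planted_junctions_recovered(self, small_pipeline):
        res = small_pipeline
        for j in res.truth.planted_junctions:
            assert any(
                ev.scaffold == j.scaffold
                and ev.interval[0] <= j.position <= ev.interval[1]
                for ev in res.break_events
            )

    def test_no_false_breaks_at_zero_noise(self, small_pipeline):
        res = small_pipeline
        chimeric = {j.scaffold for j in res.truth.planted_junctions}
        assert {ev.scaffold for ev in res.break_events} <= chimeric


class TestApplyBreaks:
    def test_split_sizes_and_conservation(self):
        assembly = {"s": "ACGT" * 3000}  # 12 kb
        ev = BreakEvent("s", (4000, 6000), 5000, ({}, {}))
        broken, ledger = apply_breaks(assembly, [ev])
        assert len(broken["s_p1"]) == 5000 and len(broken["s_p2"]) == 7000
        assert broken["s_p1"] + broken["s_p2"] == assembly["s"]

    def test_two_breaks_three_pieces_with_lifted_placements(self):
        assembly = {"s": "ACGT" * 3000}
        events = [
            BreakEvent("s", (0, 1), 4000, ({}, {})),
            BreakEvent("s", (0, 1), 8000, ({}, {})),
        ]
        broken, ledger = apply_breaks(assembly, events)
        assert sorted(broken) == ["s_p1", "s_p2", "s_p3"]
        placements = [
            Placement("m1", "s", 100, 150, "+", "epcr_N0"),
            Placement("m2", "s", 4100, 4150, "+", "epcr_N0"),
            Placement("m3", "s", 11_000, 11_050, "+", "epcr_N0"),
            Placement("spanning", "s", 3990, 4050, "+", "epcr_N0"),
        ]
        lifted = {p.marker_id: p for p in lift_placements(placements, ledger)}
        assert lifted["m1"].scaffold == "s_p1" and lifted["m1"].start == 100
        assert lifted["m2"].scaffold == "s_p2" and lifted["m2"].start == 100
        assert lifted["m3"].scaffold == "s_p3" and lifted["m3"].start == 3000
        assert "spanning" not in lifted  # crosses the cut

    def test_invalid_break_position_rejected(self):
        with pytest.raises(ValueError):
            apply_breaks({"s": "ACGT"}, [BreakEvent("s", (0, 1), 0, ({}, {}))])


class TestOrderOrient:
    def _setup(self, cm_by_pos):
        entries = [
            (f"m{i}", "A", 1, cm, pos, "full")
            for i, (pos, cm) in enumerate(cm_by_pos)
        ]
        anchor = _anchor("s", entries)
        maps = _maps_frame(
            [(f"m{i}", "A", 1, cm, "full") for i, (_, cm) in enumerate(cm_by_pos)]
            + [("lo", "A", 1, 0.0, "full"), ("hi", "A", 1, 10.0, "full")]
        )
        calls = assign_scaffolds_to_chromosomes([anchor])
        return order_and_orient([anchor], calls, maps)

    def test_positive_association_plus(self):
        (call,) = self._setup([(10_000, 5.0), (90_000, 9.0)])
        assert call.orientation == "+"

    def test_negative_association_minus(self):
        (call,) = self._setup([(10_000, 9.0), (90_000, 5.0)])
        assert call.orientation == "-"

    def test_cosegregating_markers_unknown(self):
        (call,) = self._setup([(10_000, 5.0), (50_000, 5.0), (90_000, 5.0)])
        assert call.orientation == "unknown"

    def test_pipeline_order_and_orientation_perfect(self, small_pipeline):
        ev = small_pipeline.evaluation
        assert ev["assignment_accuracy"] == 1.0
        assert ev["order_kendall_tau_min"] == pytest.approx(1.0)
        assert ev["orientation_accuracy"] == 1.0


class TestPseudomolecules:
    def test_spacer_arithmetic_and_agp_parts(self):
        from scaffmap.integrate import OrderOrientCall

        assembly = {"a": "A" * 100, "c": "C" * 200}
        calls = [
            OrderOrientCall("a", 1, 1, 0.1, "+", 2, 1.0),
            OrderOrientCall("c", 1, 2, 0.9, "-", 2, 1.0),
        ]
        pseudos, agp, unplaced = build_pseudomolecules(assembly, calls)
        assert len(pseudos["Pm01"]) == 10_300
        assert list(agp["component_type"]) == ["W", "U", "W"]
        assert unplaced == {}

    def test_single_scaffold_no_spacer(self):
        from scaffmap.integrate import OrderOrientCall

        pseudos, agp, _ = build_pseudomolecules(
            {"a": "ACGT" * 50}, [OrderOrientCall("a", 2, 1, 0.5, "+", 2, 1.0)]
        )
        assert pseudos["Pm02"] == "ACGT" * 50
        assert len(agp) == 1

    def test_agp_round_trip_byte_identical(self, small_pipeline):
        res = small_pipeline
        rebuilt = rebuild_from_agp(res.agp, res.broken_assembly)
        assert rebuilt == res.pseudomolecules

    def test_sequence_conservation(self, small_pipeline):
        res = small_pipeline
        from collections import Counter

        def base_counts(seqs):
            c = Counter()
            for s in seqs.values():
                c.update(s)
            return c

        from scaffmap.seqio import revcomp

        # orient inputs as the build placed them: '-' components contribute
        # their reverse complement to the pseudomolecule sequence
        orientation = {
            r["component_id"]: r["orientation"]
            for _, r in res.agp.iterrows()
            if r["component_type"] == "W"
        }
        oriented_inputs = {
            n: revcomp(s) if orientation.get(n) == "-" else s
            for n, s in res.broken_assembly.items()
        }
        inputs = base_counts(oriented_inputs)
        outputs = base_counts(res.pseudomolecules) + base_counts(res.unplaced)
        spacers = sum(
            1 for _, r in res.agp.iterrows() if r["component_type"] == "U"
        )
        outputs["N"] -= spacers * integrate.SPACER_LENGTH
        assert inputs == outputs

    def test_duplicate_ranks_rejected(self):
        from scaffmap.integrate import OrderOrientCall

        calls = [
            OrderOrientCall("a", 1, 1, 0.1, "+", 2, 1.0),
            OrderOrientCall("c", 1, 1, 0.9, "+", 2, 1.0),
        ]
        with pytest.raises(ValueError):
            build_pseudomolecules({"a": "A" * 10, "c": "C" * 10}, calls)


class TestAnchoringReport:
    def test_totals_equal_column_sums(self, small_pipeline):
        res = small_pipeline
        for map_id, grp in res.anchoring.groupby("map_id"):
            body = grp[grp["chromosome"] != "total"]
            total = grp[grp["chromosome"] == "total"].iloc[0]
            assert total["markers"] == body["markers"].sum()
            assert total["bp_span"] == body["bp_span"].sum()
            assert total["cM_span"] == pytest.approx(body["cM_span"].sum())

    def test_percentages_well_formed(self, small_pipeline):
        res = small_pipeline
        pct = res.anchoring["pct_of_pseudomolecule"]
        assert ((pct >= 0) & (pct <= 100)).all()
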