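"""In-silico PCR, flank placement and the marker/genotype filters."""

import numpy as np
import pytest

from scaffmap.markers import (
    ArrayGenotypeRecord,
    SnpSiteStats,
    epcr_place,
    filter_array_genotypes,
    filter_snp_candidates,
    place_all_markers,
    place_by_flank,
)
from scaffmap.seqio import revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant_product(rng, length=2000, fwd_len=20, rev_len=20, product=200, at=700):
    """Random template with one primer-pair site at a known position."""
    seq = _random_seq(rng, length)
    fwd = seq[at : at + fwd_len]
    rev = revcomp(seq[at + product - rev_len : at + product])
    return seq, fwd, rev, at, at + product


def brute_force_epcr(fwd, rev, seq, max_mm, product_range):
    """Oracle: exhaustive window scan with mismatch counting."""

    def sites(p):
        out = []
        for i in range(len(seq) - len(p) + 1):
            w = seq[i : i + len(p)]
            mm = sum(a != b or b == "N" for a, b in zip(p, w))
            if mm <= max_mm:
                out.append(i)
        return out

    hits = []
    for p1, p2, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
        starts = [i for i in sites(p1) if seq[i + len(p1) - 1] == p1[-1]]
        rc2 = revcomp(p2)
        ends = [
            i + len(p2)
            for i in sites(rc2)
            if seq[i] == rc2[0]
        ]
        for a in starts:
            for e in ends:
                if product_range[0] <= e - a <= product_range[1]:
                    hits.append((a, e, strand))
    return sorted(hits)


class TestEpcr:
    def test_exact_site_found(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng)
        cands = epcr_place(fwd, rev, {"s": seq}, 0)
        assert [(c.start, c.end, c.strand) for c in cands] == [(a, e, "+")]

    def test_mismatch_threshold_semantics(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng)
        # one substitution in the middle of the forward primer
        bad = fwd[:10] + ("A" if fwd[10] != "A" else "C") + fwd[11:]
        assert epcr_place(bad, rev, {"s": seq}, 0) == []
        cands = epcr_place(bad, rev, {"s": seq}, 1)
        assert [(c.start, c.end) for c in cands] == [(a, e)]

    def test_two_loci_reported_with_hit_count(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng, length=1500)
        dup = seq + _random_seq(rng, 300) + seq[a:e] + _random_seq(rng, 100)
        cands = epcr_place(fwd, rev, {"s": dup}, 0)
        assert len(cands) == 2
        assert all(c.n_candidate_hits == 2 for c in cands)

    def test_reverse_strand_site(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng)
        flipped = revcomp(seq)
        cands = epcr_place(fwd, rev, {"s": flipped}, 0)
        assert [(c.start, c.end, c.strand) for c in cands] == [
            (len(seq) - e, len(seq) - a, "-")
        ]

    def test_three_prime_anchor_mismatch_kills_site(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng)
        bad = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        assert epcr_place(bad, rev, {"s": seq}, 3) == []

    def test_n_in_template_never_matches(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng)
        broken = seq[: a + 5] + "N" + seq[a + 6 :]
        assert epcr_place(fwd, rev, {"s": broken}, 0) == []
        assert len(epcr_place(fwd, rev, {"s": broken}, 1)) == 1

    def test_matches_brute_force_oracle(self, rng):
        product_range = (60, 400)
        for trial in range(100):
            n = int(rng.integers(300, 800))
            seq = _random_seq(rng, n)
            at = int(rng.integers(0, n - 220))
            fwd = seq[at : at + 18]
            rev = revcomp(seq[at + 182 : at + 200])
            if set(fwd + rev) - set("ACGT"):
                continue
            max_mm = int(rng.integers(0, 3))
            got = epcr_place(fwd, rev, {"s": seq}, max_mm, product_range)
            expected = brute_force_epcr(fwd, rev, seq, max_mm, product_range)
            assert sorted((c.start, c.end, c.strand) for c in got) == expected

    def test_mismatch_budget_monotonicity(self, rng):
        seq, fwd, rev, *_ = _plant_product(rng)
        prev: set = set()
        for mm in (0, 1, 2, 3):
            cur = {
                (c.start, c.end, c.strand)
                for c in epcr_place(fwd, rev, {"s": seq}, mm)
            }
            assert prev <= cur
            prev = cur

    def test_malformed_primer_rejected(self, rng):
        seq = _random_seq(rng, 500)
        with pytest.raises(ValueError):
            epcr_place("ACGTACGTACGTACGTXX", "ACGTACGTACGTACGTAC", {"s": seq}, 0)

    def test_empty_assembly_empty_result(self):
        assert epcr_place("ACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG", {}, 0) == []


class TestFlankPlacement:
    def test_exact_substring_hit(self, rng):
        seq = _random_seq(rng, 3000)
        q = seq[1000:1150]
        hits = place_by_flank(q, {"s": seq})
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (1000, 1150, "+")

    def test_identity_threshold(self, rng):
        seq = _random_seq(rng, 3000)
        q = list(seq[1000:1150])
        idx = rng.choice(150, size=7, replace=False)  # ~5% substitutions
        for i in idx:
            q[i] = "A" if q[i] != "A" else "C"
        q = "".join(q)
        assert len(place_by_flank(q, {"s": seq}, min_identity=0.90)) == 1
        assert place_by_flank(q, {"s": seq}, min_identity=0.97) == []

    def test_reverse_complement_strand(self, rng):
        seq = _random_seq(rng, 3000)
        q = revcomp(seq[1000:1150])
        hits = place_by_flank(q, {"s": seq})
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (1000, "-")

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            place_by_flank("ACGT" * 10, {"s": "ACGT" * 100})


class TestPlaceAllMarkers:
    def test_synthetic_panel_all_placed_at_truth(self, small_truth):
        truth, scaffolds, markers, _ = small_truth
        placements, rejects = place_all_markers(markers, scaffolds)
        assert rejects == []
        placed = {p.marker_id: p for p in placements}
        assert len(placed) == len(set(markers["marker_id"]))
        for mid, p in placed.items():
            mt = truth.marker_truth[mid]
            assert p.scaffold == mt.scaffold
            assert p.start <= mt.scaffold_pos < p.end

    def test_primer_markers_use_first_epcr_round(self, small_truth):
        _, scaffolds, markers, _ = small_truth
        placements, _ = place_all_markers(markers, scaffolds)
        primered = set(markers[markers.primer_fwd != ""]["marker_id"])
        for p in placements:
            if p.marker_id in primered:
                assert p.method == "epcr_N0"
            else:
                assert p.method == "flank"

    def test_multi_locus_marker_rejected(self, rng):
        seq, fwd, rev, a, e = _plant_product(rng, length=1500)
        assembly = {"s": seq + seq}  # every locus duplicated
        import pandas as pd

        markers = pd.DataFrame(
            [
                {
                    "marker_id": "dup1",
                    "map_id": "m",
                    "linkage_group": 1,
                    "cM": 1.0,
                    "level": "full",
                    "primer_fwd": fwd,
                    "primer_rev": rev,
                    "flank_seq": "",
                }
            ]
        )
        placements, rejects = place_all_markers(markers, assembly)
        assert placements == []
        assert rejects[0].reason == "multi-locus"

    def test_strand_symmetry_on_flipped_assembly(self, small_truth):
        truth, scaffolds, markers, _ = small_truth
        sub = markers.head(30)
        placements, _ = place_all_markers(sub, scaffolds)
        flipped = {n: revcomp(s) for n, s in scaffolds.items()}
        placements_f, _ = place_all_markers(sub, flipped)
        fwd = {p.marker_id: p for p in placements}
        rev = {p.marker_id: p for p in placements_f}
        assert set(fwd) == set(rev)
        for mid in fwd:
            L = len(scaffolds[fwd[mid].scaffold])
            assert rev[mid].start == L - fwd[mid].end
            assert rev[mid].strand != fwd[mid].strand


class TestSnpFilter:
    def test_rule_outcomes(self):
        mk = lambda cov, maf, q, fq: SnpSiteStats("s", cov, 1.0, maf, q, fq)
        kept, disc = filter_snp_candidates(
            [
                mk(1.0, 0.45, 30, 20),   # passes all
                mk(2.5, 0.45, 30, 20),   # coverage
                mk(0.4, 0.45, 30, 20),   # coverage (low side)
                mk(1.0, 0.25, 30, 20),   # maf
                mk(1.0, 0.30, 30, 20),   # maf boundary: strict >
                mk(1.0, 0.45, 19, 20),   # snp_qual
                mk(1.0, 0.45, 30, 14),   # flank_qual
            ]
        )
        assert len(kept) == 1
        assert [r for _, r in disc] == [
            "coverage",
            "coverage",
            "maf",
            "maf",
            "snp_qual",
            "flank_qual",
        ]


class TestArrayFilter:
    def test_boundaries_and_segregation(self):
        recs = [
            ArrayGenotypeRecord("a", 0.39, 0.0),               # score boundary: out
            ArrayGenotypeRecord("b", 0.4, 0.10),               # missing boundary: out
            ArrayGenotypeRecord("c", 0.4, 0.09),               # retained
            ArrayGenotypeRecord(                                # AAxAA with AB progeny
                "d", 0.9, 0.0, ("AA", "AA"), ("AA", "AB", "AA")
            ),
        ]
        retained, counts, flagged = filter_array_genotypes(recs)
        assert [r.snp_id for r in retained] == ["c"]
        assert counts == {
            "genetrain": 1,
            "missing": 1,
            "unexpected segregation": 1,
        }
        assert [r.snp_id for r in flagged] == ["d"]
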