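"""Marker placement on assembly sequences and marker/genotype filters.

Two placement routes mirror how mapped markers are tied to a genome
sequence in practice:

* **in-silico PCR** for markers with a primer pair: three successive
  rounds allowing 0, 1 and 3 substitutions per primer, accepting a
  marker at the first round that yields exactly one product;
* **flank-sequence search** for markers that carry a ~150 bp flanking
  sequence instead (or whose primers found no unique product).

The mismatch budget is per primer, substitutions only, and the 3'
terminal base of each primer must match exactly (a primer with a
mismatched 3' end does not extend).  Ambiguity bases (N) in the
template never count as matches.

Also implements the sequencing-based SNP candidate filter (coverage
window around the mean, minor-allele frequency, site and flank
quality) and the array-genotype retention filter (GeneTrain score,
missingness, segregation consistency with the parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .seqio import revcomp

__all__ = [
    "Marker",
    "Placement",
    "SnpSiteStats",
    "ArrayGenotypeRecord",
    "epcr_place",
    "place_by_flank",
    "place_all_markers",
    "filter_snp_candidates",
    "filter_array_genotypes",
]

DEFAULT_PRODUCT_RANGE = (80, 600)
DEFAULT_EPCR_ROUNDS = (0, 1, 3)


@dataclass
class Marker:
    marker_id: str
    map_id: str
    linkage_group: int
    cM: float
    level: str = "full"  # or "bin"
    primer_fwd: str = ""
    primer_rev: str = ""
    flank_seq: str = ""
    marker_class: str = "SSR"


@dataclass
class Placement:
    marker_id: str
    scaffold: str
    start: int  # 0-based half-open scaffold coordinates
    end: int
    strand: str  # "+" or "-"
    method: str  # epcr_N0 / epcr_N1 / epcr_N3 / flank
    n_candidate_hits: int = 1


@dataclass
class Reject:
    marker_id: str
    reason: str  # "multi-locus" or "unplaced"
    n_hits: int = 0


class InputError(ValueError):
    pass


def _check_primer(primer: str) -> str:
    primer = primer.upper()
    if len(primer) < 15:
        raise InputError(f"primer too short ({len(primer)} < 15 nt)")
    if set(primer) - set("ACGT"):
        raise InputError(f"malformed primer alphabet: {primer}")
    return primer


def _hamming_hits(
    pattern: str, text: str, max_mm: int, anchor: str
) -> list[int]:
    """Start positions where ``pattern`` matches ``text`` with at most
    ``max_mm`` substitutions (no indels).

    ``anchor`` is "right" or "left": that end of the pattern must match
    exactly (the primer's 3' base).  N in the text never matches.  Uses
    pigeonhole seeding: with k mismatches allowed, one of k+1 pattern
    chunks must occur exactly; candidates are then verified in full.
    """
    m, n = len(pattern), len(text)
    if m > n:
        return []
    if max_mm == 0:
        hits, start = [], text.find(pattern)
        while start != -1:
            hits.append(start)
            start = text.find(pattern, start + 1)
        return hits
    k = max_mm + 1
    chunk = m // k
    candidates: set[int] = set()
    for c in range(k):
        lo = c * chunk
        hi = (c + 1) * chunk if c < k - 1 else m
        seed = pattern[lo:hi]
        pos = text.find(seed)
        while pos != -1:
            cand = pos - lo
            if 0 <= cand <= n - m:
                candidates.add(cand)
            pos = text.find(seed, pos + 1)
    hits = []
    for cand in sorted(candidates):
        window = text[cand : cand + m]
        if anchor == "right" and window[-1] != pattern[-1]:
            continue
        if anchor == "left" and window[0] != pattern[0]:
            continue
        mm = sum(1 for a, b in zip(pattern, window) if a != b or b == "N")
        if mm <= max_mm:
            hits.append(cand)
    return hits


def epcr_place(
    primer_fwd: str,
    primer_rev: str,
    assembly: dict[str, str],
    max_mismatches: int = 0,
    product_range: tuple[int, int] = DEFAULT_PRODUCT_RANGE,
    marker_id: str = "",
) -> list[Placement]:
    """All loci a primer pair would amplify, on both strands.

    A product exists where one primer matches a strand and the other
    matches the opposite strand downstream, each with at most
    ``max_mismatches`` substitutions, and the product length falls
    within ``product_range``.
    """
    fwd = _check_primer(primer_fwd)
    rev = _check_primer(primer_rev)
    lo, hi = product_range
    if lo < len(fwd) + len(rev):
        raise InputError("product_range minimum below combined primer length")
    out: list[Placement] = []
    for name, seq in assembly.items():
        # '+' strand: fwd as-is (3' = right end), reverse primer binds the
        # minus strand so its reverse complement appears downstream with its
        # 3' base at the left end of that match.
        f_plus = _hamming_hits(fwd, seq, max_mismatches, anchor="right")
        r_plus = _hamming_hits(revcomp(rev), seq, max_mismatches, anchor="left")
        ends = sorted(p + len(rev) for p in r_plus)
        for a in f_plus:
            for e in ends:
                length = e - a
                if lo <= length <= hi:
                    out.append(Placement(marker_id, name, a, e, "+", "epcr"))
        # '-' strand: the roles swap — rev matches the plus strand as-is,
        # the reverse complement of fwd appears downstream.
        r_minus = _hamming_hits(rev, seq, max_mismatches, anchor="right")
        f_minus = _hamming_hits(revcomp(fwd), seq, max_mismatches, anchor="left")
        ends = sorted(p + len(fwd) for p in f_minus)
        for a in r_minus:
            for e in ends:
                length = e - a
                if lo <= length <= hi:
                    out.append(Placement(marker_id, name, a, e, "-", "epcr"))
    for p in out:
        p.n_candidate_hits = len(out)
    return out


def place_by_flank(
    flank_seq: str,
    assembly: dict[str, str],
    min_identity: float = 0.90,
    min_query_coverage: float = 0.80,
    marker_id: str = "",
) -> list[Placement]:
    """Best-scoring flank-sequence hits per locus, both strands.

    Alignment uses banded semi-global (infix) edit distance: the whole
    query aligns inside the target (coverage 1.0 up to indels), with at
    most ``floor(len * (1 - min_identity))`` edits.  Hits closer than
    one query length are collapsed to the best per locus.
    """
    query = flank_seq.upper()
    if len(query) < 50:
        raise InputError(f"flank sequence too short ({len(query)} < 50 nt)")
    k = int(len(query) * (1 - min_identity))
    raw: list[tuple[str, int, int, str, float]] = []
    for name, seq in assembly.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            res = edlib.align(q, seq, mode="HW", task="locations", k=k)
            if res["editDistance"] == -1:
                continue
            identity = 1.0 - res["editDistance"] / len(query)
            for s, e in res["locations"]:
                raw.append((name, s, e + 1, strand, identity))
    # collapse hits on the same locus (within a query length)
    raw.sort(key=lambda t: (t[0], t[1]))
    loci: list[tuple[str, int, int, str, float]] = []
    for hit in raw:
        if loci and hit[0] == loci[-1][0] and hit[1] - loci[-1][1] < len(query):
            if hit[4] > loci[-1][4]:
                loci[-1] = hit
            continue
        loci.append(hit)
    out = [
        Placement(marker_id, name, s, e, strand, "flank")
        for name, s, e, strand, _ in loci
    ]
    for p in out:
        p.n_candidate_hits = len(out)
    return out


def place_all_markers(
    markers: pd.DataFrame,
    assembly: dict[str, str],
    rounds: tuple[int, ...] = DEFAULT_EPCR_ROUNDS,
    product_range: tuple[int, int] = DEFAULT_PRODUCT_RANGE,
    min_identity: float = 0.90,
    min_query_coverage: float = 0.80,
) -> tuple[list[Placement], list[Reject]]:
    """Place a marker panel, applying the uniqueness rule per stage.

    Primer-bearing markers try the mismatch rounds in order; the first
    round yielding exactly one candidate wins and the method records
    the round.  Markers unique at no round fall back to the flank
    search if a flanking sequence is available.  Markers with multiple
    candidates at every attempted stage are rejected as multi-locus;
    markers never hit at all are rejected as unplaced.
    """
    if len(markers) == 0:
        raise InputError("empty marker table")
    placements: list[Placement] = []
    rejects: list[Reject] = []
    # de-duplicate marker rows (a marker can belong to several maps)
    seen: set[str] = set()
    for _, row in markers.iterrows():
        mk = row["marker_id"]
        if mk in seen:
            continue
        seen.add(mk)
        primer_fwd = str(row.get("primer_fwd", "") or "")
        primer_rev = str(row.get("primer_rev", "") or "")
        flank = str(row.get("flank_seq", "") or "")
        max_hits = 0
        placed = None
        if primer_fwd and primer_rev:
            for n_mm in rounds:
                cands = epcr_place(
                    primer_fwd, primer_rev, assembly, n_mm, product_range, mk
                )
                max_hits = max(max_hits, len(cands))
                if len(cands) == 1:
                    placed = cands[0]
                    placed.method = f"epcr_N{n_mm}"
                    break
        if placed is None and flank:
            cands = place_by_flank(
                flank, assembly, min_identity, min_query_coverage, mk
            )
            max_hits = max(max_hits, len(cands))
            if len(cands) == 1:
                placed = cands[0]
        if placed is not None:
            placements.append(placed)
        elif max_hits > 1:
            rejects.append(Reject(mk, "multi-locus", max_hits))
        else:
            rejects.append(Reject(mk, "unplaced", 0))
    return placements, rejects


def placements_to_frame(placements: list[Placement]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in placements])


def placements_to_bed(placements: list[Placement]) -> pd.DataFrame:
    """BED6 frame (0-based half-open) of accepted placements."""
    return pd.DataFrame(
        {
            "chrom": [p.scaffold for p in placements],
            "start": [p.start for p in placements],
            "end": [p.end for p in placements],
            "name": [p.marker_id for p in placements],
            "score": [p.n_candidate_hits for p in placements],
            "strand": [p.strand for p in placements],
        }
    )


# ---------------------------------------------------------------------------
# quality filters


@dataclass
class SnpSiteStats:
    site_id: str
    coverage: float          # x
    mean_coverage: float     # x, zero-coverage regions excluded
    maf: float               # minor allele frequency, 0..0.5
    snp_qual: float          # Phred
    flank11_mean_qual: float  # Phred, mean over the 11 bp window


def filter_snp_candidates(
    sites: list[SnpSiteStats],
) -> tuple[list[SnpSiteStats], list[tuple[SnpSiteStats, str]]]:
    """Keep sequencing-derived SNP candidates passing all four rules.

    Keep iff coverage within [0.5x, 2x] of the mean, MAF > 0.30, site
    quality >= 20 and mean flanking quality (11 bp window) >= 15.  Each
    discard carries the first failed rule in this order.
    """
    kept, discarded = [], []
    for s in sites:
        if s.mean_coverage <= 0:
            raise InputError("mean_coverage must be > 0")
        if not 0.5 * s.mean_coverage <= s.coverage <= 2.0 * s.mean_coverage:
            discarded.append((s, "coverage"))
        elif not s.maf > 0.30:
            discarded.append((s, "maf"))
        elif not s.snp_qual >= 20:
            discarded.append((s, "snp_qual"))
        elif not s.flank11_mean_qual >= 15:
            discarded.append((s, "flank_qual"))
        else:
            kept.append(s)
    return kept, discarded


@dataclass
class ArrayGenotypeRecord:
    snp_id: str
    genetrain_score: float
    missing_fraction: float
    parent_genotypes: tuple[str, str] = ("AA", "BB")
    progeny_genotypes: tuple[str, ...] = ()


def _segregation_consistent(rec: ArrayGenotypeRecord) -> bool:
    p1, p2 = rec.parent_genotypes
    both_homozygous_same = p1 == p2 and len(set(p1)) == 1
    if both_homozygous_same:
        # all progeny must share the parental homozygous genotype
        return all(g == p1 for g in rec.progeny_genotypes)
    return True


def filter_array_genotypes(
    records: list[ArrayGenotypeRecord],
) -> tuple[list[ArrayGenotypeRecord], dict[str, int], list[ArrayGenotypeRecord]]:
    """Array-genotyping retention filter.

    Retain iff GeneTrain score >= 0.4 and missing fraction < 0.10
    (strict).  Records whose progeny segregation is inconsistent with
    the parental genotypes (e.g. identical homozygous parents producing
    heterozygous progeny) are flagged, not silently dropped; they are
    returned separately along with per-rule counts.
    """
    retained, flagged = [], []
    counts = {"genetrain": 0, "missing": 0, "unexpected segregation": 0}
    for r in records:
        if r.genetrain_score < 0.4:
            counts["genetrain"] += 1
            continue
        if not r.missing_fraction < 0.10:
            counts["missing"] += 1
            continue
        if not _segregation_consistent(r):
            counts["unexpected segregation"] += 1
            flagged.append(r)
            continue
        retained.append(r)
    return retained, counts, flagged
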