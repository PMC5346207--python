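"""Gap patching with assembled contigs and homozygous variant polishing.

A gap is a maximal N-run inside a scaffold.  An independently assembled
contig may close it when the contig's ends align to the sequence
flanking the gap: the acceptance rule requires at least 1/3 of the
contig length anchored to the gap edges at >= 95% identity.  The 1/3
is evaluated on the combined anchored fraction over both edges by
default (the identity threshold applies to each side independently);
``anchor_mode="per_side"`` demands the fraction on each side.

Variant polishing applies homozygous-alternate VCF records to the
assembly with cumulative offset tracking, so positions recorded
against the uncorrected sequence stay valid as upstream indels shift
coordinates.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .seqio import revcomp

__all__ = [
    "Gap",
    "FlankAlignment",
    "GapPatch",
    "find_gaps",
    "align_contig_to_gap",
    "is_eligible",
    "select_patches",
    "apply_patches",
    "apply_variant_corrections",
]

DEFAULT_MIN_N_RUN = 10
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_ANCHOR_FRAC = 1.0 / 3.0
#: window-side alignments must reach within this many bases of the gap edge
EDGE_TOLERANCE = 10


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class Gap:
    scaffold: str
    start: int  # 0-based half-open coordinates of the maximal N-run
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FlankAlignment:
    contig_id: str
    gap: Gap
    orientation: str  # contig orientation, '+' or '-'
    left_anchor_len: int
    right_anchor_len: int
    left_identity: float
    right_identity: float
    insert_interval: tuple[int, int]  # contig coords of the unanchored middle
    contig_length: int

    @property
    def anchored_fraction(self) -> float:
        return (self.left_anchor_len + self.right_anchor_len) / self.contig_length

    @property
    def min_side_fraction(self) -> float:
        return min(self.left_anchor_len, self.right_anchor_len) / self.contig_length

    @property
    def mean_identity(self) -> float:
        return (self.left_identity + self.right_identity) / 2.0

    @property
    def score(self) -> float:
        return self.anchored_fraction * self.mean_identity


@dataclass
class GapPatch:
    gap: Gap
    contig_id: str
    replacement: str  # sequence replacing the N-run
    gap_bases_patched: int
    bases_gained: int


def find_gaps(
    assembly: dict[str, str],
    min_n_run: int = DEFAULT_MIN_N_RUN,
    agp: pd.DataFrame | None = None,
) -> list[Gap]:
    """All maximal N-runs of length >= ``min_n_run``, sorted by coordinate.

    When an AGP is given, N-runs matching ``U`` components of gap type
    "map" (the standard pseudomolecule spacers) are excluded — they are
    joins, not sequence gaps.
    """
    if min_n_run < 1:
        raise InputError("min_n_run must be >= 1")
    spacers: set[tuple[str, int, int]] = set()
    if agp is not None:
        for _, row in agp.iterrows():
            if row["component_type"] == "U" and row["component_beg"] == "map":
                spacers.add(
                    (row["object"], int(row["object_beg"]) - 1, int(row["object_end"]))
                )
    pattern = re.compile("N{%d,}" % min_n_run)
    gaps = []
    for name in sorted(assembly):
        for m in pattern.finditer(assembly[name]):
            if (name, m.start(), m.end()) in spacers:
                continue
            gaps.append(Gap(name, m.start(), m.end()))
    return gaps


_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-2,
    extend_gap_score=-1,
)


def _best_local(target: str, query: str):
    """Best local alignment (target window vs contig); returns
    (t_start, t_end, q_start, q_end, identity) or None."""
    if not target or not query:
        return None
    alns = _aligner.align(target, query)
    if alns.score <= 0:
        return None
    aln = alns[0]
    t0 = int(aln.aligned[0][0][0])
    t1 = int(aln.aligned[0][-1][-1])
    q0 = int(aln.aligned[1][0][0])
    q1 = int(aln.aligned[1][-1][-1])
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return t0, t1, q0, q1, identity


def align_contig_to_gap(
    contig: str,
    assembly: dict[str, str],
    gap: Gap,
    flank_window: int | None = None,
    contig_id: str = "",
) -> FlankAlignment | None:
    """Anchor a contig to both edges of a gap.

    The contig (in both orientations) is locally aligned against the
    sequence windows immediately left and right of the N-run; the
    orientation maximizing the total anchored length wins.  The
    window-side alignment must reach the gap edge (within a small
    tolerance), otherwise the contig does not anchor *to the gap* but
    merely somewhere nearby.  Returns None when either side has zero
    anchored bases.
    """
    if flank_window is None:
        flank_window = min(2 * len(contig), 50_000)
    if flank_window < 50:
        raise InputError("flank_window must be >= 50")
    if len(contig) < 40:
        return None
    seq = assembly[gap.scaffold]
    left_w = seq[max(0, gap.start - flank_window) : gap.start]
    right_w = seq[gap.end : gap.end + flank_window]
    best: FlankAlignment | None = None
    for orientation in ("+", "-"):
        c = contig if orientation == "+" else revcomp(contig)
        left = _best_local(left_w, c)
        right = _best_local(right_w, c)
        if left is None or right is None:
            continue
        lt0, lt1, lq0, lq1, lid = left
        rt0, rt1, rq0, rq1, rid = right
        # anchors must reach the gap edges
        if len(left_w) - lt1 > EDGE_TOLERANCE or rt0 > EDGE_TOLERANCE:
            continue
        # anchors must not overlap on the contig
        if rq0 < lq1:
            continue
        fa = FlankAlignment(
            contig_id=contig_id,
            gap=gap,
            orientation=orientation,
            left_anchor_len=lq1 - lq0,
            right_anchor_len=rq1 - rq0,
            left_identity=lid,
            right_identity=rid,
            insert_interval=(lq1, rq0),
            contig_length=len(contig),
        )
        if best is None or (
            fa.left_anchor_len + fa.right_anchor_len
            > best.left_anchor_len + best.right_anchor_len
        ):
            best = fa
    return best


_SEED_K = 15
_SEED_FLANK = 1_000


def _seed_filter(
    gap: Gap, contigs: dict[str, str], assembly: dict[str, str]
) -> list[str]:
    """Contigs sharing an exact 15-mer with the gap's immediate flanks.

    Cheap pre-screen before the quadratic local alignment; a contig
    anchoring at >= 95% identity over >= 1/3 of its length shares many
    exact 15-mers with the flank, while an unrelated contig matches
    with probability ~ |contig| x |flank| / 4^15.
    """
    seq = assembly[gap.scaffold]
    flank = (
        seq[max(0, gap.start - _SEED_FLANK) : gap.start]
        + "#"
        + seq[gap.end : gap.end + _SEED_FLANK]
    )
    kmers = {
        flank[i : i + _SEED_K]
        for i in range(len(flank) - _SEED_K + 1)
        if "#" not in flank[i : i + _SEED_K] and "N" not in flank[i : i + _SEED_K]
    }
    out = []
    for cid, cseq in contigs.items():
        for probe in (cseq, revcomp(cseq)):
            if any(
                probe[i : i + _SEED_K] in kmers
                for i in range(0, len(probe) - _SEED_K + 1, 4)
            ):
                out.append(cid)
                break
    return out


def is_eligible(
    fa: FlankAlignment,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_anchor_frac: float = DEFAULT_MIN_ANCHOR_FRAC,
    anchor_mode: str = "combined",
) -> bool:
    """The gap-patching acceptance rule as a pure predicate."""
    if min(fa.left_identity, fa.right_identity) < min_identity:
        return False
    if anchor_mode == "combined":
        return fa.anchored_fraction >= min_anchor_frac
    if anchor_mode == "per_side":
        return fa.min_side_fraction >= min_anchor_frac
    raise InputError(f"unknown anchor_mode {anchor_mode!r}")


def select_patches(
    gaps: list[Gap],
    contigs: dict[str, str],
    assembly: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_anchor_frac: float = DEFAULT_MIN_ANCHOR_FRAC,
    anchor_mode: str = "combined",
    flank_window: int | None = None,
) -> tuple[list[GapPatch], list[FlankAlignment]]:
    """Choose at most one contig per gap (and one gap per contig).

    Eligible (gap, contig) alignments are ranked by anchored fraction x
    mean identity, ties broken by longer contig then lexicographic id;
    assignment is greedy in that order, so the selection is
    deterministic.  Returns the chosen patches and every computed
    alignment (for reporting/diagnostics).
    """
    alignments: list[FlankAlignment] = []
    for gap in gaps:
        candidates = _seed_filter(gap, contigs, assembly)
        for cid in candidates:
            fa = align_contig_to_gap(contigs[cid], assembly, gap, flank_window, cid)
            if fa is not None:
                alignments.append(fa)
    eligible = [
        fa
        for fa in alignments
        if is_eligible(fa, min_identity, min_anchor_frac, anchor_mode)
    ]
    eligible.sort(key=lambda fa: (-fa.score, -fa.contig_length, fa.contig_id))
    used_gaps: set[Gap] = set()
    used_contigs: set[str] = set()
    patches: list[GapPatch] = []
    for fa in eligible:
        if fa.gap in used_gaps or fa.contig_id in used_contigs:
            continue
        used_gaps.add(fa.gap)
        used_contigs.add(fa.contig_id)
        c = contigs[fa.contig_id]
        if fa.orientation == "-":
            c = revcomp(c)
        replacement = c[fa.insert_interval[0] : fa.insert_interval[1]]
        patches.append(
            GapPatch(
                gap=fa.gap,
                contig_id=fa.contig_id,
                replacement=replacement,
                gap_bases_patched=fa.gap.length,
                bases_gained=len(replacement.replace("N", "")),
            )
        )
    return patches, alignments


def apply_patches(
    assembly: dict[str, str],
    patches: list[GapPatch],
    chromosome_of: dict[str, str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Replace patched N-runs and emit the per-chromosome report.

    Report columns mirror the standard gap-patching summary: contigs
    used, gaps closed, gap bases patched, initial and post-patch contig
    (non-N) length and bases gained, with a totals row equal to the
    column sums.
    """
    by_seq: dict[str, list[GapPatch]] = defaultdict(list)
    for p in patches:
        by_seq[p.gap.scaffold].append(p)
    for name, ps in by_seq.items():
        ps.sort(key=lambda p: p.gap.start)
        for a, b in zip(ps[:-1], ps[1:]):
            if b.gap.start < a.gap.end:
                raise InputError(f"overlapping patches on {name}")

    def contig_bp(seq: str) -> int:
        return len(seq) - seq.count("N")

    groups: dict[str, dict] = defaultdict(
        lambda: {
            "contigs_used": 0,
            "gaps_closed": 0,
            "gap_bases_patched": 0,
            "initial_contig_bp": 0,
            "post_patch_contig_bp": 0,
            "bases_gained": 0,
        }
    )
    out: dict[str, str] = {}
    for name, seq in assembly.items():
        group = chromosome_of.get(name, name) if chromosome_of else name
        g = groups[group]
        g["initial_contig_bp"] += contig_bp(seq)
        new = seq
        for p in sorted(by_seq.get(name, []), key=lambda p: -p.gap.start):
            new = new[: p.gap.start] + p.replacement + new[p.gap.end :]
            g["contigs_used"] += 1
            g["gaps_closed"] += 1
            g["gap_bases_patched"] += p.gap_bases_patched
            g["bases_gained"] += p.bases_gained
        g["post_patch_contig_bp"] += contig_bp(new)
        out[name] = new
    report = pd.DataFrame(
        [{"chromosome": k, **v} for k, v in sorted(groups.items())]
    )
    if len(report):
        totals = report.drop(columns="chromosome").sum()
        report = pd.concat(
            [report, pd.DataFrame([{"chromosome": "total", **totals.to_dict()}])],
            ignore_index=True,
        )
    return out, report


def report_totals(per_chromosome: pd.DataFrame) -> dict:
    """Column sums of a per-chromosome patch/polish report."""
    numeric = per_chromosome.select_dtypes("number")
    return {k: int(v) for k, v in numeric.sum().items()}


def apply_variant_corrections(
    assembly: dict[str, str], vcf_path: str
) -> tuple[dict[str, str], dict]:
    """Apply homozygous-alternate corrections from a VCF.

    Only records with a homozygous alternate genotype and PASS/empty
    filter are applied, in coordinate order per sequence with
    cumulative offset tracking so positions after upstream indels stay
    valid.  Records whose REF does not match the current assembly are
    skipped and counted; overlapping records keep the first and skip
    the later one.  Counts partition into SNPs and indels by REF/ALT
    length.
    """
    import pysam

    try:
        vf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise InputError(f"malformed VCF: {exc}") from exc
    by_seq: dict[str, list] = defaultdict(list)
    for rec in vf:
        by_seq[rec.chrom].append(rec)
    counts = {
        "snps_corrected": 0,
        "indels_corrected": 0,
        "skipped_ref_mismatch": 0,
        "skipped_genotype": 0,
        "skipped_filter": 0,
        "skipped_overlap": 0,
    }
    out = dict(assembly)
    for chrom, recs in by_seq.items():
        if chrom not in out:
            continue
        seq = out[chrom]
        recs.sort(key=lambda r: r.pos)
        parts: list[str] = []
        last = 0
        for rec in recs:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                counts["skipped_filter"] += 1
                continue
            gts = [s.get("GT") for s in rec.samples.values()]
            hom_alt = any(
                gt is not None and None not in gt and len(set(gt)) == 1 and gt[0] == 1
                for gt in gts
            )
            if not hom_alt:
                counts["skipped_genotype"] += 1
                continue
            pos0 = rec.pos - 1
            ref, alt = rec.ref, rec.alts[0]
            if pos0 < last:
                counts["skipped_overlap"] += 1
                continue
            if seq[pos0 : pos0 + len(ref)] != ref:
                counts["skipped_ref_mismatch"] += 1
                continue
            parts.append(seq[last:pos0])
            parts.append(alt)
            last = pos0 + len(ref)
            if len(ref) == 1 and len(alt) == 1:
                counts["snps_corrected"] += 1
            else:
                counts["indels_corrected"] += 1
        parts.append(seq[last:])
        out[chrom] = "".join(parts)
    return out, counts
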