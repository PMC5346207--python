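"""Map-sequence integration: from marker placements to pseudomolecules.

Pipeline stages:

1. join placements with the linkage maps into per-scaffold anchors;
2. assign scaffolds to chromosomes by majority linkage group, flagging
   candidate chimeras (a physically contiguous block of >= 2 discordant
   fully-mapped markers) and lone discordant "suspect" markers;
3. detect chimeric scaffolds — adjacent marker blocks on different
   linkage groups, or a large cM discontinuity over a short physical
   distance — and break them, placing each break at the midpoint of the
   longest N-run inside the discordant interval (N-runs are the
   assembly-intrinsic proxy for weakly supported joins);
4. order and orient scaffolds along each chromosome from a marker-count
   weighted consensus of per-map positions (per-map cM rescaled to
   [0, 1] within each linkage group so maps of different total lengths
   are commensurable), orientation from the sign of the rank
   correlation between physical and genetic position;
5. concatenate ordered, oriented scaffolds into pseudomolecules with a
   standard spacer of 10,000 N between consecutive components, emitting
   AGP v2.1.

Bin-level markers vote for chromosome assignment but are excluded from
ordering and orientation: they localize a scaffold to a chromosome but
carry no within-group recombination information.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import Placement
from .seqio import AGP_COLUMNS, revcomp

__all__ = [
    "Anchor",
    "AnchorEntry",
    "BreakEvent",
    "OrderOrientCall",
    "build_anchors",
    "assign_scaffolds_to_chromosomes",
    "detect_chimeras",
    "apply_breaks",
    "lift_placements",
    "order_and_orient",
    "build_pseudomolecules",
    "rebuild_from_agp",
    "placements_to_object_coords",
    "anchoring_report",
]

SPACER_LENGTH = 10_000


class InputError(ValueError):
    pass


@dataclass
class AnchorEntry:
    marker_id: str
    map_id: str
    linkage_group: int
    cM: float
    pos: int  # physical position on the scaffold (placement midpoint)
    level: str


@dataclass
class Anchor:
    scaffold: str
    entries: list[AnchorEntry] = field(default_factory=list)

    def full_entries(self) -> list[AnchorEntry]:
        return [e for e in self.entries if e.level == "full"]


def build_anchors(
    placements: list[Placement], maps: pd.DataFrame
) -> tuple[list[Anchor], list[str]]:
    """Join placements with map positions, one anchor per scaffold.

    A marker mapped in several maps contributes one entry per map.
    Markers placed but absent from the map table are returned
    separately.  Duplicate placements of one marker are an input error
    (multi-locus markers must be rejected upstream).
    """
    seen = Counter(p.marker_id for p in placements)
    dups = [m for m, c in seen.items() if c > 1]
    if dups:
        raise InputError(f"duplicate placements for markers: {dups[:5]}")
    by_marker = maps.groupby("marker_id")
    known = set(maps["marker_id"])
    anchors: dict[str, Anchor] = {}
    unknown: list[str] = []
    for p in placements:
        if p.marker_id not in known:
            unknown.append(p.marker_id)
            continue
        anchor = anchors.setdefault(p.scaffold, Anchor(p.scaffold))
        pos = (p.start + p.end) // 2
        for _, row in by_marker.get_group(p.marker_id).iterrows():
            anchor.entries.append(
                AnchorEntry(
                    p.marker_id,
                    row["map_id"],
                    int(row["linkage_group"]),
                    float(row["cM"]),
                    pos,
                    row["level"],
                )
            )
    for a in anchors.values():
        a.entries.sort(key=lambda e: e.pos)
    return list(anchors.values()), unknown


@dataclass
class AssignmentCall:
    scaffold: str
    chromosome: int | None  # linkage group number; None for candidate chimeras
    status: str  # "assigned" or "candidate_chimera"
    suspect_markers: set[str] = field(default_factory=set)
    n_markers: int = 0
    ordering_support: str = "ok"  # or "insufficient"


def _discordant_blocks(
    entries: list[AnchorEntry], majority_lg: int, min_block: int
) -> tuple[list[list[AnchorEntry]], set[str]]:
    """Physically contiguous runs of full markers disagreeing with the
    majority linkage group; runs shorter than ``min_block`` become
    suspect markers instead."""
    full = sorted(
        (e for e in entries if e.level == "full"), key=lambda e: e.pos
    )
    runs: list[list[AnchorEntry]] = []
    for e in full:
        if runs and runs[-1][0].linkage_group == e.linkage_group:
            runs[-1].append(e)
        else:
            runs.append([e])
    blocks, suspects = [], set()
    for run in runs:
        if run[0].linkage_group == majority_lg:
            continue
        if len(run) >= min_block:
            blocks.append(run)
        else:
            suspects.update(e.marker_id for e in run)
    return blocks, suspects


def assign_scaffolds_to_chromosomes(
    anchors: list[Anchor], min_block: int = 2
) -> list[AssignmentCall]:
    """Majority-vote chromosome assignment with chimera flagging.

    Every marker (full and bin, across maps) votes equally.  Scaffolds
    whose minority markers form a physical block of >= ``min_block``
    fully-mapped markers are flagged candidate chimeras and not
    assigned a single chromosome.  Lone discordant markers are flagged
    suspect and excluded from later steps.
    """
    if not anchors:
        raise InputError("empty anchor list")
    calls = []
    for anchor in anchors:
        votes = Counter(e.linkage_group for e in anchor.entries)
        majority_lg = votes.most_common(1)[0][0]
        blocks, suspects = _discordant_blocks(anchor.entries, majority_lg, min_block)
        full_ok = [
            e
            for e in anchor.full_entries()
            if e.marker_id not in suspects and e.linkage_group == majority_lg
        ]
        support = "ok" if len(full_ok) >= 2 else "insufficient"
        if blocks:
            calls.append(
                AssignmentCall(
                    anchor.scaffold,
                    None,
                    "candidate_chimera",
                    suspects,
                    len(anchor.entries),
                    support,
                )
            )
        else:
            calls.append(
                AssignmentCall(
                    anchor.scaffold,
                    majority_lg,
                    "assigned",
                    suspects,
                    len(anchor.entries),
                    support,
                )
            )
    return calls


@dataclass
class BreakEvent:
    scaffold: str
    interval: tuple[int, int]  # physical range bounding the misjoin
    chosen_break: int
    evidence: tuple[dict, dict]  # the two flanking marker blocks


def _longest_n_run(seq: str, start: int, end: int) -> tuple[int, int] | None:
    best = None
    for m in re.finditer("N+", seq[start:end]):
        if best is None or (m.end() - m.start()) > (best[1] - best[0]):
            best = (start + m.start(), start + m.end())
    return best


def _block_evidence(block: list[AnchorEntry]) -> dict:
    return {
        "linkage_group": block[0].linkage_group,
        "cM_range": (min(e.cM for e in block), max(e.cM for e in block)),
        "n_markers": len(block),
        "pos_range": (block[0].pos, block[-1].pos),
    }


def detect_chimeras(
    anchors: list[Anchor],
    assembly: dict[str, str],
    min_block: int = 2,
    cm_jump: float = 10.0,
    phys_window_frac: float = 0.2,
) -> list[BreakEvent]:
    """Locate misjoins from marker discordance.

    A break is emitted where physically ordered fully-mapped markers
    split into adjacent blocks of at least ``min_block`` markers that
    (a) belong to different linkage groups, or (b) share a linkage
    group but jump more than ``cm_jump`` centimorgans within less than
    ``phys_window_frac`` of the scaffold length.  The break interval
    runs from the last marker of the left block to the first marker of
    the right block; the chosen break point is the midpoint of the
    longest N-run inside the interval, else the interval midpoint.
    Lone discordant markers never trigger a break.
    """
    events: list[BreakEvent] = []
    for anchor in anchors:
        seq = assembly.get(anchor.scaffold)
        if seq is None:
            continue
        full = sorted(anchor.full_entries(), key=lambda e: e.pos)
        if len(full) < 2 * min_block:
            continue
        # condense into LG runs, discarding runs below min_block (suspects)
        runs: list[list[AnchorEntry]] = []
        for e in full:
            if runs and runs[-1][0].linkage_group == e.linkage_group:
                runs[-1].append(e)
            else:
                runs.append([e])
        big = [r for r in runs if len(r) >= min_block]
        merged: list[list[AnchorEntry]] = []
        for r in big:
            if merged and merged[-1][0].linkage_group == r[0].linkage_group:
                merged[-1].extend(r)
            else:
                merged.append(r)
        intervals: list[tuple[int, int, dict, dict]] = []
        for left, right in zip(merged[:-1], merged[1:]):
            intervals.append(
                (
                    left[-1].pos,
                    right[0].pos,
                    _block_evidence(left),
                    _block_evidence(right),
                )
            )
        # same-LG cM discontinuities, evaluated per map
        window = phys_window_frac * len(seq)
        by_map_lg: dict[tuple[str, int], list[AnchorEntry]] = defaultdict(list)
        for e in full:
            by_map_lg[(e.map_id, e.linkage_group)].append(e)
        for entries in by_map_lg.values():
            entries = sorted(entries, key=lambda e: e.pos)
            for i in range(len(entries) - 1):
                a, b = entries[i], entries[i + 1]
                if (
                    abs(b.cM - a.cM) > cm_jump
                    and (b.pos - a.pos) < window
                    and i + 1 >= min_block
                    and len(entries) - i - 1 >= min_block
                ):
                    intervals.append(
                        (
                            a.pos,
                            b.pos,
                            _block_evidence(entries[: i + 1]),
                            _block_evidence(entries[i + 1 :]),
                        )
                    )
        # merge overlapping intervals from different evidence sources
        intervals.sort(key=lambda t: t[:2])
        kept: list[tuple[int, int, dict, dict]] = []
        for iv in intervals:
            if kept and iv[0] < kept[-1][1]:
                # same junction seen through two evidence routes: intersect
                prev = kept[-1]
                s, e = max(prev[0], iv[0]), min(prev[1], iv[1])
                if s < e:
                    kept[-1] = (s, e, prev[2], prev[3])
                continue
            kept.append(iv)
        for start, end, ev_l, ev_r in kept:
            if end <= start:
                continue
            n_run = _longest_n_run(seq, start, end)
            chosen = (n_run[0] + n_run[1]) // 2 if n_run else (start + end) // 2
            events.append(
                BreakEvent(anchor.scaffold, (start, end), chosen, (ev_l, ev_r))
            )
    return events


def apply_breaks(
    assembly: dict[str, str], events: list[BreakEvent]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Split scaffolds at chosen break points.

    Pieces get deterministic derived names (``<scaffold>_p1`` ...); the
    rename ledger maps every output sequence (broken or not) to its
    source interval, so concatenating the pieces in order reproduces
    the original scaffold byte-for-byte.
    """
    by_scaffold: dict[str, list[int]] = defaultdict(list)
    for ev in events:
        if ev.scaffold not in assembly:
            raise InputError(f"unknown scaffold in break event: {ev.scaffold}")
        if not 0 < ev.chosen_break < len(assembly[ev.scaffold]):
            raise InputError(
                f"break position {ev.chosen_break} outside {ev.scaffold}"
            )
        by_scaffold[ev.scaffold].append(ev.chosen_break)
    out: dict[str, str] = {}
    ledger_rows = []
    for name, seq in assembly.items():
        cuts = sorted(set(by_scaffold.get(name, [])))
        if not cuts:
            out[name] = seq
            ledger_rows.append((name, name, 0, len(seq)))
            continue
        bounds = [0] + cuts + [len(seq)]
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
            piece = f"{name}_p{i}"
            out[piece] = seq[a:b]
            ledger_rows.append((piece, name, a, b))
    ledger = pd.DataFrame(
        ledger_rows, columns=["name", "source", "start", "end"]
    )
    return out, ledger


def lift_placements(
    placements: list[Placement], ledger: pd.DataFrame
) -> list[Placement]:
    """Re-coordinate placements onto broken pieces.

    Placements spanning a break point are dropped (their marker product
    no longer exists as a contiguous locus).
    """
    pieces = defaultdict(list)
    for _, row in ledger.iterrows():
        pieces[row["source"]].append((row["name"], row["start"], row["end"]))
    lifted = []
    for p in placements:
        for name, a, b in pieces.get(p.scaffold, [(p.scaffold, 0, None)]):
            if p.start >= a and (b is None or p.end <= b):
                lifted.append(
                    Placement(
                        p.marker_id,
                        name,
                        p.start - a,
                        p.end - a,
                        p.strand,
                        p.method,
                        p.n_candidate_hits,
                    )
                )
                break
    return lifted


@dataclass
class OrderOrientCall:
    scaffold: str
    chromosome: int
    rank: int
    consensus_cM: float
    orientation: str  # '+', '-', 'unknown'
    n_markers: int
    rho: float
    flags: list[str] = field(default_factory=list)


def _lg_ranges(maps: pd.DataFrame) -> dict[tuple[str, int], tuple[float, float]]:
    out = {}
    for (m, lg), grp in maps.groupby(["map_id", "linkage_group"]):
        out[(m, int(lg))] = (float(grp["cM"].min()), float(grp["cM"].max()))
    return out


def order_and_orient(
    anchors: list[Anchor],
    assignments: list[AssignmentCall],
    maps: pd.DataFrame,
    assembly: dict[str, str] | None = None,
) -> list[OrderOrientCall]:
    """Consensus ordering and orientation of assigned scaffolds.

    Per map, a scaffold's position is the median cM of its fully-mapped
    concordant markers, rescaled to [0, 1] within the linkage group;
    the consensus is the marker-count weighted mean across maps.
    Orientation is the sign of the Spearman rank correlation between
    physical position and rescaled cM pooled over maps; 'unknown' with
    fewer than two distinct genetic positions.  When maps disagree on
    the sign, the map with more distinct cM positions on the scaffold
    wins and the call is flagged "conflict".  Ties in consensus
    position are broken by scaffold length descending and flagged.
    """
    by_scaffold = {a.scaffold: a for a in anchors}
    ranges = _lg_ranges(maps)
    calls: list[OrderOrientCall] = []
    unordered: list[OrderOrientCall] = []
    for call in assignments:
        if call.status != "assigned" or call.chromosome is None:
            continue
        lg = call.chromosome
        anchor = by_scaffold.get(call.scaffold)
        entries = [
            e
            for e in (anchor.full_entries() if anchor else [])
            if e.linkage_group == lg and e.marker_id not in call.suspect_markers
        ]
        if not entries:
            unordered.append(
                OrderOrientCall(
                    call.scaffold, lg, -1, float("nan"), "unknown", 0, float("nan"),
                    ["unordered"],
                )
            )
            continue

        def rescale(e: AnchorEntry) -> float:
            lo, hi = ranges[(e.map_id, e.linkage_group)]
            return (e.cM - lo) / (hi - lo) if hi > lo else 0.5

        by_map: dict[str, list[AnchorEntry]] = defaultdict(list)
        for e in entries:
            by_map[e.map_id].append(e)
        num = den = 0.0
        for m, es in by_map.items():
            num += len(es) * float(np.median([rescale(e) for e in es]))
            den += len(es)
        consensus = num / den

        # orientation from per-map rank correlations: genetic positions are
        # only comparable within one map, so each map with >= 2 distinct cM
        # values on the scaffold votes with the sign of its own correlation
        flags: list[str] = []
        signs: dict[str, tuple[str, int, float]] = {}
        for m, es in by_map.items():
            distinct_cm = len({e.cM for e in es})
            if distinct_cm < 2:
                continue
            r = stats.spearmanr([e.pos for e in es], [e.cM for e in es]).statistic
            if not np.isnan(r) and r != 0:
                signs[m] = ("+" if r > 0 else "-", distinct_cm, float(r))
        if not signs:
            orientation, rho = "unknown", float("nan")
        else:
            weights = {m: n for m, (_, n, _) in signs.items()}
            rho = float(
                sum(weights[m] * signs[m][2] for m in signs) / sum(weights.values())
            )
            if len({s for s, _, _ in signs.values()}) > 1:
                # maps disagree: the map resolving more genetic positions wins
                winner = max(signs.items(), key=lambda kv: kv[1][1])
                orientation = winner[1][0]
                flags.append("conflict")
            else:
                orientation = next(iter(signs.values()))[0]
        calls.append(
            OrderOrientCall(
                call.scaffold, lg, -1, consensus, orientation, len(entries), rho,
                flags,
            )
        )
    # rank within chromosome; ties broken by length descending.  The
    # consensus value places scaffolds coarsely; adjacent pairs are then
    # refined by direct within-map comparison (median cM of two scaffolds in
    # the *same* map is free of the small affine offsets the per-map [0,1]
    # rescaling leaves between maps).
    length = (lambda s: len(assembly[s])) if assembly else (lambda s: 0)

    def pairwise_vote(a: OrderOrientCall, b: OrderOrientCall) -> float:
        """> 0 endorses a before b; marker-count-weighted across maps."""
        ea = by_scaffold.get(a.scaffold)
        eb = by_scaffold.get(b.scaffold)
        if ea is None or eb is None:
            return 0.0
        med = {}
        for anchor, tag in ((ea, 0), (eb, 1)):
            for e in anchor.full_entries():
                if e.linkage_group != a.chromosome:
                    continue
                med.setdefault(e.map_id, ([], []))[tag].append(e.cM)
        vote = 0.0
        for m, (va, vb) in med.items():
            if not va or not vb:
                continue
            da, db = float(np.median(va)), float(np.median(vb))
            if db != da:
                vote += (len(va) + len(vb)) * (1.0 if db > da else -1.0)
        return vote

    out: list[OrderOrientCall] = []
    for lg in sorted({c.chromosome for c in calls}):
        group = [c for c in calls if c.chromosome == lg]
        keyed = sorted(group, key=lambda c: (c.consensus_cM, -length(c.scaffold)))
        for _ in range(len(keyed)):
            swapped = False
            for i in range(len(keyed) - 1):
                if pairwise_vote(keyed[i], keyed[i + 1]) < 0:
                    keyed[i], keyed[i + 1] = keyed[i + 1], keyed[i]
                    swapped = True
            if not swapped:
                break
        seen_cm: dict[float, OrderOrientCall] = {}
        for rank, c in enumerate(keyed, start=1):
            c.rank = rank
            prev = seen_cm.get(round(c.consensus_cM, 9))
            if prev is not None:
                for cc in (prev, c):
                    if "order uncertain" not in cc.flags:
                        cc.flags.append("order uncertain")
            seen_cm[round(c.consensus_cM, 9)] = c
            out.append(c)
        tail = [u for u in unordered if u.chromosome == lg]
        for j, u in enumerate(tail, start=len(keyed) + 1):
            u.rank = j
            out.append(u)
    return out


def build_pseudomolecules(
    assembly: dict[str, str],
    calls: list[OrderOrientCall],
    spacer_length: int = SPACER_LENGTH,
    name_template: str = "Pm{:02d}",
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Concatenate ordered scaffolds into pseudomolecule FASTA + AGP.

    Consecutive components are separated by exactly one spacer of
    ``spacer_length`` N.  Scaffolds with unknown orientation enter as
    '+' but are written with AGP orientation '0' so consumers see the
    uncertainty.  Returns (pseudomolecules, AGP frame, unplaced
    scaffolds).
    """
    placed: set[str] = set()
    pseudos: dict[str, str] = {}
    agp_rows = []
    by_chrom: dict[int, list[OrderOrientCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chromosome].append(c)
    for lg in sorted(by_chrom):
        group = sorted(by_chrom[lg], key=lambda c: c.rank)
        ranks = [c.rank for c in group]
        if len(set(ranks)) != len(ranks):
            raise InputError(f"duplicate ranks on chromosome {lg}")
        obj = name_template.format(lg)
        parts: list[str] = []
        cursor = 0
        part_no = 0
        for i, c in enumerate(group):
            seq = assembly[c.scaffold]
            if c.orientation == "-":
                seq = revcomp(seq)
            if i > 0:
                part_no += 1
                agp_rows.append(
                    [
                        obj,
                        cursor + 1,
                        cursor + spacer_length,
                        part_no,
                        "U",
                        str(spacer_length),
                        "map",
                        "no",
                        "na",
                    ]
                )
                parts.append("N" * spacer_length)
                cursor += spacer_length
            part_no += 1
            orient = {"+": "+", "-": "-", "unknown": "0"}[c.orientation]
            agp_rows.append(
                [obj, cursor + 1, cursor + len(seq), part_no, "W", c.scaffold, 1,
                 len(seq), orient]
            )
            parts.append(seq)
            cursor += len(seq)
            placed.add(c.scaffold)
        pseudos[obj] = "".join(parts)
    agp = pd.DataFrame(agp_rows, columns=AGP_COLUMNS)
    unplaced = {n: s for n, s in assembly.items() if n not in placed}
    return pseudos, agp, unplaced


def rebuild_from_agp(
    agp: pd.DataFrame, scaffolds: dict[str, str]
) -> dict[str, str]:
    """Reconstruct pseudomolecule sequences from AGP + source scaffolds."""
    out: dict[str, list[str]] = defaultdict(list)
    for _, row in agp.iterrows():
        if row["component_type"] == "U":
            out[row["object"]].append("N" * int(row["component_id"]))
        else:
            seq = scaffolds[row["component_id"]][
                int(row["component_beg"]) - 1 : int(row["component_end"])
            ]
            if row["orientation"] == "-":
                seq = revcomp(seq)
            out[row["object"]].append(seq)
    return {k: "".join(v) for k, v in out.items()}


def placements_to_object_coords(
    placements: list[Placement], agp: pd.DataFrame
) -> pd.DataFrame:
    """Marker positions lifted from scaffolds onto pseudomolecules.

    Returns columns ``marker_id, object, pos`` (midpoint, 0-based).
    Placements on unintegrated scaffolds are omitted.
    """
    comp: dict[str, tuple[str, int, int, str]] = {}
    for _, row in agp.iterrows():
        if row["component_type"] == "W":
            comp[row["component_id"]] = (
                row["object"],
                int(row["object_beg"]) - 1,
                int(row["object_end"]),
                row["orientation"],
            )
    rows = []
    for p in placements:
        info = comp.get(p.scaffold)
        if info is None:
            continue
        obj, beg, end, orient = info
        mid = (p.start + p.end) // 2
        if orient == "-":
            pos = beg + (end - beg - 1 - mid)
        else:
            pos = beg + mid
        rows.append({"marker_id": p.marker_id, "object": obj, "pos": pos})
    return pd.DataFrame(rows)


def anchoring_report(
    object_placements: pd.DataFrame,
    maps: pd.DataFrame,
    agp: pd.DataFrame,
    pseudomolecules: dict[str, str],
) -> pd.DataFrame:
    """Per map x chromosome anchoring statistics with a totals row.

    Reports markers integrated, scaffolds anchored, genetic distance
    covered (max - min cM among fully-mapped markers), physical span
    covered by the integrated markers and its percentage of the
    pseudomolecule length.
    """
    scaffold_of: dict[str, str] = {}
    for _, row in agp.iterrows():
        if row["component_type"] == "W":
            scaffold_of[row["component_id"]] = row["object"]
    merged = object_placements.merge(maps, on="marker_id", how="inner")
    rows = []
    for map_id, mgrp in merged.groupby("map_id", sort=False):
        for obj in sorted(pseudomolecules):
            grp = mgrp[mgrp["object"] == obj]
            if len(grp) == 0:
                rows.append(
                    {
                        "map_id": map_id,
                        "chromosome": obj,
                        "markers": 0,
                        "scaffolds_anchored": 0,
                        "cM_span": 0.0,
                        "bp_span": 0,
                        "pct_of_pseudomolecule": 0.0,
                    }
                )
                continue
            full = grp[grp["level"] == "full"]
            cm_span = float(full["cM"].max() - full["cM"].min()) if len(full) else 0.0
            bp_span = int(grp["pos"].max() - grp["pos"].min())
            n_scaf = len(_scaffold_lookup(grp, agp))
            rows.append(
                {
                    "map_id": map_id,
                    "chromosome": obj,
                    "markers": int(len(grp)),
                    "scaffolds_anchored": n_scaf,
                    "cM_span": cm_span,
                    "bp_span": bp_span,
                    "pct_of_pseudomolecule": round(
                        100.0 * bp_span / len(pseudomolecules[obj]), 1
                    ),
                }
            )
        sub = [r for r in rows if r["map_id"] == map_id]
        total_len = sum(len(s) for s in pseudomolecules.values())
        rows.append(
            {
                "map_id": map_id,
                "chromosome": "total",
                "markers": sum(r["markers"] for r in sub),
                "scaffolds_anchored": sum(r["scaffolds_anchored"] for r in sub),
                "cM_span": round(sum(r["cM_span"] for r in sub), 6),
                "bp_span": sum(r["bp_span"] for r in sub),
                "pct_of_pseudomolecule": round(
                    100.0 * sum(r["bp_span"] for r in sub) / total_len, 1
                ),
            }
        )
    return pd.DataFrame(rows)


def _scaffold_lookup(object_grp: pd.DataFrame, agp: pd.DataFrame) -> set[str]:
    """Source scaffolds containing the given object-coordinate markers."""
    comps = agp[agp["component_type"] == "W"]
    found = set()
    for _, row in object_grp.iterrows():
        hit = comps[
            (comps["object"] == row["object"])
            & (comps["object_beg"] - 1 <= row["pos"])
            & (comps["object_end"] > row["pos"])
        ]
        if len(hit):
            found.add(hit.iloc[0]["component_id"])
    return found
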