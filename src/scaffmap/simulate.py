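"""Synthetic truth genomes with known misassemblies, maps and variants.

The generator emulates, at desk scale, the study design used to refine
a chromosome-scale plant assembly with linkage maps and resequencing:

* an 8-chromosome genome (hundreds of kb to ~1 Mb per chromosome) whose
  genetic-to-physical (Marey) function is monotone with a zero-slope
  centromeric plateau (recombination suppression);
* a scaffold set carrying planted interchromosomal chimeras, wrong
  orientations, unplaced pieces and N-run gaps whose true insert is
  recorded;
* several linkage maps of markers (primer pairs or flanking sequence)
  with configurable bin-level fraction, cM noise and mismapping rate;
* patch contigs that span gaps (plus decoys failing the acceptance rule
  in exactly one recorded way) and planted homozygous SNPs/indels.

Every output is a deterministic function of the configuration and seed,
and a truth ledger records the provenance of every scaffold base so
each downstream inference step can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .seqio import revcomp, write_fasta, write_vcf

BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """A simulation parameter is out of range; the message names the field."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenomeConfig:
    n_chromosomes: int = 8
    length_range: tuple[int, int] = (800_000, 1_200_000)
    gc_fraction: float = 0.38
    centromere_fraction: float = 0.15
    map_length_cm: tuple[float, float] = (45.0, 80.0)
    n_control_points: int = 4  # per chromosome arm

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.length_range[0] < 10_000:
            raise ConfigError("length_range minimum must be >= 10 kb")
        if not 0 < self.centromere_fraction < 0.5:
            raise ConfigError("centromere_fraction must be in (0, 0.5)")
        if not 0 < self.gc_fraction < 1:
            raise ConfigError("gc_fraction must be in (0, 1)")


@dataclass
class FragmentationConfig:
    n_scaffolds: int = 40
    n_chimeras: int = 3
    n_flipped: int = 6
    n_unplaced: int = 3
    n_gaps: int = 30
    gap_n_run_range: tuple[int, int] = (50, 500)
    gap_insert_range: tuple[int, int] = (100, 800)

    def validate(self, genome: "GenomeConfig | None" = None) -> None:
        if self.n_scaffolds < 1:
            raise ConfigError("n_scaffolds must be >= 1")
        if self.n_chimeras < 0 or self.n_flipped < 0 or self.n_unplaced < 0:
            raise ConfigError("n_chimeras/n_flipped/n_unplaced must be >= 0")
        if self.n_chimeras * 2 + self.n_unplaced > self.n_scaffolds + self.n_chimeras:
            raise ConfigError("n_chimeras/n_unplaced infeasible for n_scaffolds")
        if genome is not None and self.n_chimeras > 0 and genome.n_chromosomes < 2:
            raise ConfigError("n_chimeras requires >= 2 chromosomes")
        if self.gap_n_run_range[0] < 1:
            raise ConfigError("gap_n_run_range minimum must be >= 1")


@dataclass
class LinkageMapConfig:
    #: markers per chromosome for each simulated map (one entry per map)
    markers_per_chromosome: tuple[int, ...] = (45, 60, 15, 25)
    bin_fraction: float = 0.2
    cm_noise_sd: float = 0.0
    mismap_rate: float = 0.0
    primer_fraction: float = 0.7
    primer_length: int = 20
    product_size: tuple[int, int] = (140, 320)
    flank_length: int = 150
    min_marker_spacing: int = 1_000

    def validate(self) -> None:
        if any(n < 0 for n in self.markers_per_chromosome):
            raise ConfigError("markers_per_chromosome entries must be >= 0")
        if self.cm_noise_sd < 0:
            raise ConfigError("cm_noise_sd must be >= 0")
        if not 0 <= self.bin_fraction <= 1:
            raise ConfigError("bin_fraction must be in [0, 1]")
        if not 0 <= self.mismap_rate <= 1:
            raise ConfigError("mismap_rate must be in [0, 1]")


@dataclass
class PatchContigConfig:
    fraction_spanning: float = 0.8
    n_decoys: int = 9
    decoy_classes: tuple[str, ...] = ("low_identity", "low_anchor", "one_sided")
    flank_anchor_range: tuple[int, int] = (120, 300)

    def validate(self) -> None:
        if not 0 <= self.fraction_spanning <= 1:
            raise ConfigError("fraction_spanning must be in [0, 1]")
        known = {"low_identity", "low_anchor", "one_sided"}
        if not set(self.decoy_classes) <= known:
            raise ConfigError(f"decoy_classes must be among {sorted(known)}")


@dataclass
class VariantConfig:
    n_snps: int = 40
    n_indels: int = 30
    indel_size_range: tuple[int, int] = (1, 6)
    min_site_spacing: int = 10

    def validate(self) -> None:
        if self.n_snps < 0 or self.n_indels < 0:
            raise ConfigError("n_snps/n_indels must be >= 0")
        if self.indel_size_range[0] < 1:
            raise ConfigError("indel_size_range minimum must be >= 1")


# ---------------------------------------------------------------------------
# truth ledger types


@dataclass
class ProvenanceRecord:
    """One constituent of a scaffold, in final scaffold orientation.

    ``kind`` is ``"segment"`` (truth interval on ``strand``) or ``"gap"``
    (an N-run replacing truth interval [start, end) of the chromosome).
    """

    kind: str
    scaf_start: int
    scaf_end: int
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class PlantedJunction:
    scaffold: str
    position: int  # scaffold coordinate of the chimeric join
    left_chrom: str
    right_chrom: str


@dataclass
class PlantedGap:
    scaffold: str
    start: int  # scaffold coordinates of the N-run
    end: int
    true_insert: str
    chrom: str


@dataclass
class PlantedVariant:
    seq_name: str
    position: int  # 0-based position in the corrupted sequence
    ref: str       # corrupted allele
    alt: str       # true allele
    kind: str      # "SNP" or "indel"


@dataclass
class MarkerTruth:
    marker_id: str
    chrom: str
    position: int
    scaffold: str | None
    scaffold_pos: int | None
    mismapped: bool


@dataclass
class TruthSet:
    chromosomes: dict[str, str]
    marey_functions: dict[str, Callable]
    marey_total_cm: dict[str, float]
    centromere_intervals: dict[str, tuple[int, int]]
    rng_seed: int
    scaffold_provenance: dict[str, list[ProvenanceRecord]] = field(default_factory=dict)
    scaffold_strand: dict[str, str] = field(default_factory=dict)
    unplaced_scaffolds: set[str] = field(default_factory=set)
    planted_junctions: list[PlantedJunction] = field(default_factory=list)
    patchable_gaps: list[PlantedGap] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    marker_truth: dict[str, MarkerTruth] = field(default_factory=dict)
    contig_truth: dict[str, dict] = field(default_factory=dict)

    def truth_location(self, scaffold: str, pos: int) -> ProvenanceRecord | None:
        """Provenance record covering scaffold coordinate ``pos``."""
        for rec in self.scaffold_provenance.get(scaffold, []):
            if rec.scaf_start <= pos < rec.scaf_end:
                return rec
        return None


# ---------------------------------------------------------------------------
# genome simulation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode()


def _make_marey(
    rng: np.random.Generator,
    length: int,
    total_cm: float,
    cen_frac: float,
    n_ctrl: int,
) -> tuple[Callable, tuple[int, int]]:
    """Monotone piecewise-cubic Marey function with a flat centromere.

    Control abscissae bracket a centromeric interval; genetic increments
    between control points are random positive weights, zero across the
    centromere, scaled to the configured total.  PCHIP through these
    points is monotone, continuous, exactly flat over the plateau, and
    its slope integrates to ``total_cm`` by construction.
    """
    cen_len = int(cen_frac * length)
    cen_mid = int(length * rng.uniform(0.35, 0.65))
    cen_start = max(1, cen_mid - cen_len // 2)
    cen_end = min(length - 1, cen_start + cen_len)
    left = np.linspace(0, cen_start, n_ctrl + 1)
    right = np.linspace(cen_end, length, n_ctrl + 1)
    xs = np.concatenate([left, right])
    # positive increments on every interval except the centromeric one
    w = rng.uniform(0.5, 1.5, size=len(xs) - 1)
    w[n_ctrl] = 0.0  # the [cen_start, cen_end] interval
    ys = np.concatenate([[0.0], np.cumsum(w)])
    ys = ys / ys[-1] * total_cm
    return PchipInterpolator(xs, ys), (cen_start, cen_end)


def simulate_truth_genome(config: GenomeConfig | None = None, seed: int = 0) -> TruthSet:
    """Generate a truth genome with per-chromosome Marey functions."""
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    mareys: dict[str, Callable] = {}
    totals: dict[str, float] = {}
    cens: dict[str, tuple[int, int]] = {}
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        total_cm = float(rng.uniform(*config.map_length_cm))
        chromosomes[name] = _random_sequence(rng, length, config.gc_fraction)
        mareys[name], cens[name] = _make_marey(
            rng, length, total_cm, config.centromere_fraction, config.n_control_points
        )
        totals[name] = total_cm
    return TruthSet(
        chromosomes=chromosomes,
        marey_functions=mareys,
        marey_total_cm=totals,
        centromere_intervals=cens,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# scaffold fragmentation


def _cut_positions(
    rng: np.random.Generator, length: int, n_segments: int, min_len: int = 20_000
) -> list[tuple[int, int]]:
    if n_segments <= 1:
        return [(0, length)]
    for _ in range(100):
        cuts = np.sort(rng.integers(min_len, length - min_len, size=n_segments - 1))
        bounds = np.concatenate([[0], cuts, [length]])
        if np.all(np.diff(bounds) >= min_len):
            return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    # fall back to even cuts
    bounds = np.linspace(0, length, n_segments + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def fragment_into_scaffolds(
    truth: TruthSet,
    config: FragmentationConfig | None = None,
    seed: int = 1,
) -> dict[str, str]:
    """Cut the truth genome into scaffolds with planted misassemblies.

    Populates the truth ledger (provenance, junctions, gaps, strands)
    and returns the scaffold sequences.  Chimeric scaffolds concatenate
    two segments from different chromosomes with the junction recorded;
    flipped scaffolds are reverse-complemented with their provenance
    strand set to '-'; N-run gaps replace a recorded truth interval
    whose sequence becomes the gap's true insert (the N-run length is
    drawn independently of the insert length).  Gaps are planted only
    on plain scaffolds so that each planted defect exercises exactly
    one downstream repair path.
    """
    config = config or FragmentationConfig()
    config.validate(genome=None)
    rng = np.random.default_rng(seed)
    chroms = list(truth.chromosomes)
    if config.n_chimeras > 0 and len(chroms) < 2:
        raise ConfigError("n_chimeras requires >= 2 chromosomes")

    # total segments: chimeras consume two each
    n_segments = config.n_scaffolds + config.n_chimeras
    base = n_segments // len(chroms)
    extra = n_segments - base * len(chroms)
    seg_counts = {c: base + (1 if i < extra else 0) for i, c in enumerate(chroms)}
    segments: list[tuple[str, int, int]] = []
    for c in chroms:
        for a, b in _cut_positions(rng, len(truth.chromosomes[c]), seg_counts[c]):
            segments.append((c, a, b))

    # pick chimera partner pairs from different chromosomes
    order = rng.permutation(len(segments))
    seg_by_chrom: dict[str, list[int]] = {}
    for idx in order:
        seg_by_chrom.setdefault(segments[idx][0], []).append(int(idx))
    chimera_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for _ in range(config.n_chimeras):
        avail = sorted(
            (c for c in seg_by_chrom if any(i not in used for i in seg_by_chrom[c])),
            key=lambda c: -sum(i not in used for i in seg_by_chrom[c]),
        )
        if len(avail) < 2:
            raise ConfigError("n_chimeras infeasible: not enough segments")
        a = next(i for i in seg_by_chrom[avail[0]] if i not in used)
        b = next(i for i in seg_by_chrom[avail[1]] if i not in used)
        used.update((a, b))
        chimera_pairs.append((a, b))

    remaining = [i for i in range(len(segments)) if i not in used]
    scaffolds: dict[str, list[ProvenanceRecord]] = {}
    k = 0

    def new_name() -> str:
        nonlocal k
        k += 1
        return f"scaffold_{k}"

    for a, b in chimera_pairs:
        ca, sa, ea = segments[a]
        cb, sb, eb = segments[b]
        name = new_name()
        scaffolds[name] = [
            ProvenanceRecord("segment", 0, ea - sa, ca, sa, ea, "+"),
            ProvenanceRecord("segment", ea - sa, (ea - sa) + (eb - sb), cb, sb, eb, "+"),
        ]
        truth.planted_junctions.append(PlantedJunction(name, ea - sa, ca, cb))
    for i in remaining:
        c, s, e = segments[i]
        name = new_name()
        scaffolds[name] = [ProvenanceRecord("segment", 0, e - s, c, s, e, "+")]

    names = list(scaffolds)
    plain = [n for n in names if not any(j.scaffold == n for j in truth.planted_junctions)]

    # unplaced: the shortest plain scaffolds
    plain_sorted = sorted(plain, key=lambda n: scaffolds[n][-1].scaf_end)
    truth.unplaced_scaffolds = set(plain_sorted[: config.n_unplaced])

    # gaps on plain scaffolds (placed or unplaced), interior positions
    gap_hosts = [n for n in plain for _ in range(1)]
    margin = 5_000
    planted = 0
    attempts = 0
    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    while planted < config.n_gaps and attempts < config.n_gaps * 50:
        attempts += 1
        host = gap_hosts[int(rng.integers(len(gap_hosts)))]
        rec = scaffolds[host][0]
        length = rec.scaf_end
        ins_len = int(rng.integers(*config.gap_insert_range))
        if length < 2 * margin + ins_len + 1:
            continue
        pos = int(rng.integers(margin, length - margin - ins_len))
        if any(pos < e + 2_000 and s - 2_000 < pos + ins_len for s, e in taken[host]):
            continue
        taken[host].append((pos, pos + ins_len))
        planted += 1

    for host, intervals in taken.items():
        if not intervals:
            continue
        intervals.sort()
        rec = scaffolds[host][0]
        chrom, t0 = rec.chrom, rec.start
        new_records: list[ProvenanceRecord] = []
        cursor_t = rec.start
        cursor_s = 0
        for s, e in intervals:
            n_len = int(rng.integers(*config.gap_n_run_range))
            # segment before the gap
            seg_len = (t0 + s) - cursor_t
            new_records.append(
                ProvenanceRecord(
                    "segment", cursor_s, cursor_s + seg_len, chrom, cursor_t, t0 + s, "+"
                )
            )
            cursor_s += seg_len
            new_records.append(
                ProvenanceRecord("gap", cursor_s, cursor_s + n_len, chrom, t0 + s, t0 + e)
            )
            insert = truth.chromosomes[chrom][t0 + s : t0 + e]
            truth.patchable_gaps.append(
                PlantedGap(host, cursor_s, cursor_s + n_len, insert, chrom)
            )
            cursor_s += n_len
            cursor_t = t0 + e
        seg_len = rec.end - cursor_t
        new_records.append(
            ProvenanceRecord(
                "segment", cursor_s, cursor_s + seg_len, chrom, cursor_t, rec.end, "+"
            )
        )
        scaffolds[host] = new_records

    # flips: plain, placed, gap-free scaffolds reverse-complemented
    flip_candidates = [
        n
        for n in plain
        if n not in truth.unplaced_scaffolds and not taken[n]
    ]
    if len(flip_candidates) < config.n_flipped:
        raise ConfigError("n_flipped infeasible: not enough plain scaffolds")
    flipped = set(
        rng.choice(flip_candidates, size=config.n_flipped, replace=False).tolist()
    )

    out: dict[str, str] = {}
    for name, records in scaffolds.items():
        parts = []
        for rec in records:
            if rec.kind == "segment":
                parts.append(truth.chromosomes[rec.chrom][rec.start : rec.end])
            else:
                parts.append("N" * (rec.scaf_end - rec.scaf_start))
        seq = "".join(parts)
        strand = "+"
        if name in flipped:
            seq = revcomp(seq)
            strand = "-"
            total = len(seq)
            records = [
                ProvenanceRecord(
                    r.kind,
                    total - r.scaf_end,
                    total - r.scaf_start,
                    r.chrom,
                    r.start,
                    r.end,
                    "-" if r.kind == "segment" else "+",
                )
                for r in reversed(records)
            ]
        truth.scaffold_provenance[name] = records
        truth.scaffold_strand[name] = strand
        out[name] = seq
    return out


def reassemble_from_ledger(truth: TruthSet, scaffolds: dict[str, str]) -> dict[str, str]:
    """Reconstruct truth chromosome substrings from the provenance ledger.

    Returns per-scaffold sequences rebuilt from the truth genome; N-run
    gap records are reproduced as N-runs, so the result must equal the
    emitted scaffold byte-for-byte.
    """
    rebuilt: dict[str, str] = {}
    for name, records in truth.scaffold_provenance.items():
        if truth.scaffold_strand[name] == "-":
            records = list(reversed(records))
        parts = []
        for rec in records:
            if rec.kind == "segment":
                parts.append(truth.chromosomes[rec.chrom][rec.start : rec.end])
            else:
                parts.append("N" * (rec.scaf_end - rec.scaf_start))
        seq = "".join(parts)
        if truth.scaffold_strand[name] == "-":
            seq = revcomp(seq)
        rebuilt[name] = seq
    return rebuilt


# ---------------------------------------------------------------------------
# linkage maps


def _scaffold_position(truth: TruthSet, chrom: str, pos: int) -> tuple[str, int] | None:
    """Locate a truth coordinate on the emitted scaffold set."""
    for name, records in truth.scaffold_provenance.items():
        for rec in records:
            if rec.kind != "segment" or rec.chrom != chrom:
                continue
            if rec.start <= pos < rec.end:
                if rec.strand == "+":
                    return name, rec.scaf_start + (pos - rec.start)
                return name, rec.scaf_start + (rec.end - 1 - pos)
    return None


def simulate_linkage_maps(
    truth: TruthSet,
    config: LinkageMapConfig | None = None,
    seed: int = 2,
):
    """Simulate linkage maps over the fragmented scaffold set.

    Returns a markers DataFrame with columns ``marker_id, map_id,
    linkage_group, cM, level, primer_fwd, primer_rev, flank_seq,
    marker_class``.  Marker cM equals the truth Marey value plus
    Gaussian noise clipped to the map length; an exact
    ``round(n * bin_fraction)`` count per map/chromosome is flagged
    bin-level, and ``round(n * mismap_rate)`` markers are deliberately
    emitted with a wrong linkage group (recorded in the truth ledger).
    Each marker carries either a primer pair or a flanking sequence.
    """
    import pandas as pd

    config = config or LinkageMapConfig()
    config.validate()
    if not truth.scaffold_provenance:
        raise ConfigError("fragment_into_scaffolds must run before map simulation")
    rng = np.random.default_rng(seed)
    chroms = list(truth.chromosomes)
    lg_of = {c: i + 1 for i, c in enumerate(chroms)}
    half_prod = config.product_size[1] // 2 + config.primer_length

    # placeable truth intervals: segments of placed scaffolds, away from edges
    placeable: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for name, records in truth.scaffold_provenance.items():
        if name in truth.unplaced_scaffolds:
            continue
        for rec in records:
            if rec.kind != "segment":
                continue
            a, b = rec.start + half_prod + 10, rec.end - half_prod - 10
            if b > a:
                placeable[rec.chrom].append((a, b))

    rows = []
    mid = 0
    for m, n_per_chrom in enumerate(config.markers_per_chromosome):
        map_id = f"map{m + 1}"
        for chrom in chroms:
            intervals = placeable[chrom]
            if not intervals:
                if n_per_chrom > 0:
                    raise ConfigError(f"no placeable sites on {chrom}")
                continue
            weights = np.array([b - a for a, b in intervals], float)
            weights /= weights.sum()
            positions: list[int] = []
            tries = 0
            while len(positions) < n_per_chrom:
                tries += 1
                if tries > n_per_chrom * 200:
                    raise ConfigError(
                        f"markers_per_chromosome too dense for {chrom} ({map_id})"
                    )
                ival = intervals[int(rng.choice(len(intervals), p=weights))]
                p = int(rng.integers(ival[0], ival[1]))
                if all(abs(p - q) >= config.min_marker_spacing for q in positions):
                    positions.append(p)
            positions.sort()
            n = len(positions)
            n_bin = int(round(n * config.bin_fraction))
            n_mis = int(round(n * config.mismap_rate))
            bin_idx = set(rng.choice(n, size=n_bin, replace=False).tolist())
            mis_idx = set(rng.choice(n, size=n_mis, replace=False).tolist())
            total_cm = truth.marey_total_cm[chrom]
            for j, pos in enumerate(positions):
                mid += 1
                marker_id = f"{map_id}_mk{mid:05d}"
                cm = float(truth.marey_functions[chrom](pos))
                if config.cm_noise_sd > 0:
                    cm += float(rng.normal(0, config.cm_noise_sd))
                cm = float(np.clip(cm, 0.0, total_cm))
                lg = lg_of[chrom]
                mismapped = j in mis_idx
                if mismapped and len(chroms) > 1:
                    other = [c for c in chroms if c != chrom]
                    wrong = other[int(rng.integers(len(other)))]
                    lg = lg_of[wrong]
                    cm = float(rng.uniform(0, truth.marey_total_cm[wrong]))
                primer_fwd = primer_rev = flank = ""
                if rng.random() < config.primer_fraction:
                    prod = int(rng.integers(*config.product_size))
                    left = pos - prod // 2
                    template = truth.chromosomes[chrom][left : left + prod]
                    primer_fwd = template[: config.primer_length]
                    primer_rev = revcomp(template[-config.primer_length :])
                    marker_class = "SSR"
                else:
                    half = config.flank_length // 2
                    flank = truth.chromosomes[chrom][pos - half : pos + half]
                    marker_class = "SNP"
                loc = _scaffold_position(truth, chrom, pos)
                truth.marker_truth[marker_id] = MarkerTruth(
                    marker_id,
                    chrom,
                    pos,
                    loc[0] if loc else None,
                    loc[1] if loc else None,
                    mismapped,
                )
                rows.append(
                    {
                        "marker_id": marker_id,
                        "map_id": map_id,
                        "linkage_group": lg,
                        "cM": cm,
                        "level": "bin" if j in bin_idx else "full",
                        "primer_fwd": primer_fwd,
                        "primer_rev": primer_rev,
                        "flank_seq": flank,
                        "marker_class": marker_class,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patch contigs


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = max(1, int(round(rate * len(seq))))
    idx = rng.choice(len(seq), size=n_mut, replace=False)
    for i in idx:
        cur = arr[i]
        choices = [b for b in BASES if b != cur]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_patch_contigs(
    truth: TruthSet,
    scaffolds: dict[str, str],
    config: PatchContigConfig | None = None,
    seed: int = 3,
) -> dict[str, str]:
    """Contigs that span planted gaps, plus decoys that must be rejected.

    A spanning contig is the true insert flanked by exact copies of the
    gap flanks, sized so the anchored fraction clears the 1/3 rule.
    Decoys fail in exactly one recorded way: ``low_identity`` (flanks
    mutated to ~90% identity), ``low_anchor`` (a long unanchored middle
    pushes the anchored fraction below 1/3) or ``one_sided`` (the right
    flank is random sequence).  The truth ledger records each contig's
    target gap and decoy class.
    """
    config = config or PatchContigConfig()
    config.validate()
    if not truth.patchable_gaps:
        raise ConfigError("no planted gaps to build contigs for")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    n_span = int(round(config.fraction_spanning * len(truth.patchable_gaps)))
    span_idx = set(rng.choice(len(truth.patchable_gaps), n_span, replace=False).tolist())

    def flanks(gap: PlantedGap, a: int, b: int) -> tuple[str, str]:
        seq = scaffolds[gap.scaffold]
        return seq[gap.start - a : gap.start], seq[gap.end : gap.end + b]

    ci = 0
    for gi, gap in enumerate(truth.patchable_gaps):
        if gi not in span_idx:
            continue
        ci += 1
        a = int(rng.integers(*config.flank_anchor_range))
        b = int(rng.integers(*config.flank_anchor_range))
        # keep anchored fraction comfortably above 1/3
        while (a + b) / (a + b + len(gap.true_insert)) < 0.4:
            a += 50
            b += 50
        left, right = flanks(gap, a, b)
        name = f"contig_{ci:04d}"
        contigs[name] = left + gap.true_insert + right
        truth.contig_truth[name] = {
            "gap_index": gi,
            "scaffold": gap.scaffold,
            "decoy_class": None,
        }
    for d in range(config.n_decoys):
        ci += 1
        gi = int(rng.integers(len(truth.patchable_gaps)))
        gap = truth.patchable_gaps[gi]
        cls = config.decoy_classes[d % len(config.decoy_classes)]
        a = int(rng.integers(*config.flank_anchor_range))
        b = int(rng.integers(*config.flank_anchor_range))
        left, right = flanks(gap, a, b)
        if cls == "low_identity":
            seq = _mutate(rng, left, 0.10) + gap.true_insert + _mutate(rng, right, 0.10)
        elif cls == "low_anchor":
            middle = _random_sequence(rng, 4 * (a + b), 0.4)
            seq = left + middle + right
        else:  # one_sided
            seq = left + gap.true_insert + _random_sequence(rng, b, 0.4)
        name = f"contig_{ci:04d}"
        contigs[name] = seq
        truth.contig_truth[name] = {
            "gap_index": gi,
            "scaffold": gap.scaffold,
            "decoy_class": cls,
        }
    return contigs


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    truth: TruthSet,
    assembly: dict[str, str],
    config: VariantConfig | None = None,
    seed: int = 4,
) -> tuple[dict[str, str], list[tuple[str, int, str, str, str]]]:
    """Plant homozygous SNP and indel errors into an assembly.

    Returns the corrupted assembly and VCF-style correction records
    (chrom, pos 1-based, REF = corrupted allele(s), ALT = true
    allele(s), GT "1/1") whose application restores the input
    byte-exactly.  Sites are at least ``min_site_spacing`` apart and
    outside N-runs; an indel labelled "deletion" means the corrupted
    sequence gained bases relative to the truth (the correction deletes
    them), and vice versa for insertions.
    """
    config = config or VariantConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    names = sorted(assembly)
    lengths = np.array([len(assembly[n]) for n in names], float)
    probs = lengths / lengths.sum()
    total = config.n_snps + config.n_indels
    chosen: dict[str, list[tuple[int, str]]] = {n: [] for n in names}
    kinds = ["SNP"] * config.n_snps + ["indel"] * config.n_indels
    rng.shuffle(kinds)
    margin = 50
    attempts = 0
    placed = 0
    while placed < total:
        attempts += 1
        if attempts > total * 1000:
            raise ConfigError("insufficient eligible variant sites")
        n = names[int(rng.choice(len(names), p=probs))]
        seq = assembly[n]
        if len(seq) < 2 * margin + 20:
            continue
        pos = int(rng.integers(margin, len(seq) - margin - 10))
        window = seq[pos - config.min_site_spacing : pos + config.min_site_spacing + 10]
        if "N" in window:
            continue
        if any(
            abs(pos - p) < config.min_site_spacing + 10 for p, _ in chosen[n]
        ):
            continue
        chosen[n].append((pos, kinds[placed]))
        placed += 1

    corrupted: dict[str, str] = {}
    vcf_records: list[tuple[str, int, str, str, str]] = []
    for n in names:
        seq = assembly[n]
        sites = sorted(chosen[n])
        parts = []
        last = 0
        offset = 0  # corrupted minus original coordinates so far
        for pos, kind in sites:
            parts.append(seq[last:pos])
            if kind == "SNP":
                true_base = seq[pos]
                wrong = rng.choice([b for b in "ACGT" if b != true_base])
                parts.append(str(wrong))
                corr_pos = pos + offset
                vcf_records.append((n, corr_pos + 1, str(wrong), true_base, "1/1"))
                truth.planted_variants.append(
                    PlantedVariant(n, corr_pos, str(wrong), true_base, "SNP")
                )
                last = pos + 1
            else:
                size = int(rng.integers(*config.indel_size_range))
                anchor = seq[pos]
                if rng.random() < 0.5:
                    # corrupted gains bases: correction is a deletion
                    extra = _random_sequence(rng, size, 0.4)
                    parts.append(anchor + extra)
                    corr_pos = pos + offset
                    vcf_records.append(
                        (n, corr_pos + 1, anchor + extra, anchor, "1/1")
                    )
                    truth.planted_variants.append(
                        PlantedVariant(n, corr_pos, anchor + extra, anchor, "indel")
                    )
                    offset += size
                    last = pos + 1
                else:
                    # corrupted loses bases: correction is an insertion
                    lost = seq[pos + 1 : pos + 1 + size]
                    parts.append(anchor)
                    corr_pos = pos + offset
                    vcf_records.append((n, corr_pos + 1, anchor, anchor + lost, "1/1"))
                    truth.planted_variants.append(
                        PlantedVariant(n, corr_pos, anchor, anchor + lost, "indel")
                    )
                    offset -= size
                    last = pos + 1 + size
            # recompute offset contribution handled above
        parts.append(seq[last:])
        corrupted[n] = "".join(parts)
    vcf_records.sort(key=lambda r: (r[0], r[1]))
    return corrupted, vcf_records


# ---------------------------------------------------------------------------
# output bundle


def write_outputs(
    outdir: str | Path,
    truth: TruthSet,
    scaffolds: dict[str, str],
    markers=None,
    contigs: dict[str, str] | None = None,
    corrupted: dict[str, str] | None = None,
    vcf_records=None,
) -> None:
    """Write scaffolds/markers/contigs/VCF plus a truth-ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scaffolds, outdir / "scaffolds.fasta")
    if markers is not None:
        markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    if contigs:
        write_fasta(contigs, outdir / "contigs.fasta")
    if corrupted is not None and vcf_records is not None:
        write_fasta(corrupted, outdir / "corrupted.fasta")
        write_vcf(
            vcf_records,
            {n: len(s) for n, s in corrupted.items()},
            outdir / "corrections.vcf",
        )
    ledger = {
        "rng_seed": truth.rng_seed,
        "chromosome_lengths": {c: len(s) for c, s in truth.chromosomes.items()},
        "centromere_intervals": truth.centromere_intervals,
        "scaffold_strand": truth.scaffold_strand,
        "unplaced_scaffolds": sorted(truth.unplaced_scaffolds),
        "scaffold_provenance": {
            n: [asdict(r) for r in recs]
            for n, recs in truth.scaffold_provenance.items()
        },
        "planted_junctions": [asdict(j) for j in truth.planted_junctions],
        "patchable_gaps": [
            {k: v for k, v in asdict(g).items() if k != "true_insert"}
            for g in truth.patchable_gaps
        ],
        "planted_variants": [asdict(v) for v in truth.planted_variants],
        "contig_truth": truth.contig_truth,
    }
    (outdir / "truth_ledger.json").write_text(json.dumps(ledger, indent=1))
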