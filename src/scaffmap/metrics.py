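"""Assembly contiguity and anchoring metrics.

Follows the naming convention of the peach genome releases, where the
N50 is the *number* of sequences whose cumulative length reaches half
the assembly and the L50 is the *length* of the sequence at that point
— the reverse of the more common usage.  ``n50_l50`` implements this
convention; set ``conventional=True`` to get the swapped (common)
naming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: shared with gap patching so "contig" means the same everywhere
DEFAULT_MIN_N_RUN = 10


@dataclass
class AssemblyMetrics:
    n_scaffolds: int
    n_contigs: int
    scaffold_total_bp: int
    contig_total_bp: int
    scaffold_n50: int
    scaffold_l50: int
    contig_n50: int
    contig_l50: int
    n_scaffolds_over_50kb: int
    percent_in_scaffolds_over_50kb: float
    mapped_bp: int | None = None
    mapped_percent: float | None = None
    oriented_bp: int | None = None
    oriented_percent: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def split_into_contigs(
    assembly: dict[str, str] | str, min_n_run: int = DEFAULT_MIN_N_RUN
) -> list[int]:
    """Contig lengths obtained by cutting sequences at N-runs >= ``min_n_run``.

    N-runs shorter than the threshold are retained inside contigs and count
    as contig bases.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    if isinstance(assembly, str):
        assembly = {"seq": assembly}
    cutter = re.compile("N{%d,}" % min_n_run)
    lengths: list[int] = []
    for seq in assembly.values():
        for piece in cutter.split(seq):
            if piece:
                lengths.append(len(piece))
    return lengths


def n50_l50(lengths: Sequence[int], conventional: bool = False) -> tuple[int, int]:
    """(N50, L50) of a length multiset.

    Sort descending and accumulate; the sequence at which the cumulative sum
    first reaches half the total defines both values.  Returns
    ``(count, length)`` — the release convention — or ``(length, count)``
    with ``conventional=True``.
    """
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for i, l in enumerate(ordered, start=1):
        acc += l
        if acc >= half:
            return (l, i) if conventional else (i, l)
    raise AssertionError("unreachable")


def compute_metrics(
    assembly: dict[str, str],
    min_n_run: int = DEFAULT_MIN_N_RUN,
    mapped_bp: int | None = None,
    oriented_bp: int | None = None,
) -> AssemblyMetrics:
    """Full contiguity summary of a scaffold set."""
    scaffold_lengths = [len(s) for s in assembly.values()]
    contig_lengths = split_into_contigs(assembly, min_n_run)
    total = sum(scaffold_lengths)
    sn50, sl50 = n50_l50(scaffold_lengths)
    cn50, cl50 = n50_l50(contig_lengths)
    over = [l for l in scaffold_lengths if l > 50_000]
    return AssemblyMetrics(
        n_scaffolds=len(scaffold_lengths),
        n_contigs=len(contig_lengths),
        scaffold_total_bp=total,
        contig_total_bp=sum(contig_lengths),
        scaffold_n50=sn50,
        scaffold_l50=sl50,
        contig_n50=cn50,
        contig_l50=cl50,
        n_scaffolds_over_50kb=len(over),
        percent_in_scaffolds_over_50kb=round(100.0 * sum(over) / total, 1),
        mapped_bp=mapped_bp,
        mapped_percent=None if mapped_bp is None else round(100.0 * mapped_bp / total, 1),
        oriented_bp=oriented_bp,
        oriented_percent=None
        if oriented_bp is None
        else round(100.0 * oriented_bp / total, 1),
    )


def percent_change(before: float, after: float, ndigits: int = 1) -> float:
    """Relative change in percent, ``100 * (after - before) / before``."""
    return round(100.0 * (after - before) / before, ndigits)


def assembly_summary(before: AssemblyMetrics, after: AssemblyMetrics) -> dict:
    """Side-by-side comparison of two assemblies with percent changes."""
    return {
        "before": before.as_dict(),
        "after": after.as_dict(),
        "contig_count_change_pct": percent_change(before.n_contigs, after.n_contigs),
        "contig_l50_change_pct": percent_change(before.contig_l50, after.contig_l50),
    }
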