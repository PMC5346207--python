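"""FASTA / AGP / VCF input-output helpers.

Sequences are handled as plain upper-case strings keyed by name in an
ordered dict; Biopython does the FASTA parsing.  AGP files follow the
v2.1 tab layout (1-based inclusive coordinates, ``W`` sequence
components and ``U`` gap components).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line.rstrip("\n").split("\t"))
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        df[col] = df[col].astype(int)
    return df


def write_vcf(
    records: Iterable[tuple[str, int, str, str, str]],
    contig_lengths: dict[str, int],
    path: str | Path,
    sample: str = "sample",
) -> None:
    """Write a minimal VCF 4.2 with one homozygous-genotype sample.

    ``records`` are (chrom, pos_1based, ref, alt, gt) tuples, e.g. gt "1/1".
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for name, length in contig_lengths.items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for chrom, pos, ref, alt, gt in records:
        buf.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
    Path(path).write_text(buf.getvalue())
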