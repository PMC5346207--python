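"""Packaged reference tables from the published peach v2.0 release.

These small TSVs transcribe the per-map anchoring spans, per-chromosome
cM/Mb ratios, and the gap-patching / variant-polishing report of the
peach v2.0 chromosome-scale assembly.  They feed the statistics stages
(`chromosome_cmmb`, `compare_maps`, report totals) and let the package
reproduce the published arithmetic without any large download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: iPLEX SNP assay design outcome on the CxA progeny: markers tested vs scorable.
SNP_ASSAYS_TESTED = 265
SNP_ASSAYS_SCORABLE = 194

#: Published contiguity of the two peach chromosome-scale releases.
PEACH_CONTIG_L50_KB = {"v1.0": 214.2, "v2.0": 255.4}
PEACH_CONTIG_COUNT = {"v1.0": 2730, "v2.0": 2525}

#: Chromosomes excluded from the published map comparison for low coverage
#: (< 50% of pseudomolecule length): G3, G5, G7, G8 in the PxF recurrent
#: map and G5 in CxA.
PUBLISHED_COVERAGE_CUTOFF = 0.5


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("scaffmap.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def anchoring_spans() -> pd.DataFrame:
    """Per map x chromosome genetic (cM) and physical (bp) spans covered."""
    return _load("anchoring_spans.tsv")


def pseudomolecule_lengths() -> pd.DataFrame:
    """Published pseudomolecule lengths (total anchored bases per chromosome)."""
    return _load("pseudomolecule_lengths.tsv")


def cmmb_ratios() -> pd.DataFrame:
    """Published whole-chromosome cM/Mb ratios for seven linkage maps."""
    return _load("cmmb_ratios.tsv")


def gap_polish_report() -> pd.DataFrame:
    """Published per-chromosome gap patching and SNP/indel correction counts."""
    return _load("gap_polish_report.tsv")
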