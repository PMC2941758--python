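"""Bundled reference tables from the genome-wide EST screen this
package models.

These are published aggregate results — per-tissue event counts, the
gene list with condition-specific cassette exons, the RT-qPCR-validated
exon coordinates, and cross-tissue intron-concordance counts.  The raw
EST corpus behind them is not redistributable at this scale, so the
tables serve as fixed inputs for report aggregation and as worked
examples for the package's arithmetic (coordinate conventions, totals,
percentages); they are never used to fit or tune anything.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import HeterogeneitySummary
from .model import GenomeInterval


def _load(name: str) -> pd.DataFrame:
    with resources.files("estsplice.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def tissue_summary() -> pd.DataFrame:
    """Per-tissue counts of genes, alternative introns, and T/N exons."""
    return _load("reference_tissue_summary.tsv")


def gene_events() -> pd.DataFrame:
    """The 46 genes with condition-specific cassette exons and the
    tissue(s) each was predicted in (comma-separated)."""
    return _load("reference_gene_events.tsv")


def gene_tissue_pairs() -> list[tuple[str, str]]:
    """(gene, tissue) pairs expanded from the gene list; genes predicted
    in several anatomical systems contribute one pair per tissue."""
    pairs = []
    for r in gene_events().itertuples():
        for t in r.tissues.split(","):
            pairs.append((r.gene_id, t))
    return pairs


def validated_exons() -> pd.DataFrame:
    """RT-qPCR-validated exon segments with absolute coordinates and
    printed lengths (the worked example fixing the 1-based fully-closed
    coordinate convention)."""
    return _load("reference_validated_exons.tsv")


def validated_exon_intervals() -> list[tuple[str, GenomeInterval, int]]:
    """(exon label, interval, printed length) for each validated segment."""
    return [
        (r.exon_label,
         GenomeInterval(r.chrom, int(r.start), int(r.end)),
         int(r.length_bp))
        for r in validated_exons().itertuples()
    ]


def intron_concordance() -> HeterogeneitySummary:
    """Cross-tissue concordance counts for introns classified in five
    or more anatomical systems."""
    df = _load("reference_intron_concordance.tsv")
    counts = dict(zip(df["pattern"], df["n_introns"]))
    return HeterogeneitySummary(
        n_heterogeneous=int(counts["heterogeneous"]),
        n_homogeneous_tumor=int(counts["homogeneous_tumor"]),
        n_homogeneous_normal=int(counts["homogeneous_normal"]),
    )
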