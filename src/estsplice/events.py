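"""Detection of condition-specific cassette and mutually exclusive exons.

Given introns labelled tumor-side (T/TT) or normal-side (N/NN) within
one gene and one anatomical system, a cassette exon is called wherever a
single skipping intron of one side shares its exact outer splice
boundaries with a chain of two (one exon) or three (two adjacent exons)
introns of the opposite side.  A mutually exclusive pair is called
wherever a tumor-side 2-intron chain and a normal-side 2-intron chain
share the same outermost donor and acceptor and their internal exons do
not overlap.

"Alternative" is operationalised as exact sharing of the outer splice
boundaries, not mere overlap: alternative-donor/acceptor events, which
do not define a clean cassette, are thereby excluded.  E-labelled
introns cannot anchor events.  Detection is purely combinatorial over
intron coordinates and labels; mixed configurations at one locus emit
separate events with no cross-kind deduplication.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import NORMAL_SIDE, TUMOR_SIDE, ClassificationResult
from .model import GenomeInterval, Intron

EVENT_KINDS = ("cassette", "double_cassette", "mutually_exclusive")


@dataclass(frozen=True)
class LabeledIntron:
    """An intron interval with its five-class label in one (gene, tissue)."""

    interval: GenomeInterval
    label: str

    @property
    def side(self) -> str | None:
        if self.label in TUMOR_SIDE:
            return "T"
        if self.label in NORMAL_SIDE:
            return "N"
        return None


@dataclass(frozen=True)
class SpliceEvent:
    """A cassette-exon chain or mutually-exclusive-exon pair.

    For cassette kinds the inclusion chain belongs to
    ``condition_of_inclusion`` and the single skipping intron to the
    opposite condition.  For mutually exclusive pairs the convention is
    inclusion = tumor-side chain, skipping = normal-side chain,
    ``condition_of_inclusion = "T"``; ``exon_intervals`` then holds the
    tumor-included exon followed by the normal-included exon.
    """

    gene_id: str
    anatomical_system: str
    kind: str
    inclusion_introns: tuple[GenomeInterval, ...]
    skipping_introns: tuple[GenomeInterval, ...]
    exon_intervals: tuple[GenomeInterval, ...]
    condition_of_inclusion: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.condition_of_inclusion not in ("T", "N"):
            raise ValueError("condition_of_inclusion must be 'T' or 'N'")
        # Outer boundaries of the skipping side must equal those of the
        # inclusion chain, and exons are exactly the inter-intron gaps.
        incl = self.inclusion_introns
        skip = self.skipping_introns
        assert incl[0].start == min(s.start for s in skip)
        assert incl[-1].end == max(s.end for s in skip)
        for ex in self.exon_intervals:
            assert ex.length() >= 1

    def intron_coords(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (iv.start, iv.end)
            for iv in self.inclusion_introns + self.skipping_introns
        )


def introns_incompatible(a: Intron, b: Intron) -> bool:
    """True iff two introns of the same gene overlap but are not identical.

    Two overlapping, non-identical splice-site pairs cannot both be
    excised from the same transcript molecule.
    """
    if a.gene_id != b.gene_id:
        raise ValueError(
            f"introns belong to different genes: {a.gene_id} vs {b.gene_id}"
        )
    return a.interval.overlaps(b.interval) and a.interval != b.interval


def _chains(introns: Sequence[GenomeInterval], start: int, end: int,
            length: int) -> list[tuple[GenomeInterval, ...]]:
    """All ordered chains of ``length`` introns with outer bounds
    (start, end), consecutive members separated by >= 1 exonic base."""
    pool = sorted(introns, key=lambda iv: (iv.start, iv.end))
    out: list[tuple[GenomeInterval, ...]] = []

    def extend(chain: tuple[GenomeInterval, ...]) -> None:
        if len(chain) == length:
            if chain[-1].end == end:
                out.append(chain)
            return
        for iv in pool:
            if iv.start >= chain[-1].end + 2 and iv.end <= end:
                extend(chain + (iv,))

    for iv in pool:
        if iv.start == start and iv.end <= end:
            extend((iv,))
    return out


def _gaps(chain: Sequence[GenomeInterval]) -> tuple[GenomeInterval, ...]:
    return tuple(
        GenomeInterval(a.chrom, a.end + 1, b.start - 1)
        for a, b in zip(chain, chain[1:])
    )


def find_cassette_exons(
    gene_id: str,
    anatomical_system: str,
    labeled_introns: Sequence[LabeledIntron],
    max_chain: int = 3,
) -> list[SpliceEvent]:
    """Single and adjacent-double cassette exons in one (gene, tissue).

    For every directional intron S and every chain of 2 or 3 introns of
    the opposite side whose outer boundaries equal S's exactly, one
    event is emitted; S is the skipping form and the chain the inclusion
    form, so the included exon(s) belong to the chain's condition.
    """
    by_side: dict[str, list[GenomeInterval]] = {"T": [], "N": []}
    for li in labeled_introns:
        if li.side is not None:
            by_side[li.side].append(li.interval)

    events = []
    for skip_side, incl_side in (("T", "N"), ("N", "T")):
        for skip in sorted(by_side[skip_side], key=lambda iv: (iv.start, iv.end)):
            for length in range(2, max_chain + 1):
                for chain in _chains(by_side[incl_side], skip.start,
                                     skip.end, length):
                    events.append(SpliceEvent(
                        gene_id=gene_id,
                        anatomical_system=anatomical_system,
                        kind="cassette" if length == 2 else "double_cassette",
                        inclusion_introns=chain,
                        skipping_introns=(skip,),
                        exon_intervals=_gaps(chain),
                        condition_of_inclusion=incl_side,
                    ))
    return events


def find_mutually_exclusive(
    gene_id: str,
    anatomical_system: str,
    labeled_introns: Sequence[LabeledIntron],
) -> list[SpliceEvent]:
    """Mutually exclusive exon pairs in one (gene, tissue).

    Every tumor-side 2-intron chain paired with every normal-side
    2-intron chain sharing identical outermost boundaries, whose
    internal exons do not overlap, yields one event.
    """
    by_side: dict[str, list[GenomeInterval]] = {"T": [], "N": []}
    for li in labeled_introns:
        if li.side is not None:
            by_side[li.side].append(li.interval)

    bounds = sorted({
        (iv.start, jv.end)
        for side in ("T", "N")
        for iv in by_side[side]
        for jv in by_side[side]
    })
    events = []
    for start, end in bounds:
        t_chains = _chains(by_side["T"], start, end, 2)
        n_chains = _chains(by_side["N"], start, end, 2)
        for tc in t_chains:
            (t_exon,) = _gaps(tc)
            for nc in n_chains:
                (n_exon,) = _gaps(nc)
                if t_exon.overlaps(n_exon):
                    continue
                events.append(SpliceEvent(
                    gene_id=gene_id,
                    anatomical_system=anatomical_system,
                    kind="mutually_exclusive",
                    inclusion_introns=tc,
                    skipping_introns=nc,
                    exon_intervals=(t_exon, n_exon),
                    condition_of_inclusion="T",
                ))
    return events


def detect_events(
    introns: Sequence[Intron],
    intron_results: Sequence[ClassificationResult],
    label_field: str = "label_bonferroni",
    max_chain: int = 3,
) -> list[SpliceEvent]:
    """Run both event finders over every (gene, tissue) with labelled introns.

    ``label_field`` selects which label anchors detection; the default
    uses the Bonferroni-corrected labels.
    """
    from .classify import intron_entity_id

    labels: dict[str, dict[str, str]] = defaultdict(dict)
    for r in intron_results:
        labels[r.entity_id][r.anatomical_system] = getattr(r, label_field)

    grouped: dict[tuple[str, str], list[LabeledIntron]] = defaultdict(list)
    for intron in introns:
        eid = intron_entity_id(intron)
        for tissue, label in labels.get(eid, {}).items():
            grouped[(intron.gene_id, tissue)].append(
                LabeledIntron(intron.interval, label)
            )

    events: list[SpliceEvent] = []
    for (gene, tissue) in sorted(grouped):
        lis = grouped[(gene, tissue)]
        events.extend(find_cassette_exons(gene, tissue, lis, max_chain=max_chain))
        events.extend(find_mutually_exclusive(gene, tissue, lis))
    return events


def summarize_events(events: Sequence[SpliceEvent],
                     include_total: bool = True) -> pd.DataFrame:
    """Per-tissue event summary.

    Columns: genes with >= 1 event, distinct participating introns and
    their split into normal- and tumor-side, and condition-specific exon
    counts (each cassette exon counted once, a mutually exclusive pair
    contributing one tumor and one normal exon).  An optional ``Total``
    row holds column sums, except that the gene total collapses genes
    detected in several tissues to distinct genes.
    """
    genes: dict[str, set[str]] = defaultdict(set)
    introns_by_side: dict[str, dict[str, set[tuple[int, int]]]] = defaultdict(
        lambda: {"T": set(), "N": set()}
    )
    exon_counts: dict[str, dict[str, int]] = defaultdict(lambda: {"T": 0, "N": 0})

    for ev in events:
        t = ev.anatomical_system
        genes[t].add(ev.gene_id)
        incl_side = ev.condition_of_inclusion
        skip_side = "N" if incl_side == "T" else "T"
        for iv in ev.inclusion_introns:
            introns_by_side[t][incl_side].add((iv.start, iv.end))
        for iv in ev.skipping_introns:
            introns_by_side[t][skip_side].add((iv.start, iv.end))
        if ev.kind == "mutually_exclusive":
            exon_counts[t]["T"] += 1
            exon_counts[t]["N"] += 1
        else:
            exon_counts[t][incl_side] += len(ev.exon_intervals)

    rows = []
    for t in sorted(genes):
        n_t_introns = len(introns_by_side[t]["T"])
        n_n_introns = len(introns_by_side[t]["N"])
        rows.append({
            "tissue": t,
            "n_genes": len(genes[t]),
            "n_introns": n_t_introns + n_n_introns,
            "n_normal_introns": n_n_introns,
            "n_tumoral_introns": n_t_introns,
            "n_T_exons": exon_counts[t]["T"],
            "n_N_exons": exon_counts[t]["N"],
        })
    df = pd.DataFrame(rows, columns=[
        "tissue", "n_genes", "n_introns", "n_normal_introns",
        "n_tumoral_introns", "n_T_exons", "n_N_exons",
    ])
    if include_total:
        df = add_totals_row(df, distinct_genes=distinct_gene_count(events))
    return df


def add_totals_row(summary: pd.DataFrame,
                   distinct_genes: int | None = None) -> pd.DataFrame:
    """Append a ``Total`` row of column sums to a per-tissue summary.

    ``distinct_genes`` optionally overrides the gene-column sum with a
    distinct-gene count (a gene detected in several tissues appears in
    several rows but is one gene).
    """
    if summary.empty:
        total = {c: 0 for c in summary.columns if c != "tissue"}
    else:
        total = summary.drop(columns="tissue").sum().to_dict()
    if distinct_genes is not None:
        total["n_genes"] = distinct_genes
    total["tissue"] = "Total"
    return pd.concat([summary, pd.DataFrame([total])], ignore_index=True)


def distinct_gene_count(
    events: Iterable[SpliceEvent] | Iterable[tuple[str, str]],
) -> int:
    """Number of distinct genes across (gene, tissue) event entries."""
    genes = set()
    for ev in events:
        if isinstance(ev, SpliceEvent):
            genes.add(ev.gene_id)
        else:
            gene, _tissue = ev
            genes.add(gene)
    return len(genes)
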