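"""End-to-end orchestration: classify -> detect -> summarize (-> enrich).

`run_pipeline` takes in-memory gene models, libraries and ESTs (read
from files by the CLI, or produced by the synthetic cohort generator),
runs gene and intron classification, event detection and reporting, and
optionally writes every table plus a JSON run manifest to an output
directory.  Reruns with identical inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_GENE_ESTS,
    DEFAULT_MIN_TISSUE_ESTS,
    ClassificationResult,
    classify_genes,
    classify_introns,
    count_gene_ests,
    eligible_tissues,
    heterogeneity_summary,
)
from .events import (
    SpliceEvent,
    detect_events,
    distinct_gene_count,
    summarize_events,
)
from .io import (
    ensure_dir,
    write_classifications,
    write_events,
    write_events_bed12,
    write_introns,
)
from .model import (
    EstRecord,
    GeneModel,
    Intron,
    Library,
    backgrounds_from_libraries,
    infer_introns,
)

logger = logging.getLogger(__name__)


def percent(num: float, den: float, ndigits: int = 1) -> float:
    """``100 * num / den`` rounded to ``ndigits`` decimals."""
    if den == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * num / den, ndigits)


def format_ratio(num: int, den: int) -> str:
    """A ratio as the report prints it, e.g. ``format_ratio(36, 46)``
    -> ``'78.3%'``."""
    return f"{percent(num, den):.1f}%"


@dataclass
class PipelineConfig:
    """Thresholds and switches for one pipeline run."""

    alpha: float = DEFAULT_ALPHA
    min_gene_ests: int = DEFAULT_MIN_GENE_ESTS
    min_tissue_ests: int = DEFAULT_MIN_TISSUE_ESTS
    family: str = "per-tissue"          # Bonferroni family: per-tissue | global
    event_label_field: str = "label_bonferroni"
    max_chain: int = 3
    go_p_cut: float = 0.01
    go_min_genome: int = 50

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_gene_ests", "min_tissue_ests", "max_chain",
                     "go_min_genome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.family not in ("per-tissue", "global"):
            raise ValueError("family must be 'per-tissue' or 'global'")
        if self.event_label_field not in ("label", "label_bonferroni"):
            raise ValueError(
                "event_label_field must be 'label' or 'label_bonferroni'")


@dataclass
class PipelineResult:
    """All tables produced by one run."""

    eligible_tissues: list[str]
    gene_results: list[ClassificationResult]
    intron_results: list[ClassificationResult]
    introns: list[Intron]
    events: list[SpliceEvent]
    summary: pd.DataFrame
    gene_table: pd.DataFrame
    exon_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def gene_event_table(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    """Per-gene list of tissues and exon conditions, one row per gene."""
    acc: dict[str, dict[str, set[str]]] = {}
    for ev in events:
        d = acc.setdefault(ev.gene_id, {"tissues": set(), "conditions": set()})
        d["tissues"].add(ev.anatomical_system)
        if ev.kind == "mutually_exclusive":
            d["conditions"].update({"T", "N"})
        else:
            d["conditions"].add(ev.condition_of_inclusion)
    rows = [
        {"gene_id": g,
         "tissues": ",".join(sorted(d["tissues"])),
         "cassette_exons": "/".join(
             c for c in ("N", "T") if c in d["conditions"])}
        for g, d in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "tissues", "cassette_exons"])


def exon_event_table(
    events: Sequence[SpliceEvent],
    intron_labels: Mapping[tuple[str, str, int, int], str] | None = None,
) -> pd.DataFrame:
    """One row per event exon: coordinates, length, predicted specificity.

    Specificity is the inclusion condition, doubled (TT/NN) when every
    inclusion intron of the event is exclusively supported in that
    condition (label TT/NN), if intron labels are supplied.
    """
    rows = []
    for ev in events:
        sides = (
            [ev.condition_of_inclusion] * len(ev.exon_intervals)
            if ev.kind != "mutually_exclusive" else ["T", "N"]
        )
        for ex, side in zip(ev.exon_intervals, sides):
            spec = side
            if intron_labels is not None and ev.kind != "mutually_exclusive":
                labels = {
                    intron_labels.get(
                        (ev.gene_id, ev.anatomical_system, iv.start, iv.end))
                    for iv in ev.inclusion_introns
                }
                if labels == {side * 2}:
                    spec = side * 2
            rows.append({
                "gene_id": ev.gene_id,
                "anatomical_system": ev.anatomical_system,
                "kind": ev.kind,
                "exon": f"{ex.chrom}:{ex.start}-{ex.end}",
                "length_bp": ex.length(),
                "predicted_specificity": spec,
            })
    return pd.DataFrame(rows, columns=[
        "gene_id", "anatomical_system", "kind", "exon", "length_bp",
        "predicted_specificity",
    ])


def run_pipeline(
    genes: Sequence[GeneModel],
    libraries: Sequence[Library],
    ests: Sequence[EstRecord],
    config: PipelineConfig | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Classify genes and introns, detect events, and build report tables."""
    config = config or PipelineConfig()
    config.validate()
    lib_map = {lib.library_id: lib for lib in libraries}

    backgrounds = backgrounds_from_libraries(libraries)
    tissues = eligible_tissues(backgrounds, config.min_tissue_ests)
    backgrounds = {t: bg for t, bg in backgrounds.items() if t in tissues}
    if not tissues:
        logger.warning("no eligible tissues at min_tissue_ests=%d",
                       config.min_tissue_ests)
        result = PipelineResult([], [], [], [], [],
                                summary=summarize_events([]),
                                gene_table=gene_event_table([]),
                                exon_table=exon_event_table([]))
        result.manifest = _manifest(config, result,
                                    notice="no eligible tissues")
        if outdir is not None:
            _write_outputs(result, outdir)
        return result
    logger.info("eligible tissues: %s", ", ".join(sorted(tissues)))

    gene_counts = count_gene_ests(ests, lib_map)
    gene_results = classify_genes(gene_counts, backgrounds,
                                  min_ests=config.min_gene_ests,
                                  alpha=config.alpha, family=config.family)
    gene_labels = {
        (r.entity_id, r.anatomical_system): getattr(
            r, config.event_label_field)
        for r in gene_results
    }
    for t in sorted(tissues):
        n = sum(1 for (g, tt) in gene_labels if tt == t)
        logger.info("%s: %d genes classified", t, n)

    introns = infer_introns(ests, lib_map)
    intron_results = classify_introns(
        introns, gene_labels, backgrounds,
        alpha=config.alpha, family=config.family,
    )
    events = detect_events(introns, intron_results,
                           label_field=config.event_label_field,
                           max_chain=config.max_chain)
    logger.info("detected %d events in %d genes", len(events),
                distinct_gene_count(events))

    intron_label_map = {}
    for r in intron_results:
        gene, rest = r.entity_id.split(":", 1)
        _chrom, span = rest.rsplit(":", 1)
        s, e = span.split("-")
        intron_label_map[(gene, r.anatomical_system, int(s), int(e))] = \
            getattr(r, config.event_label_field)

    result = PipelineResult(
        eligible_tissues=sorted(tissues),
        gene_results=gene_results,
        intron_results=intron_results,
        introns=introns,
        events=events,
        summary=summarize_events(events),
        gene_table=gene_event_table(events),
        exon_table=exon_event_table(events, intron_label_map),
    )
    result.manifest = _manifest(config, result)
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _manifest(config: PipelineConfig, result: PipelineResult,
              notice: str | None = None) -> dict:
    m = {
        "package": "estsplice",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "eligible_tissues": result.eligible_tissues,
        "n_gene_results": len(result.gene_results),
        "n_intron_results": len(result.intron_results),
        "n_events": len(result.events),
        "n_event_genes": distinct_gene_count(result.events),
    }
    if notice:
        m["notice"] = notice
    return m


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    ensure_dir(outdir)

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    write_classifications(result.gene_results, p("gene_classification.tsv"))
    write_classifications(result.intron_results,
                          p("intron_classification.tsv"))
    write_introns(result.introns, p("introns.tsv"))
    write_events(result.events, p("events.tsv"))
    write_events_bed12(result.events, p("events.bed"))
    result.summary.to_csv(p("tissue_summary.tsv"), sep="\t", index=False)
    result.gene_table.to_csv(p("gene_events.tsv"), sep="\t", index=False)
    result.exon_table.to_csv(p("exon_events.tsv"), sep="\t", index=False)
    with open(p("run_manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def intron_heterogeneity(result: PipelineResult, min_tissues: int = 5,
                         label_field: str = "label"):
    """Cross-tissue concordance summary of this run's intron labels."""
    return heterogeneity_summary(result.intron_results,
                                 min_tissues=min_tissues,
                                 label_field=label_field)
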