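"""Readers and writers for the pipeline's external formats.

All coordinates are written 1-based inclusive; the sole exception is
BED12 output, whose chromStart/blockStarts follow BED's 0-based
half-open convention.  Tab-delimited tables carry a header line with a
fixed, documented column order, so write-then-read round trips
reproduce records field for field.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .classify import ClassificationResult
from .events import SpliceEvent
from .model import EstRecord, GenomeInterval, GeneModel, Intron, Library

LIBRARY_COLUMNS = ("library_id", "anatomical_system", "condition", "est_total")
EST_COLUMNS = ("est_id", "library_id", "gene_id", "chrom", "blocks")
INTRON_COLUMNS = ("gene_id", "chrom", "start", "end",
                  "anatomical_system", "condition", "n_ests")
CLASSIFICATION_COLUMNS = ("entity_id", "anatomical_system", "k_tumor",
                          "k_normal", "p_tumor", "p_normal", "m_tests",
                          "label", "label_bonferroni", "reason")
EVENT_COLUMNS = ("gene_id", "anatomical_system", "kind",
                 "condition_of_inclusion", "chrom", "inclusion_introns",
                 "skipping_introns", "exons")


# ---------------------------------------------------------------- gene models

def _check_gff3_lines(path: str) -> int:
    """Cheap structural validation giving line numbers; returns the
    number of feature lines."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields, found {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer "
                    f"coordinates"
                ) from None
            n += 1
    return n


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file."""
    if _check_gff3_lines(path) == 0:
        return []
    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        strand = g.strand if g.strand in ("+", "-") else "."
        interval = GenomeInterval(g.seqid, g.start, g.end, strand)
        exons = tuple(
            GenomeInterval(e.seqid, e.start, e.end,
                           e.strand if e.strand in ("+", "-") else ".")
            for e in db.children(g, featuretype="exon", order_by="start")
        )
        gene_id = g.id.removeprefix("gene:")
        genes.append(GeneModel(gene_id, interval, exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\testsplice\tgene\t{iv.start}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\tID=gene:{g.gene_id}\n")
            for i, ex in enumerate(g.exons, start=1):
                fh.write(f"{ex.chrom}\testsplice\texon\t{ex.start}\t{ex.end}"
                         f"\t.\t{ex.strand}\t.\tID=exon:{g.gene_id}.{i};"
                         f"Parent=gene:{g.gene_id}\n")


# ------------------------------------------------------------------ libraries

def write_libraries(libraries: Sequence[Library], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LIBRARY_COLUMNS)
        for lib in libraries:
            w.writerow([lib.library_id, lib.anatomical_system,
                        lib.condition, lib.est_total])


def read_libraries(path: str) -> list[Library]:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    _require_columns(df, LIBRARY_COLUMNS[:3], path)
    est_totals = df["est_total"] if "est_total" in df else [0] * len(df)
    return [
        Library(str(r.library_id), r.anatomical_system, r.condition,
                int(t))
        for r, t in zip(df.itertuples(), est_totals)
    ]


# ----------------------------------------------------------------------- ESTs

def _format_blocks(blocks: Sequence[GenomeInterval]) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in blocks)


def _parse_blocks(chrom: str, text: str) -> tuple[GenomeInterval, ...]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append(GenomeInterval(chrom, int(s), int(e)))
    return tuple(out)


def write_ests(ests: Sequence[EstRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EST_COLUMNS)
        for est in ests:
            w.writerow([est.est_id, est.library_id, est.gene_id,
                        est.blocks[0].chrom, _format_blocks(est.blocks)])


def read_ests(path: str) -> list[EstRecord]:
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if tuple(header) != EST_COLUMNS:
            raise ValueError(
                f"{path}: expected header {EST_COLUMNS}, found {tuple(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}: malformed line {lineno}")
            est_id, library_id, gene_id, chrom, blocks = row
            out.append(EstRecord(est_id, library_id, gene_id,
                                 _parse_blocks(chrom, blocks)))
    return out


# -------------------------------------------------------------------- introns

def write_introns(introns: Sequence[Intron], path: str) -> None:
    """Long-format support table: one row per (intron, tissue, condition)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(INTRON_COLUMNS)
        for intron in introns:
            iv = intron.interval
            for (tissue, cond) in sorted(intron.support):
                w.writerow([intron.gene_id, iv.chrom, iv.start, iv.end,
                            tissue, cond, intron.support[(tissue, cond)]])


def read_introns(path: str) -> list[Intron]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, INTRON_COLUMNS, path)
    acc: dict[tuple, Intron] = {}
    for r in df.itertuples():
        key = (r.gene_id, r.chrom, int(r.start), int(r.end))
        if key not in acc:
            acc[key] = Intron(r.gene_id,
                              GenomeInterval(r.chrom, int(r.start), int(r.end)))
        acc[key].support[(r.anatomical_system, r.condition)] = int(r.n_ests)
    return [acc[k] for k in sorted(acc)]


# ------------------------------------------------------------ classifications

def write_classifications(results: Sequence[ClassificationResult],
                          path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLASSIFICATION_COLUMNS)
        for r in results:
            w.writerow([r.entity_id, r.anatomical_system, r.k_tumor,
                        r.k_normal, repr(r.p_tumor), repr(r.p_normal),
                        r.m_tests, r.label, r.label_bonferroni,
                        r.reason or ""])


def read_classifications(path: str) -> list[ClassificationResult]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=["nan"])
    _require_columns(df, CLASSIFICATION_COLUMNS, path)
    return [
        ClassificationResult(
            r.entity_id, r.anatomical_system, int(r.k_tumor), int(r.k_normal),
            float(r.p_tumor), float(r.p_normal), int(r.m_tests),
            r.label, r.label_bonferroni, r.reason or None,
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------- events

def write_events(events: Sequence[SpliceEvent], path: str) -> None:
    """Events as TSV, intron/exon intervals semicolon-joined."""
    def fmt(ivs: Sequence[GenomeInterval]) -> str:
        return ";".join(f"{iv.start}-{iv.end}" for iv in ivs)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for ev in events:
            w.writerow([ev.gene_id, ev.anatomical_system, ev.kind,
                        ev.condition_of_inclusion,
                        ev.inclusion_introns[0].chrom,
                        fmt(ev.inclusion_introns), fmt(ev.skipping_introns),
                        fmt(ev.exon_intervals)])


def read_events(path: str) -> list[SpliceEvent]:
    def parse(chrom: str, text: str) -> tuple[GenomeInterval, ...]:
        out = []
        for part in text.split(";"):
            s, e = part.split("-")
            out.append(GenomeInterval(chrom, int(s), int(e)))
        return tuple(out)

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENT_COLUMNS, path)
    return [
        SpliceEvent(r.gene_id, r.anatomical_system, r.kind,
                    parse(r.chrom, r.inclusion_introns),
                    parse(r.chrom, r.skipping_introns),
                    parse(r.chrom, r.exons),
                    r.condition_of_inclusion)
        for r in df.itertuples()
    ]


def write_events_bed12(events: Sequence[SpliceEvent], path: str) -> None:
    """Events as BED12: blocks are the inclusion exons, name is
    gene|kind|condition.  BED is 0-based half-open."""
    with open(path, "w") as fh:
        for ev in events:
            exons = sorted(ev.exon_intervals, key=lambda iv: iv.start)
            chrom = exons[0].chrom
            chrom_start = exons[0].start - 1
            chrom_end = exons[-1].end
            name = f"{ev.gene_id}|{ev.kind}|{ev.condition_of_inclusion}"
            sizes = ",".join(str(iv.length()) for iv in exons)
            starts = ",".join(str(iv.start - 1 - chrom_start) for iv in exons)
            fh.write("\t".join(map(str, [
                chrom, chrom_start, chrom_end, name, 0, ".",
                chrom_start, chrom_end, "0,0,0", len(exons), sizes, starts,
            ])) + "\n")


# ---------------------------------------------------------------- annotations

def read_annotations(path: str) -> dict[str, set[str]]:
    """Gene -> GO term annotations from 2-column TSV or GAF 2.x.

    GAF lines (detected by the ``!gaf-version`` header or >= 15 columns)
    use column 2 (DB object symbol) and column 5 (GO id) only.
    """
    annots: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                raise ValueError(f"{path}: cannot parse annotation line: {line!r}")
            annots.setdefault(gene, set()).add(term)
    return annots


# -------------------------------------------------------------------- helpers

def _require_columns(df: pd.DataFrame, columns: Iterable[str],
                     path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def bed_to_closed(start0: int, end0: int) -> tuple[int, int]:
    """Convert a BED half-open 0-based pair to 1-based closed coordinates."""
    if end0 <= start0:
        raise ValueError(f"empty BED interval {start0}-{end0}")
    return start0 + 1, end0


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
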