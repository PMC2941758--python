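"""Seeded synthetic EST cohorts with planted condition-specific exons.

The generator emulates the data substrate of an EST-based splicing
screen: multi-exon gene models, EST libraries of configurable size per
(anatomical system, condition), and per-exon inclusion rates that
differ between conditions.  Each EST is sampled by picking a gene, then
an isoform according to the planted event's inclusion rate (PSI) for
the library's condition, then a contiguous window of the transcript,
which is mapped back to genomic blocks — so junction support is
partial, as in real EST data where coverage is uneven along the gene.

A single global seed drives a hierarchy of keyed random streams (one
per gene for the model, one per (library, gene) for EST sampling), so
adding genes or libraries to a configuration does not perturb the ESTs
of existing ones.  Library EST counts are negative-binomially
over-dispersed.

Not simulated: sequencing error, chimeric ESTs, library normalisation
artifacts, strand effects.  These distributional choices are stand-ins
for a historical EST corpus, not a fitted model of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .events import SpliceEvent
from .model import (
    ANATOMICAL_SYSTEMS,
    EstRecord,
    GenomeInterval,
    GeneModel,
    Library,
)

# Stream tags keeping the keyed RNG hierarchy collision-free.
_GENE_STREAM = 11
_COUNT_STREAM = 23
_EST_STREAM = 37
_SHUFFLE_STREAM = 53

_CHROM = "chrS"
_GENE_SPACING = 10_000_000


@dataclass(frozen=True)
class PlantedEvent:
    """A condition-specific splicing event planted in one gene.

    ``exon_index`` is the 0-based index of the (first) target exon in
    the gene's exon chain; it must be internal, with a further internal
    neighbour for the two-exon kinds.  ``psi_normal``/``psi_tumor`` are
    the inclusion rates of the target exon (for ``mutually_exclusive``,
    of the first exon of the pair; the second exon's rate is the
    complement within each condition).
    """

    gene_id: str
    kind: str  # cassette | double_cassette | mutually_exclusive
    exon_index: int
    psi_normal: float
    psi_tumor: float
    tissue: str

    def __post_init__(self) -> None:
        if self.kind not in ("cassette", "double_cassette", "mutually_exclusive"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        for name in ("psi_normal", "psi_tumor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tissue not in ANATOMICAL_SYSTEMS:
            raise ValueError(f"unknown anatomical system {self.tissue!r}")
        if self.exon_index < 1:
            raise ValueError("target exon must be internal (index >= 1)")

    @property
    def n_target_exons(self) -> int:
        return 1 if self.kind == "cassette" else 2

    @property
    def condition_of_inclusion(self) -> str:
        return "T" if self.psi_tumor > self.psi_normal else "N"


def _default_events() -> list[PlantedEvent]:
    """One strongly differential event of each archetype, plus the
    tissue-matched inclusion-rate contrast used throughout the package's
    recovery studies (|PSI difference| = 0.8)."""
    return [
        PlantedEvent("G000", "cassette", 2, 0.9, 0.1, "CNS"),
        PlantedEvent("G001", "cassette", 2, 0.1, 0.9, "CNS"),
        PlantedEvent("G002", "double_cassette", 2, 0.9, 0.1, "CNS"),
        PlantedEvent("G003", "mutually_exclusive", 2, 0.1, 0.9, "CNS"),
    ]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``est_count_mean``/``est_count_dispersion`` parametrise the
    negative-binomial EST count drawn independently per (library, gene),
    so a library's depth for one gene does not depend on how many other
    genes the cohort carries.  Defaults describe the package's reference
    recovery study: one tissue, four libraries per condition, enough
    ESTs that every planted junction draws >= 300 junction-spanning ESTs
    per condition, and planted inclusion-rate differentials of 0.8.
    """

    tissues: tuple[str, ...] = ("CNS",)
    libraries_per_tissue_per_condition: int = 4
    est_count_mean: float = 250.0
    est_count_dispersion: float = 20.0
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (6, 8)
    exon_length_range: tuple[int, int] = (90, 200)
    intron_length_range: tuple[int, int] = (300, 800)
    planted_events: list[PlantedEvent] = field(default_factory=_default_events)
    est_span_mean: float = 600.0
    est_span_sd: float = 150.0
    est_span_min: int = 150
    seed: int = 0

    def validate(self) -> None:
        if not self.tissues:
            raise ValueError("at least one tissue required")
        for t in self.tissues:
            if t not in ANATOMICAL_SYSTEMS:
                raise ValueError(f"unknown anatomical system {t!r}")
        for name in ("libraries_per_tissue_per_condition", "n_genes",
                     "est_span_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.est_count_mean <= 0 or self.est_count_dispersion <= 0:
            raise ValueError("EST count parameters must be positive")
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("invalid exons_per_gene range")
        for rng_name in ("exon_length_range", "intron_length_range"):
            a, b = getattr(self, rng_name)
            if not (1 <= a <= b):
                raise ValueError(f"invalid {rng_name}")
        if self.est_span_mean <= 0 or self.est_span_sd < 0:
            raise ValueError("invalid EST span model")
        gene_ids = {f"G{i:03d}" for i in range(self.n_genes)}
        seen = set()
        for ev in self.planted_events:
            if ev.gene_id not in gene_ids:
                raise ValueError(
                    f"planted event references unknown gene {ev.gene_id!r} "
                    f"(gene ids are G000..G{self.n_genes - 1:03d})"
                )
            if ev.gene_id in seen:
                raise ValueError(f"gene {ev.gene_id} has more than one event")
            seen.add(ev.gene_id)
            if ev.tissue not in self.tissues:
                raise ValueError(
                    f"event in {ev.gene_id} targets tissue {ev.tissue!r} "
                    f"absent from the cohort"
                )
            last_needed = ev.exon_index + ev.n_target_exons
            if last_needed > lo - 1:
                raise ValueError(
                    f"event in {ev.gene_id} needs exon index {last_needed} "
                    f"internal, but genes may have as few as {lo} exons"
                )


def load_cohort_config(path: str) -> CohortConfig:
    """Read a cohort configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    events = [PlantedEvent(**e) for e in raw.pop("planted_events", [])]
    for key in ("tissues", "exons_per_gene", "exon_length_range",
                "intron_length_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = CohortConfig(**raw)
    if events:
        cfg.planted_events = events
    cfg.validate()
    return cfg


# ------------------------------------------------------------------ genes

def _make_gene(config: CohortConfig, gi: int) -> GeneModel:
    rng = np.random.default_rng([config.seed, _GENE_STREAM, gi])
    n_ex = int(rng.integers(config.exons_per_gene[0],
                            config.exons_per_gene[1] + 1))
    ex_lo, ex_hi = config.exon_length_range
    in_lo, in_hi = config.intron_length_range
    exon_lens = rng.integers(ex_lo, ex_hi + 1, size=n_ex)
    intron_lens = rng.integers(in_lo, in_hi + 1, size=max(0, n_ex - 1))
    pos = 1 + gi * _GENE_SPACING
    exons = []
    for i, el in enumerate(exon_lens):
        exons.append(GenomeInterval(_CHROM, pos, pos + int(el) - 1, "+"))
        pos += int(el)
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    gene_id = f"G{gi:03d}"
    return GeneModel(
        gene_id,
        GenomeInterval(_CHROM, exons[0].start, exons[-1].end, "+"),
        tuple(exons),
    )


def _variants(gene: GeneModel, event: PlantedEvent | None
              ) -> list[tuple[int, ...]]:
    """Exon-index tuples of the gene's isoforms.

    Index 0 is the isoform whose sampling probability is the planted
    PSI (the exon-including form; for mutually exclusive events, the
    form carrying the first exon of the pair).
    """
    all_ix = tuple(range(len(gene.exons)))
    if event is None:
        return [all_ix]
    e = event.exon_index
    if event.kind == "cassette":
        return [all_ix, tuple(i for i in all_ix if i != e)]
    if event.kind == "double_cassette":
        return [all_ix, tuple(i for i in all_ix if i not in (e, e + 1))]
    # mutually exclusive: no isoform carries both exons of the pair
    return [
        tuple(i for i in all_ix if i != e + 1),
        tuple(i for i in all_ix if i != e),
    ]


def _psi_for_library(event: PlantedEvent | None, lib: Library) -> float:
    """Sampling probability of variant 0 in one library.

    The condition differential exists only in the event's target
    tissue; elsewhere both conditions use the normal-condition rate.
    """
    if event is None:
        return 1.0
    if lib.anatomical_system != event.tissue:
        return event.psi_normal
    return event.psi_tumor if lib.condition == "tumor" else event.psi_normal


def _window_to_blocks(gene: GeneModel, exon_ix: tuple[int, ...],
                      a: int, b: int) -> tuple[GenomeInterval, ...]:
    """Map a transcript-coordinate window [a, b] (1-based on the spliced
    isoform) to genomic alignment blocks."""
    blocks = []
    offset = 0
    for i in exon_ix:
        ex = gene.exons[i]
        lo = max(a, offset + 1)
        hi = min(b, offset + ex.length())
        if lo <= hi:
            blocks.append(GenomeInterval(
                ex.chrom, ex.start + (lo - offset - 1),
                ex.start + (hi - offset - 1),
            ))
        offset += ex.length()
    return tuple(blocks)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[GeneModel], list[Library], list[EstRecord], pd.DataFrame]:
    """Generate gene models, libraries, ESTs, and the ground-truth table.

    Deterministic given ``config.seed``; each library's ``est_total``
    equals the number of EstRecords emitted for it.  The ground truth
    lists every planted event with its intron coordinates (in the
    detection module's canonical orientation) and PSI values.
    """
    config.validate()
    genes = [_make_gene(config, gi) for gi in range(config.n_genes)]
    events_by_gene: dict[str, PlantedEvent] = {
        ev.gene_id: ev for ev in config.planted_events
    }

    libraries: list[Library] = []
    for t in config.tissues:
        for cond in ("normal", "tumor"):
            for r in range(config.libraries_per_tissue_per_condition):
                libraries.append(Library(f"{t}.{cond}.{r}", t, cond, 0))

    mu = config.est_count_mean
    disp = config.est_count_dispersion
    p_nb = disp / (disp + mu)

    ests: list[EstRecord] = []
    for li, lib in enumerate(libraries):
        lib_n = 0
        for gi, gene in enumerate(genes):
            event = events_by_gene.get(gene.gene_id)
            variants = _variants(gene, event)
            psi = _psi_for_library(event, lib)
            count_rng = np.random.default_rng(
                [config.seed, _COUNT_STREAM, li, gi])
            n = int(count_rng.negative_binomial(disp, p_nb))
            if n == 0:
                continue
            est_rng = np.random.default_rng([config.seed, _EST_STREAM, li, gi])
            pick_incl = est_rng.random(n) < psi
            spans = np.rint(est_rng.normal(
                config.est_span_mean, config.est_span_sd, size=n)).astype(int)
            starts_u = est_rng.random(n)
            for j in range(n):
                vix = variants[0] if (pick_incl[j] or len(variants) == 1) \
                    else variants[1]
                tlen = sum(gene.exons[i].length() for i in vix)
                wlen = int(min(max(spans[j], config.est_span_min), tlen))
                a = 1 + int(starts_u[j] * (tlen - wlen + 1))
                blocks = _window_to_blocks(gene, vix, a, a + wlen - 1)
                ests.append(EstRecord(
                    f"{lib.library_id}|{gene.gene_id}|{j}",
                    lib.library_id, gene.gene_id, blocks,
                ))
            lib_n += n
        lib.est_total = lib_n

    truth = ground_truth_table(genes, config.planted_events)
    return genes, libraries, ests, truth


def _fmt_ivs(ivs: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs)


def planted_intron_sets(
    gene: GeneModel, event: PlantedEvent,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(inclusion, skipping) intron coordinate lists for a planted event,
    in the detection module's canonical orientation (for mutually
    exclusive pairs: inclusion = tumor-side chain)."""
    ex = gene.exons
    e = event.exon_index

    def gap(i: int, j: int) -> tuple[int, int]:
        return (ex[i].end + 1, ex[j].start - 1)

    if event.kind == "cassette":
        incl = [gap(e - 1, e), gap(e, e + 1)]
        skip = [gap(e - 1, e + 1)]
    elif event.kind == "double_cassette":
        incl = [gap(e - 1, e), gap(e, e + 1), gap(e + 1, e + 2)]
        skip = [gap(e - 1, e + 2)]
    else:  # mutually_exclusive: chain A carries exon e, chain B exon e+1
        chain_a = [gap(e - 1, e), gap(e, e + 2)]
        chain_b = [gap(e - 1, e + 1), gap(e + 1, e + 2)]
        if event.condition_of_inclusion == "T":
            incl, skip = chain_a, chain_b
        else:
            incl, skip = chain_b, chain_a
    return incl, skip


def ground_truth_table(genes: Sequence[GeneModel],
                       events: Sequence[PlantedEvent]) -> pd.DataFrame:
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for ev in events:
        incl, skip = planted_intron_sets(by_id[ev.gene_id], ev)
        # mutually exclusive rows use the detector's canonical
        # orientation: inclusion = tumor-side chain, condition T
        condition = ("T" if ev.kind == "mutually_exclusive"
                     else ev.condition_of_inclusion)
        rows.append({
            "gene_id": ev.gene_id,
            "anatomical_system": ev.tissue,
            "kind": ev.kind,
            "condition_of_inclusion": condition,
            "inclusion_introns": _fmt_ivs(incl),
            "skipping_introns": _fmt_ivs(skip),
            "psi_normal": ev.psi_normal,
            "psi_tumor": ev.psi_tumor,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "anatomical_system", "kind", "condition_of_inclusion",
        "inclusion_introns", "skipping_introns", "psi_normal", "psi_tumor",
    ])


# -------------------------------------------------------- negative control

def shuffle_conditions(libraries: Sequence[Library], seed: int,
                       stratified: bool = True) -> list[Library]:
    """Reassign normal/tumor labels among each tissue's libraries.

    With ``stratified=True`` (default) each pseudo-condition receives an
    equal random draw from the true-normal and true-tumor libraries, so
    the relabelled groups are exactly condition-balanced and any
    planted per-condition differential is nulled.  A naive permutation
    (``stratified=False``) does not have this property: an unbalanced
    split of strongly differential libraries retains a large EST-count
    contrast that the hypergeometric test will still detect.
    """
    rng = np.random.default_rng([seed, _SHUFFLE_STREAM])
    out = []
    by_tissue: dict[str, list[Library]] = {}
    for lib in libraries:
        by_tissue.setdefault(lib.anatomical_system, []).append(lib)
    for t in sorted(by_tissue):
        libs = by_tissue[t]
        normals = [l for l in libs if l.condition == "normal"]
        tumors = [l for l in libs if l.condition == "tumor"]
        if stratified:
            if len(normals) != len(tumors) or len(normals) % 2:
                raise ValueError(
                    f"stratified shuffling requires equal, even library "
                    f"counts per condition in tissue {t} "
                    f"({len(normals)} normal, {len(tumors)} tumor)"
                )
            half = len(normals) // 2
            pick_n = set(rng.choice(len(normals), size=half, replace=False))
            pick_t = set(rng.choice(len(tumors), size=half, replace=False))
            new_conditions = {}
            for i, lib in enumerate(normals):
                new_conditions[lib.library_id] = (
                    "normal" if i in pick_n else "tumor")
            for i, lib in enumerate(tumors):
                new_conditions[lib.library_id] = (
                    "normal" if i in pick_t else "tumor")
        else:
            conds = [l.condition for l in libs]
            perm = rng.permutation(len(conds))
            new_conditions = {
                lib.library_id: conds[perm[i]] for i, lib in enumerate(libs)
            }
        for lib in libs:
            out.append(Library(lib.library_id, lib.anatomical_system,
                               new_conditions[lib.library_id], lib.est_total))
    return out


# -------------------------------------------------------------- evaluation

@dataclass(frozen=True)
class RecoveryReport:
    """Recall/precision of detected events against planted ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    per_kind: Mapping[str, tuple[float, float]]


def _truth_keys(truth: pd.DataFrame) -> set[tuple]:
    def parse(text: str) -> frozenset[tuple[int, int]]:
        return frozenset(
            tuple(int(x) for x in part.split("-")) for part in text.split(";")
        )

    return {
        (r.gene_id, r.anatomical_system, r.kind, r.condition_of_inclusion,
         parse(r.inclusion_introns), parse(r.skipping_introns))
        for r in truth.itertuples()
    }


def _event_key(ev: SpliceEvent) -> tuple:
    return (
        ev.gene_id, ev.anatomical_system, ev.kind, ev.condition_of_inclusion,
        frozenset((iv.start, iv.end) for iv in ev.inclusion_introns),
        frozenset((iv.start, iv.end) for iv in ev.skipping_introns),
    )


def truth_eval(detected: Sequence[SpliceEvent],
               truth: pd.DataFrame) -> RecoveryReport:
    """Score detected events against planted truth.

    An event is recovered iff its inclusion and skipping intron sets
    (and condition orientation) match the planted event exactly in the
    same gene and tissue.  Precision over an empty detection set is
    undefined and reported as NaN.
    """
    truth_keys = _truth_keys(truth)
    det_keys = {_event_key(ev) for ev in detected}

    def score(tk: set[tuple], dk: set[tuple]) -> tuple[float, float]:
        matched = len(tk & dk)
        recall = matched / len(tk) if tk else nan
        precision = matched / len(dk) if dk else nan
        return recall, precision

    per_kind = {}
    for kind in ("cassette", "double_cassette", "mutually_exclusive"):
        tk = {k for k in truth_keys if k[2] == kind}
        dk = {k for k in det_keys if k[2] == kind}
        if tk or dk:
            per_kind[kind] = score(tk, dk)
    recall, precision = score(truth_keys, det_keys)
    return RecoveryReport(
        n_truth=len(truth_keys),
        n_detected=len(det_keys),
        n_matched=len(truth_keys & det_keys),
        recall=recall,
        precision=precision,
        per_kind=per_kind,
    )
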