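"""Domain types for EST-based alternative-splicing analysis.

Coordinates are 1-based and fully closed on both ends, so an interval's
length in bp is ``end - start + 1``.  This is the convention used by
genome browsers for display coordinates; BED-style half-open input must
be converted on read (see :mod:`estsplice.io`).

Strand is carried on intervals but deliberately ignored by intron
counting and event detection: splice-site pairs are keyed by absolute
genomic position only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: The 17 anatomical-system codes of the Cancer Genome Anatomy Project
#: nomenclature under which EST libraries are pooled.
ANATOMICAL_SYSTEMS = (
    "BMA", "BRE", "CNS", "COL", "DER", "END", "EYE", "INT", "KID",
    "LIV", "LYM", "MSK", "PLA", "PRO", "RES", "STO", "TES",
)

CONDITIONS = ("normal", "tumor")

#: Strand symbols; ``.`` denotes unknown.
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A closed genomic interval, 1-based on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("interval coordinates must be integers")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval start must not exceed end: "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        """Width in bp; a single-base interval has length 1."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomeInterval) -> int:
    """Length of a closed interval in bp (``end - start + 1``)."""
    return iv.length()


@dataclass(frozen=True)
class GeneModel:
    """A gene with its ordered chain of (constitutive-structure) exons.

    Exons must be non-empty, strictly non-overlapping, sorted by start,
    on the gene's chromosome, and contained in the gene interval.
    """

    gene_id: str
    interval: GenomeInterval
    exons: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exons must be non-empty")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(
                    f"gene {self.gene_id}: exon on {ex.chrom} but gene on "
                    f"{self.interval.chrom}"
                )
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} outside gene interval "
                    f"{self.interval}"
                )
            if prev_end is not None and ex.start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and "
                    f"non-overlapping (exon {ex} follows end {prev_end})"
                )
            prev_end = ex.end

    def introns(self) -> tuple[GenomeInterval, ...]:
        """Gaps between consecutive exons (first and last intronic base)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(
                    GenomeInterval(self.interval.chrom, a.end + 1, b.start - 1,
                                   self.interval.strand)
                )
        return tuple(out)


@dataclass
class Library:
    """One EST library: its anatomical system, condition, and size."""

    library_id: str
    anatomical_system: str
    condition: str
    est_total: int = 0

    def __post_init__(self) -> None:
        if self.anatomical_system not in ANATOMICAL_SYSTEMS:
            raise ValueError(
                f"library {self.library_id}: unknown anatomical system "
                f"{self.anatomical_system!r} (must be one of the 17 CGAP codes)"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"library {self.library_id}: condition must be 'normal' or "
                f"'tumor', got {self.condition!r}"
            )
        if self.est_total < 0:
            raise ValueError(f"library {self.library_id}: est_total must be >= 0")


@dataclass(frozen=True)
class EstRecord:
    """One EST-to-genome alignment as an ordered list of aligned blocks.

    Gaps between consecutive blocks are the introns the EST supports;
    an EST with a single block supports no intron.
    """

    est_id: str
    library_id: str
    gene_id: str
    blocks: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError(f"EST {self.est_id}: blocks must be non-empty")
        chrom = self.blocks[0].chrom
        prev_end = None
        for b in self.blocks:
            if b.chrom != chrom:
                raise ValueError(f"EST {self.est_id}: blocks span chromosomes")
            if prev_end is not None and b.start <= prev_end + 1:
                raise ValueError(
                    f"EST {self.est_id}: blocks must be sorted, non-overlapping "
                    f"and separated by at least one intronic base"
                )
            prev_end = b.end

    def implied_introns(self) -> tuple[GenomeInterval, ...]:
        """The gaps between consecutive aligned blocks."""
        return tuple(
            GenomeInterval(a.chrom, a.end + 1, b.start - 1)
            for a, b in zip(self.blocks, self.blocks[1:])
        )


IntronKey = tuple[str, str, int, int]  # (gene_id, chrom, start, end)


@dataclass
class Intron:
    """A splice-site pair with per-(tissue, condition) EST support counts."""

    gene_id: str
    interval: GenomeInterval
    support: dict[tuple[str, str], int] = field(default_factory=dict)

    def key(self) -> IntronKey:
        return (self.gene_id, self.interval.chrom, self.interval.start,
                self.interval.end)

    def counts_in(self, anatomical_system: str) -> tuple[int, int]:
        """(k_tumor, k_normal) junction-spanning EST support in one tissue."""
        return (
            self.support.get((anatomical_system, "tumor"), 0),
            self.support.get((anatomical_system, "normal"), 0),
        )

    def tissues(self) -> set[str]:
        """Anatomical systems with at least one supporting EST."""
        return {t for (t, _c), n in self.support.items() if n > 0}


@dataclass(frozen=True)
class TissueBackground:
    """Total normal and tumor EST counts pooled for one anatomical system."""

    anatomical_system: str
    n_normal: int
    n_tumor: int

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_tumor < 0:
            raise ValueError("background EST totals must be >= 0")


def backgrounds_from_libraries(
    libraries: Iterable[Library],
) -> dict[str, TissueBackground]:
    """Pool library sizes into per-tissue normal/tumor EST totals."""
    acc: dict[str, dict[str, int]] = defaultdict(lambda: {"normal": 0, "tumor": 0})
    for lib in libraries:
        acc[lib.anatomical_system][lib.condition] += lib.est_total
    return {
        t: TissueBackground(t, n_normal=v["normal"], n_tumor=v["tumor"])
        for t, v in sorted(acc.items())
    }


def infer_introns(
    ests: Sequence[EstRecord],
    libraries: Mapping[str, Library],
) -> list[Intron]:
    """Collect distinct introns implied by EST block gaps, with support counts.

    An EST supports an intron only if its block list contains that exact
    gap, i.e. it spans the junction with aligned sequence on both sides.
    Support counts distinct ESTs (duplicate records with the same est_id
    contribute once).  Output is sorted by intron key, so the result is
    invariant to EST input order.
    """
    support: dict[IntronKey, dict[tuple[str, str], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    seen: set[tuple[str, IntronKey]] = set()
    for est in ests:
        lib = libraries.get(est.library_id)
        if lib is None:
            raise KeyError(
                f"EST {est.est_id} references unknown library "
                f"{est.library_id!r}"
            )
        for gap in est.implied_introns():
            k = (est.gene_id, gap.chrom, gap.start, gap.end)
            if (est.est_id, k) in seen:
                continue
            seen.add((est.est_id, k))
            support[k][(lib.anatomical_system, lib.condition)] += 1
    out = []
    for k in sorted(support):
        gene_id, chrom, start, end = k
        out.append(
            Intron(gene_id, GenomeInterval(chrom, start, end),
                   dict(support[k]))
        )
    return out
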