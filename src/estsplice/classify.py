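"""Five-class tumor/normal labelling of genes and introns from EST counts.

For each entity (a gene, or one intron) in each anatomical system, the
observed EST counts from tumor and normal libraries are compared against
the tissue's pooled library sizes with two one-sided hypergeometric
tests.  Labels:

* ``TT`` / ``NN`` — exclusively expressed in tumor / normal (zero ESTs
  in the other condition) and the directional upper tail is significant;
* ``T`` / ``N``  — over-expressed in tumor / normal (significant upper
  tail, non-zero count in the other condition);
* ``E``          — no significant difference;
* ``UNCLASSIFIED`` — not tested (insufficient support, ineligible gene,
  or degenerate background), with the reason recorded.

Both an uncorrected label (at ``alpha``) and a Bonferroni-corrected one
(at ``alpha / m_tests``) are always emitted side by side.  The Bonferroni
family defaults to the entities of the same type tested within the same
tissue; ``family="global"`` uses the cross-tissue count instead.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (
    EstRecord,
    Intron,
    Library,
    TissueBackground,
)
from .stats import hypergeom_upper_tail

logger = logging.getLogger(__name__)

CLASS_LABELS = ("NN", "N", "E", "T", "TT", "UNCLASSIFIED")

#: Label sides used by event detection.
TUMOR_SIDE = frozenset({"T", "TT"})
NORMAL_SIDE = frozenset({"N", "NN"})

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GENE_ESTS = 10
DEFAULT_MIN_TISSUE_ESTS = 30_000
DEFAULT_MIN_TISSUES_FOR_CONCORDANCE = 5


@dataclass
class ClassificationResult:
    """Outcome of classifying one entity in one anatomical system."""

    entity_id: str
    anatomical_system: str
    k_tumor: int
    k_normal: int
    p_tumor: float
    p_normal: float
    m_tests: int
    label: str
    label_bonferroni: str
    reason: str | None = None

    @property
    def gene_id(self) -> str:
        """For intron entities (``gene:chrom:start-end``) the gene part."""
        return self.entity_id.split(":", 1)[0]


def _directional_label(p_tumor: float, p_normal: float, k_tumor: int,
                       k_normal: int, alpha: float) -> str:
    if p_tumor < alpha:
        return "TT" if k_normal == 0 else "T"
    if p_normal < alpha:
        return "NN" if k_tumor == 0 else "N"
    return "E"


def classify_entity(
    entity_id: str,
    k_tumor: int,
    k_normal: int,
    bg: TissueBackground,
    alpha: float = DEFAULT_ALPHA,
    m_tests: int = 1,
) -> ClassificationResult:
    """Classify one entity in one tissue from its tumor/normal EST counts.

    ``p_tumor`` is the upper tail of drawing ``k_tumor`` tumor ESTs out of
    ``k_tumor + k_normal`` draws from the tissue's pooled libraries;
    ``p_normal`` is the symmetric test.  For any margins the two one-sided
    p-values satisfy ``p_tumor + p_normal >= 1``, so at alpha <= 0.5 at
    most one direction can be significant.
    """
    if k_tumor < 0 or k_normal < 0:
        raise ValueError("EST counts must be >= 0")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if bg.n_tumor == 0 or bg.n_normal == 0:
        logger.debug(
            "%s/%s unclassified: zero background in one condition",
            entity_id, bg.anatomical_system,
        )
        return ClassificationResult(
            entity_id, bg.anatomical_system, k_tumor, k_normal,
            float("nan"), float("nan"), m_tests,
            "UNCLASSIFIED", "UNCLASSIFIED",
            reason="zero background in one condition",
        )
    n = k_tumor + k_normal
    N = bg.n_tumor + bg.n_normal
    if k_tumor > bg.n_tumor or k_normal > bg.n_normal:
        raise ValueError(
            f"{entity_id}: observed counts exceed tissue background "
            f"({k_tumor}/{bg.n_tumor} tumor, {k_normal}/{bg.n_normal} normal)"
        )
    p_tumor = hypergeom_upper_tail(k_tumor, bg.n_tumor, n, N)
    p_normal = hypergeom_upper_tail(k_normal, bg.n_normal, n, N)
    # The two one-sided tails overlap at k; their sum is >= 1 exactly.
    assert p_tumor + p_normal >= 1.0 - 1e-9
    return ClassificationResult(
        entity_id, bg.anatomical_system, k_tumor, k_normal,
        p_tumor, p_normal, m_tests,
        label=_directional_label(p_tumor, p_normal, k_tumor, k_normal, alpha),
        label_bonferroni=_directional_label(
            p_tumor, p_normal, k_tumor, k_normal, alpha / m_tests
        ),
    )


def eligible_tissues(
    backgrounds: Mapping[str, TissueBackground],
    min_per_condition: int = DEFAULT_MIN_TISSUE_ESTS,
) -> set[str]:
    """Anatomical systems with at least ``min_per_condition`` ESTs in
    both the normal and the tumor condition."""
    return {
        t for t, bg in backgrounds.items()
        if bg.n_normal >= min_per_condition and bg.n_tumor >= min_per_condition
    }


def count_gene_ests(
    ests: Sequence[EstRecord],
    libraries: Mapping[str, Library],
) -> dict[tuple[str, str], tuple[int, int]]:
    """Per-(gene, tissue) EST counts as (k_tumor, k_normal).

    All gene-mapped ESTs count here, junction-spanning or not; the
    junction-spanning requirement applies to intron support only.
    """
    acc: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for est in ests:
        lib = libraries.get(est.library_id)
        if lib is None:
            raise KeyError(
                f"EST {est.est_id} references unknown library "
                f"{est.library_id!r}"
            )
        idx = 0 if lib.condition == "tumor" else 1
        acc[(est.gene_id, lib.anatomical_system)][idx] += 1
    return {k: (v[0], v[1]) for k, v in acc.items()}


def classify_genes(
    gene_counts: Mapping[tuple[str, str], tuple[int, int]],
    backgrounds: Mapping[str, TissueBackground],
    min_ests: int = DEFAULT_MIN_GENE_ESTS,
    alpha: float = DEFAULT_ALPHA,
    family: str = "per-tissue",
) -> list[ClassificationResult]:
    """Classify every (gene, tissue) pair with enough EST support.

    Genes represented by fewer than ``min_ests`` ESTs in a tissue are
    emitted as UNCLASSIFIED there.  The Bonferroni family size is the
    number of gene tests actually performed in the same tissue
    (``family="per-tissue"``, default) or overall (``family="global"``).
    """
    if family not in ("per-tissue", "global"):
        raise ValueError(f"family must be 'per-tissue' or 'global', got {family!r}")
    eligible = {
        (g, t): c for (g, t), c in gene_counts.items()
        if t in backgrounds and sum(c) >= min_ests
    }
    per_tissue_m: dict[str, int] = defaultdict(int)
    for (_g, t) in eligible:
        per_tissue_m[t] += 1
    global_m = max(1, len(eligible))

    results = []
    for (gene, tissue), (k_t, k_n) in sorted(gene_counts.items()):
        if tissue not in backgrounds:
            continue
        if (gene, tissue) not in eligible:
            results.append(ClassificationResult(
                gene, tissue, k_t, k_n, float("nan"), float("nan"), 1,
                "UNCLASSIFIED", "UNCLASSIFIED",
                reason=f"fewer than {min_ests} ESTs",
            ))
            continue
        m = global_m if family == "global" else max(1, per_tissue_m[tissue])
        results.append(classify_entity(gene, k_t, k_n, backgrounds[tissue],
                                       alpha=alpha, m_tests=m))
    return results


def intron_entity_id(intron: Intron) -> str:
    iv = intron.interval
    return f"{intron.gene_id}:{iv.chrom}:{iv.start}-{iv.end}"


def classify_introns(
    introns: Sequence[Intron],
    gene_labels: Mapping[tuple[str, str], str],
    backgrounds: Mapping[str, TissueBackground],
    alpha: float = DEFAULT_ALPHA,
    family: str = "per-tissue",
    gene_classes_allowed: Iterable[str] = ("T", "N", "E"),
) -> list[ClassificationResult]:
    """Classify introns per tissue from junction-spanning EST support.

    Introns of genes labelled TT or NN in a tissue are skipped there
    (exclusively-expressed genes carry no within-gene splicing contrast),
    as are introns of genes that were not classifiable at all.  Each
    tissue is classified independently, so the same intron may be
    tumor-associated in one tissue and normal-associated in another.
    No minimum support floor is applied beyond statistical significance.
    """
    if family not in ("per-tissue", "global"):
        raise ValueError(f"family must be 'per-tissue' or 'global', got {family!r}")
    allowed = set(gene_classes_allowed)

    testable: list[tuple[Intron, str, int, int]] = []
    skipped: list[tuple[Intron, str, int, int, str]] = []
    for intron in introns:
        for tissue in sorted(intron.tissues()):
            if tissue not in backgrounds:
                continue
            k_t, k_n = intron.counts_in(tissue)
            glabel = gene_labels.get((intron.gene_id, tissue))
            if glabel in ("TT", "NN"):
                skipped.append((intron, tissue, k_t, k_n,
                                "gene exclusively expressed"))
            elif glabel not in allowed:
                skipped.append((intron, tissue, k_t, k_n,
                                "gene not classified"))
            else:
                testable.append((intron, tissue, k_t, k_n))

    per_tissue_m: dict[str, int] = defaultdict(int)
    for (_i, tissue, _kt, _kn) in testable:
        per_tissue_m[tissue] += 1
    global_m = max(1, len(testable))

    results = []
    for intron, tissue, k_t, k_n in testable:
        m = global_m if family == "global" else max(1, per_tissue_m[tissue])
        results.append(classify_entity(
            intron_entity_id(intron), k_t, k_n, backgrounds[tissue],
            alpha=alpha, m_tests=m,
        ))
    for intron, tissue, k_t, k_n, reason in skipped:
        results.append(ClassificationResult(
            intron_entity_id(intron), tissue, k_t, k_n,
            float("nan"), float("nan"), 1,
            "UNCLASSIFIED", "UNCLASSIFIED", reason=reason,
        ))
    results.sort(key=lambda r: (r.entity_id, r.anatomical_system))
    return results


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Cross-tissue concordance of directional intron labels."""

    n_heterogeneous: int
    n_homogeneous_tumor: int
    n_homogeneous_normal: int

    @property
    def n_total(self) -> int:
        return (self.n_heterogeneous + self.n_homogeneous_tumor
                + self.n_homogeneous_normal)

    def _pct(self, n: int) -> float:
        return round(100.0 * n / self.n_total, 1) if self.n_total else float("nan")

    @property
    def pct_heterogeneous(self) -> float:
        return self._pct(self.n_heterogeneous)

    @property
    def pct_homogeneous_tumor(self) -> float:
        return self._pct(self.n_homogeneous_tumor)

    @property
    def pct_homogeneous_normal(self) -> float:
        return self._pct(self.n_homogeneous_normal)


def heterogeneity_summary(
    intron_results: Sequence[ClassificationResult],
    min_tissues: int = DEFAULT_MIN_TISSUES_FOR_CONCORDANCE,
    label_field: str = "label",
) -> HeterogeneitySummary:
    """Concordance of intron labels across tissues.

    Considers introns carrying a directional label (N/NN or T/TT) in at
    least ``min_tissues`` tissues; such an intron is heterogeneous if
    both normal-side and tumor-side labels occur, otherwise homogeneously
    tumoral or normal.  Percentages are over that >= ``min_tissues`` set.
    """
    sides: dict[str, list[str]] = defaultdict(list)
    for r in intron_results:
        label = getattr(r, label_field)
        if label in TUMOR_SIDE:
            sides[r.entity_id].append("T")
        elif label in NORMAL_SIDE:
            sides[r.entity_id].append("N")
    het = hom_t = hom_n = 0
    for labels in sides.values():
        if len(labels) < min_tissues:
            continue
        s = set(labels)
        if s == {"T"}:
            hom_t += 1
        elif s == {"N"}:
            hom_n += 1
        else:
            het += 1
    return HeterogeneitySummary(het, hom_t, hom_n)
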