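"""GO biological-process enrichment of candidate gene sets.

Annotations are propagated up the ontology's ``is_a`` hierarchy (every
parent term up to the root), terms annotated to fewer than a
genome-scale floor of genes are discarded, and each remaining term is
tested with a one-sided Fisher exact test (enrichment direction) that
shares its hypergeometric kernel with the EST-count classification.
No multiple-testing correction is applied to GO p-values by default; a
plain p-value cut selects reported terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .stats import fisher_one_sided

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACE = "biological_process"
DEFAULT_MIN_GENOME = 50
DEFAULT_P_CUT = 0.01


class OntologyGraph:
    """A GO-style ontology restricted to its ``is_a`` parent relation."""

    def __init__(self, parents: Mapping[str, frozenset[str]],
                 names: Mapping[str, str],
                 namespaces: Mapping[str, str]):
        self.parents = {t: frozenset(p) for t, p in parents.items()}
        self.names = dict(names)
        self.namespaces = dict(namespaces)
        for term, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise ValueError(
                    f"term {term} has unknown parents {sorted(unknown)}"
                )
        self._check_acyclic()
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            g.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent relation contains a cycle")

    @classmethod
    def from_obo(cls, path: str) -> "OntologyGraph":
        """Load an OBO 1.2 file, keeping ``is_a`` edges only."""
        graph = obonet.read_obo(path)
        parents: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        namespaces: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            parents[term] = frozenset(data.get("is_a", []))
            names[term] = data.get("name", term)
            namespaces[term] = data.get("namespace", DEFAULT_NAMESPACE)
        return cls(parents, names, namespaces)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def roots(self) -> frozenset[str]:
        return frozenset(t for t, p in self.parents.items() if not p)

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        return frozenset(out)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable through ``is_a``, excluding ``term`` itself."""
        if term not in self.parents:
            raise KeyError(term)
        return self._ancestors(term)


def propagate_annotations(
    direct: Mapping[str, Iterable[str]],
    ontology: OntologyGraph,
    namespace: str | None = DEFAULT_NAMESPACE,
) -> dict[str, frozenset[str]]:
    """Close each gene's term set under the parent relation.

    Terms absent from the ontology are skipped with a logged count.
    With a ``namespace`` given (default biological_process), the closed
    sets are restricted to terms of that namespace; genes left with no
    terms are dropped.  The closure is a fixed point: propagating an
    already-propagated map changes nothing.
    """
    n_unknown = 0
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for term in terms:
            if term not in ontology:
                n_unknown += 1
                continue
            closed.add(term)
            closed.update(ontology.ancestors(term))
        if namespace is not None:
            closed = {t for t in closed if ontology.namespaces[t] == namespace}
        if closed:
            out[gene] = frozenset(closed)
    if n_unknown:
        logger.warning("skipped %d annotations to unknown terms", n_unknown)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested GO term."""

    term_id: str
    name: str
    k_set: int       # annotated genes in the query set
    n_set: int       # query set size
    K_genome: int    # annotated genes in the universe
    N_genome: int    # universe size
    p: float


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    ontology: OntologyGraph,
    min_genome: int = DEFAULT_MIN_GENOME,
    p_cut: float = DEFAULT_P_CUT,
    namespace: str | None = DEFAULT_NAMESPACE,
    restrict_universe_to_annotated: bool = True,
) -> list[EnrichmentResult]:
    """Test every genome-scale term for over-representation in ``query``.

    Annotations are propagated first; terms annotated to fewer than
    ``min_genome`` universe genes are discarded before testing.  By
    default the effective universe is the annotated subset of the given
    universe ("whole genome set" = genes with at least one propagated
    annotation); pass ``restrict_universe_to_annotated=False`` to keep
    unannotated genes in the denominator.  Results are sorted by
    p-value; only terms with p <= ``p_cut`` are returned (use
    ``p_cut=1.0`` for the full table).
    """
    query = set(query)
    universe = set(universe)
    missing = sorted(query - universe)
    if missing:
        raise ValueError(
            f"{len(missing)} query genes absent from the universe: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    propagated = propagate_annotations(annotations, ontology,
                                       namespace=namespace)
    if restrict_universe_to_annotated:
        universe = universe & propagated.keys()
        query = query & universe

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in propagated.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(universe), len(query)
    results = []
    for term, genes in term_genes.items():
        K = len(genes)
        if K < min_genome:
            continue
        k = len(genes & query)
        results.append(EnrichmentResult(
            term, ontology.names.get(term, term), k, n, K, N,
            fisher_one_sided(k, K, n, N),
        ))
    results.sort(key=lambda r: (r.p, r.term_id))
    return [r for r in results if r.p <= p_cut]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame (GO id, gene count, p, description)."""
    return pd.DataFrame(
        [{"term_id": r.term_id, "k_set": r.k_set, "n_set": r.n_set,
          "K_genome": r.K_genome, "N_genome": r.N_genome, "p": r.p,
          "description": r.name} for r in results],
        columns=["term_id", "k_set", "n_set", "K_genome", "N_genome",
                 "p", "description"],
    )
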