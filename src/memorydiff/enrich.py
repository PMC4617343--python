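"""Term enrichment over a DAG ontology with slim projection.

Annotations are projected onto a generic slim subset by replacing each
term with every slim term reachable through ``is_a`` ancestry
(including the term itself when it is in the slim). Over-representation
of each slim term in a study gene set against a population background
is scored with a one-sided Fisher exact test (hypergeometric upper
tail). The conventional background is the set of genes surviving the
expression filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom


class EnrichmentError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """is_a DAG over ontology terms plus a designated slim subset.

    ``graph`` follows the obonet convention: edges point child -> parent.
    """

    graph: nx.MultiDiGraph
    slim_subset: frozenset[str]

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise EnrichmentError("ontology is_a graph contains a cycle")
        unknown = self.slim_subset - set(self.graph.nodes)
        if unknown:
            raise EnrichmentError(f"slim terms absent from ontology: {sorted(unknown)}")

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus all is_a ancestors."""
        if term not in self.graph:
            raise EnrichmentError(f"unknown term id {term!r}")
        return {term} | nx.descendants(self.graph, term)

    def term_name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)


def load_ontology(obo_path, slim_terms: Iterable[str]) -> OntologyGraph:
    """Read an OBO file (id / name / namespace / is_a stanzas) and attach
    the slim subset."""
    import obonet

    graph = obonet.read_obo(obo_path)
    isa = nx.MultiDiGraph()
    isa.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            isa.add_edge(child, parent, key="is_a")
    return OntologyGraph(graph=isa, slim_subset=frozenset(slim_terms))


def map_to_slim(
    annotations: Mapping[str, Iterable[str]], ontology: OntologyGraph
) -> dict[str, set[str]]:
    """Project each gene's term set onto the slim: a gene inherits every
    slim term that is one of its terms or an is_a ancestor thereof."""
    unknown = sorted(
        {t for terms in annotations.values() for t in terms}
        - set(ontology.graph.nodes)
    )
    if unknown:
        raise EnrichmentError(f"unknown term ids in annotations: {unknown}")
    cache: dict[str, frozenset[str]] = {}

    def slim_of(term: str) -> frozenset[str]:
        if term not in cache:
            cache[term] = frozenset(ontology.ancestors(term) & ontology.slim_subset)
        return cache[term]

    return {
        gene: set().union(*(slim_of(t) for t in terms)) if terms else set()
        for gene, terms in annotations.items()
    }


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hit: int
    study_n: int
    pop_hit: int
    pop_n: int
    p_value: float

    def __post_init__(self):
        if not (
            0 <= self.study_hit <= self.study_n <= self.pop_n
            and self.study_hit <= self.pop_hit <= self.pop_n
        ):
            raise EnrichmentError(f"inconsistent contingency margins: {self}")


def fisher_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact over-representation test per term.

    For each term annotated in the population, the p-value is the
    hypergeometric upper tail P(X >= study_hit) for drawing ``study_n``
    genes from ``pop_n`` of which ``pop_hit`` carry the term. Results
    are ordered by p-value, then term id.
    """
    study_set = set(study)
    pop_set = set(population)
    if not study_set <= pop_set:
        extra = sorted(study_set - pop_set)[:5]
        raise EnrichmentError(f"study genes outside population, e.g. {extra}")
    pop_n = len(pop_set)
    study_n = len(study_set)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in pop_set:
        for term in set(annotations.get(gene, ())):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1
    results = []
    for term in sorted(term_pop):
        k = term_study.get(term, 0)
        K = term_pop[term]
        p = float(hypergeom.sf(k - 1, pop_n, K, study_n))
        results.append(
            EnrichmentResult(
                term_id=term,
                study_hit=k,
                study_n=study_n,
                pop_hit=K,
                pop_n=pop_n,
                p_value=min(p, 1.0),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_to_dataframe(
    results: Iterable[EnrichmentResult], **stratum_labels: str
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(stratum_labels)
        row.update(r.__dict__)
        rows.append(row)
    cols = list(stratum_labels) + [
        "term_id",
        "study_hit",
        "study_n",
        "pop_hit",
        "pop_n",
        "p_value",
    ]
    return pd.DataFrame(rows, columns=cols)
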