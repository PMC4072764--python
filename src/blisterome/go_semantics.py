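"""Information content and Resnik similarity over a GO DAG, redundant-term
reduction, and the top-similarity term graph.

The information content of a term is the negative log frequency of genes
annotated to the term or any of its descendants, relative to the genes
annotated to the namespace root: IC(root) = 0 and IC grows towards the
leaves.  Resnik similarity of two same-namespace terms is the IC of their
most informative common ancestor (MICA).  For the redundancy cutoff C the
similarity is normalised to [0, 1] by the maximum finite IC of the
annotation corpus, since raw Resnik values are unbounded.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .go_enrichment import AnnotationSet, EnrichmentResult


@dataclass
class GoDag:
    """An ``is_a`` ontology: term -> parent set, one root per namespace."""

    parents: dict[str, set[str]]
    namespace: dict[str, str]
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {child!r} is not a known term")
                if self.namespace[p] != self.namespace[child]:
                    raise ValueError(f"cross-namespace parent link {child!r} -> {p!r}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self._graph = g
        if not self.roots:
            for t, ps in self.parents.items():
                if not ps:
                    ns = self.namespace[t]
                    if ns in self.roots:
                        raise ValueError(f"namespace {ns!r} has multiple roots")
                    self.roots[ns] = t
        for ns in set(self.namespace.values()):
            if ns not in self.roots:
                raise ValueError(f"namespace {ns!r} has no root")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable via is_a edges (descendants in nx terms)."""
        anc = nx.descendants(self._graph, term)
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        desc = nx.ancestors(self._graph, term)
        if include_self:
            desc.add(term)
        return desc

    def depth(self, term: str) -> int:
        """Shortest is_a distance to the namespace root."""
        root = self.roots[self.namespace[term]]
        return nx.shortest_path_length(self._graph, term, root)

    def terms_in(self, namespace: str) -> set[str]:
        return {t for t, ns in self.namespace.items() if ns == namespace}


class TermIC:
    """Information content per term, natural-log units.

    Terms with no annotated gene in the corpus (even after propagation to
    descendants) carry an infinite sentinel and are skipped in MICA search.
    """

    def __init__(self, ic: Mapping[str, float], max_ic: float):
        self._ic = dict(ic)
        self.max_ic = max_ic

    def __getitem__(self, term: str) -> float:
        return self._ic[term]

    def get(self, term: str, default: float = math.inf) -> float:
        return self._ic.get(term, default)

    def items(self):
        return self._ic.items()


def information_content(dag: GoDag, annotations: AnnotationSet) -> TermIC:
    """Corpus-frequency information content with ancestor propagation.

    Gene counts are propagated upwards so that a term's count is the number
    of distinct genes annotated to it or to any descendant; the root count
    is the corpus size of its namespace.
    """
    counts: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in annotations.propagated.items():
        for t in terms:
            if t not in counts:
                raise ValueError(f"annotation to unknown term {t!r}")
            counts[t].add(gene)
    ic: dict[str, float] = {}
    max_ic = 0.0
    for t in dag.terms:
        root = dag.roots[dag.namespace[t]]
        root_n = len(counts[root])
        n = len(counts[t])
        if n == 0 or root_n == 0:
            ic[t] = math.inf
        else:
            ic[t] = -math.log(n / root_n)
            max_ic = max(max_ic, ic[t])
    return TermIC(ic, max_ic)


def resnik(t1: str, t2: str, dag: GoDag, ic: TermIC) -> float:
    """IC of the most informative common ancestor of two same-namespace terms."""
    if dag.namespace[t1] != dag.namespace[t2]:
        raise ValueError(
            f"terms {t1!r} and {t2!r} belong to different namespaces"
        )
    common = dag.ancestors(t1) & dag.ancestors(t2)
    finite = [ic[t] for t in common if math.isfinite(ic[t])]
    return max(finite, default=0.0)


def normalized_resnik(t1: str, t2: str, dag: GoDag, ic: TermIC) -> float:
    """Resnik similarity scaled to [0, 1] by the corpus maximum IC."""
    if ic.max_ic == 0:
        return 0.0
    return min(1.0, resnik(t1, t2, dag, ic) / ic.max_ic)


def reduce_terms(
    results: Sequence[EnrichmentResult],
    dag: GoDag,
    ic: TermIC,
    cutoff: float = 0.5,
) -> list[EnrichmentResult]:
    """Drop redundant enriched terms whose normalised similarity exceeds C.

    Iterative greedy reduction: among all surviving same-namespace pairs with
    normalised Resnik similarity above ``cutoff``, take the most similar pair
    and discard its member with the larger adjusted p-value (ties: the less
    informative term, then the lexicographically larger id).  Terminates when
    no surviving pair exceeds the cutoff; output order follows the input.
    """
    survivors = list(results)

    def sim(a: EnrichmentResult, b: EnrichmentResult) -> float:
        if dag.namespace[a.term_id] != dag.namespace[b.term_id]:
            return 0.0
        if a.term_id == b.term_id:
            return 1.0
        return normalized_resnik(a.term_id, b.term_id, dag, ic)

    while True:
        worst: tuple[float, int, int] | None = None
        for i, j in combinations(range(len(survivors)), 2):
            s = sim(survivors[i], survivors[j])
            if s > cutoff and (worst is None or s > worst[0]):
                worst = (s, i, j)
        if worst is None:
            break
        _, i, j = worst
        a, b = survivors[i], survivors[j]
        drop = _redundancy_loser(a, b, ic)
        survivors.remove(drop)
    return survivors


def _redundancy_loser(a: EnrichmentResult, b: EnrichmentResult, ic: TermIC) -> EnrichmentResult:
    if a.p_adjusted != b.p_adjusted:
        return a if a.p_adjusted > b.p_adjusted else b
    ia, ib = ic.get(a.term_id), ic.get(b.term_id)
    if ia != ib:
        return a if ia < ib else b   # keep the more informative term
    return max(a, b, key=lambda r: r.term_id)


def similarity_graph(
    results: Sequence[EnrichmentResult],
    dag: GoDag,
    ic: TermIC,
    top_fraction: float = 0.03,
) -> nx.Graph:
    """Term graph keeping only the strongest pairwise similarities as edges.

    Nodes are enriched terms annotated with IC (a specificity/size proxy)
    and the adjusted p-value (a shading proxy); edges carry the similarity
    weight.  Of the n(n-1)/2 pairs, the ceil(top_fraction * n_pairs)
    most similar are kept, breaking ties by term-id pair order.
    """
    if len(results) < 2:
        raise ValueError("a similarity graph needs at least two terms")
    g = nx.Graph()
    for r in results:
        g.add_node(r.term_id, ic=ic.get(r.term_id), p_adjusted=r.p_adjusted,
                   namespace=dag.namespace[r.term_id])
    pairs = []
    for a, b in combinations(sorted(r.term_id for r in results), 2):
        if dag.namespace[a] != dag.namespace[b]:
            s = 0.0
        else:
            s = resnik(a, b, dag, ic)
        pairs.append((-s, a, b))
    pairs.sort()
    n_keep = math.ceil(top_fraction * len(pairs))
    for negs, a, b in pairs[:n_keep]:
        g.add_edge(a, b, similarity=-negs)
    return g
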