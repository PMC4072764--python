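"""GO term over-representation against a custom background, and kappa-based
functional classification of genes by annotation co-occurrence.

The enrichment statistic is the EASE score: a conservative variant of the
one-sided Fisher exact test in which the observed overlap is decremented by
one before taking the hypergeometric upper tail.  With overlap k, list size
n, term background count K and background size N::

    p_EASE = P[X >= k - 1],   X ~ Hypergeometric(N, K, n)

so a single-gene overlap carries no evidence (p = 1).  Raw p-values are
corrected per namespace with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .phenotype_screen import GeneList

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class AnnotationSet:
    """Gene-to-term assignments, direct and ancestor-propagated.

    ``direct`` and ``propagated`` map gene_id -> set of term ids (terms of
    all namespaces mixed; the DAG knows each term's namespace).  Propagation
    closes annotations over ``is_a`` ancestors, so ``direct[g] <=
    propagated[g]`` for every gene.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.propagated)

    def terms_of(self, gene_id: str) -> set[str]:
        return self.propagated.get(gene_id, set())

    def term_to_genes(self, namespace_terms: set[str] | None = None) -> dict[str, set[str]]:
        """Invert the propagated map, optionally restricted to a term subset."""
        out: dict[str, set[str]] = {}
        for g, terms in self.propagated.items():
            for t in terms:
                if namespace_terms is None or t in namespace_terms:
                    out.setdefault(t, set()).add(g)
        return out


@dataclass
class EnrichmentResult:
    term_id: str
    k: int                       # target genes carrying the term
    n: int                       # target list size
    K: int                       # background genes carrying the term
    N: int                       # background size
    p_raw: float
    p_adjusted: float
    gene_ids: frozenset[str]
    significant: bool = False

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("overlap k exceeds min(n, K)")


def fisher_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided (upper tail) Fisher exact p-value, P[X >= k]."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def ease_pvalue(k: int, n: int, K: int, N: int) -> float:
    """EASE score: upper-tail hypergeometric with the overlap decremented by one."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return fisher_pvalue(k - 1, n, K, N)


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent contingency counts (k={k}, n={n}, K={K}, N={N})")


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    target: GeneList | set[str],
    annotations: AnnotationSet,
    background: set[str],
    namespace_terms: set[str],
    p_cutoff: float = 0.05,
    min_count: int = 2,
    method: str = "ease",
) -> list[EnrichmentResult]:
    """Test every term of one namespace for over-representation in ``target``.

    ``background`` is the custom gene universe (all screened genes);
    ``namespace_terms`` restricts testing to one GO namespace, and BH
    correction is applied within that namespace only.  Terms with overlap
    below ``min_count`` are not tested.  ``method`` selects 'ease'
    (default) or plain one-sided 'fisher'.
    """
    target_ids = target.gene_ids() if isinstance(target, GeneList) else set(target)
    if not target_ids <= background:
        raise ValueError("target genes must be a subset of the background")
    pfun = {"ease": ease_pvalue, "fisher": fisher_pvalue}[method]

    term_genes = annotations.term_to_genes(namespace_terms)
    N = len(background)
    n = len(target_ids)
    rows: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        bg_hits = term_genes[term] & background
        hits = bg_hits & target_ids
        k, K = len(hits), len(bg_hits)
        if k < min_count:
            continue
        rows.append(EnrichmentResult(
            term_id=term, k=k, n=n, K=K, N=N,
            p_raw=pfun(k, n, K, N), p_adjusted=1.0,
            gene_ids=frozenset(hits),
        ))
    adjusted = benjamini_hochberg([r.p_raw for r in rows])
    for r, adj in zip(rows, adjusted):
        r.p_adjusted = adj
        r.significant = adj < p_cutoff
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def kappa(gene_a_terms: set[str], gene_b_terms: set[str],
          term_universe: set[str]) -> float:
    """Cohen's kappa between two genes' binary annotation vectors.

    Measures above-chance agreement of term membership over
    ``term_universe``.  Degenerate vectors (both all-present or both
    all-absent over the universe) are defined as kappa 0.
    """
    if not term_universe:
        raise ValueError("term universe must be non-empty")
    a = gene_a_terms & term_universe
    b = gene_b_terms & term_universe
    t = len(term_universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = t - n11 - n10 - n01
    observed = (n11 + n00) / t
    expected = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (t * t)
    if expected == 1.0:
        return 0.0
    return (observed - expected) / (1.0 - expected)


def functional_classify(
    genes: Iterable[str],
    annotations: AnnotationSet,
    term_universe: set[str] | None = None,
    kappa_threshold: float = 0.35,
    membership: float = 0.5,
) -> tuple[list[set[str]], set[str]]:
    """Greedy seed-and-merge clustering of genes by annotation co-occurrence.

    Gene pairs with kappa >= ``kappa_threshold`` seed two-gene groups;
    groups are merged while any two share at least a ``membership`` fraction
    of the smaller group's members.  Returns ``(modules, unclustered)``
    where modules are sorted largest-first and unclustered genes belong to
    no seed pair.
    """
    gene_list = sorted(set(genes))
    if len(gene_list) < 2:
        raise ValueError("functional classification needs at least two genes")
    if term_universe is None:
        term_universe = set().union(*(annotations.terms_of(g) for g in gene_list)) or set()
    if not term_universe:
        return [], set(gene_list)

    groups: list[set[str]] = []
    for i, ga in enumerate(gene_list):
        ta = annotations.terms_of(ga)
        for gb in gene_list[i + 1:]:
            if kappa(ta, annotations.terms_of(gb), term_universe) >= kappa_threshold:
                groups.append({ga, gb})

    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(groups[i] & groups[j])
                if shared / min(len(groups[i]), len(groups[j])) >= membership:
                    groups[i] |= groups.pop(j)
                    merged = True
                    break
            if merged:
                break

    groups.sort(key=lambda g: (-len(g), sorted(g)))
    clustered = set().union(*groups) if groups else set()
    return groups, set(gene_list) - clustered
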