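"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic for a fixed seed and uses its own
pseudo-random stream (no global state).  The defaults emulate the study
conditions of a genome-scale RNAi wing screen:

* a screened universe of ~1600 genes annotated over a small GO-like DAG,
  with term sizes decaying geometrically with depth so that information
  content spreads realistically from root to leaves;
* hit lists degraded by a 29 % false-negative and 7 % false-positive rate;
* an interaction network containing a planted densely connected module
  (functionally coherent genes interact more than chance);
* a many-to-many fly-to-human orthology map, zero-inflated Poisson counts
  (mean ~2.45 orthologues per gene, ~11.5 % of genes unmapped);
* a gene/disease/organ-system table in which some genes hit several systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .go_enrichment import AnnotationSet
from .go_semantics import GoDag
from .ortholog_projection import OrthologyMap
from .phenotype_screen import GeneEntry, GeneList, ScreenRecord

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass(frozen=True)
class UniverseSpec:
    """Shape of the synthetic screened universe."""

    n_genes: int = 1573
    n_terms_per_namespace: int = 40
    dag_depth: int = 4
    annotation_rate: float = 0.06    # per gene-term probability at depth 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("universe needs at least 10 genes")
        if self.n_terms_per_namespace < 1 or self.dag_depth < 1:
            raise ValueError("n_terms_per_namespace and dag_depth must be positive")
        if not 0 <= self.annotation_rate <= 1:
            raise ValueError("annotation_rate must be a probability")


@dataclass(frozen=True)
class NetworkSpec:
    """Background random graph plus a planted dense module."""

    background_edge_prob: float = 0.002
    module_genes: frozenset[str] = frozenset()
    module_edge_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.background_edge_prob, self.module_edge_prob):
            if not 0 <= p <= 1:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.module_edge_prob < self.background_edge_prob:
            raise ValueError("module_edge_prob must be >= background_edge_prob")


@dataclass(frozen=True)
class ScreenSpec:
    """Noisy recovery of a true hit set by an RNAi screen."""

    true_positive_set: frozenset[str]
    false_negative_rate: float = 0.29
    false_positive_rate: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.false_negative_rate, self.false_positive_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def generate_universe(spec: UniverseSpec) -> tuple[GeneList, GoDag, AnnotationSet]:
    """Gene universe, layered GO-like DAG and direct+propagated annotations.

    Each namespace gets one root and ``n_terms_per_namespace`` further terms
    spread over ``dag_depth`` levels, every non-root term drawing >= 1
    parent from the level above.  A gene is directly annotated to a term at
    depth d with probability ``annotation_rate * 2**(1 - d)``: terms near
    the root annotate many genes, leaves few.  All genes are annotated to
    every namespace root by construction (propagation forces the root in).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"CG{i:04d}" for i in range(1, spec.n_genes + 1)]
    universe = GeneList("universe", {g: GeneEntry(sources={"screen"}, n_lines=1)
                                     for g in genes})

    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    term_depth: dict[str, int] = {}
    for ns_idx, ns in enumerate(NAMESPACES):
        prefix = f"GO:{ns_idx}"
        root = f"{prefix}000000"
        parents[root] = set()
        namespace[root] = ns
        term_depth[root] = 0
        levels: list[list[str]] = [[root]]
        tid = count(1)
        # distribute terms over depths as evenly as possible
        per_level = np.full(spec.dag_depth, spec.n_terms_per_namespace // spec.dag_depth)
        per_level[: spec.n_terms_per_namespace % spec.dag_depth] += 1
        for depth in range(1, spec.dag_depth + 1):
            level_terms: list[str] = []
            for _ in range(int(per_level[depth - 1])):
                t = f"{prefix}{next(tid):06d}"
                n_parents = 1 + int(rng.random() < 0.25)  # occasional multi-parent
                pool = levels[depth - 1]
                chosen = rng.choice(len(pool), size=min(n_parents, len(pool)),
                                    replace=False)
                parents[t] = {pool[i] for i in chosen}
                namespace[t] = ns
                term_depth[t] = depth
                level_terms.append(t)
            if level_terms:
                levels.append(level_terms)

    dag = GoDag(parents=parents, namespace=namespace)

    direct: dict[str, set[str]] = {g: set() for g in genes}
    for t, d in term_depth.items():
        if d == 0:
            continue
        p_annot = spec.annotation_rate * 2.0 ** (1 - d)
        hits = rng.random(spec.n_genes) < p_annot
        for g, h in zip(genes, hits):
            if h:
                direct[g].add(t)
    propagated = {
        g: propagate_annotations(terms, dag) | set(dag.roots.values())
        for g, terms in direct.items()
    }
    annotations = AnnotationSet(direct=direct, propagated=propagated)
    return universe, dag, annotations


def propagate_annotations(terms: set[str], dag: GoDag) -> set[str]:
    """Close a term set over is_a ancestors."""
    out: set[str] = set()
    for t in terms:
        out |= dag.ancestors(t, include_self=True)
    return out


def plant_enrichment(
    annotations: AnnotationSet,
    dag: GoDag,
    genes: Iterable[str],
    rate: float = 0.5,
    n_terms_per_namespace: int = 1,
    seed: int = 0,
) -> list[str]:
    """Preferentially annotate a gene subset to a few deep terms.

    Emulates a functionally coherent gene group: for each namespace the
    ``n_terms_per_namespace`` deepest terms are chosen and each supplied
    gene is directly annotated to each with probability ``rate``, after
    which the propagated closure is rebuilt.  Returns the chosen term ids,
    which downstream enrichment should flag against an unbiased background.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for ns in sorted(dag.roots):
        terms = sorted(dag.terms_in(ns), key=lambda t: (-dag.depth(t), t))
        chosen.extend(terms[:n_terms_per_namespace])
    for t in chosen:
        for g in sorted(genes):
            if rng.random() < rate:
                annotations.direct.setdefault(g, set()).add(t)
    annotations.propagated = {
        g: propagate_annotations(ts, dag) | set(dag.roots.values())
        for g, ts in annotations.direct.items()
    }
    return chosen


def generate_network(universe: GeneList, spec: NetworkSpec) -> nx.Graph:
    """Erdos-Renyi background with a planted dense module.

    Pairs inside ``module_genes`` connect with ``module_edge_prob``; all
    other pairs with ``background_edge_prob``.  Undirected, simple, no
    self-loops; every universe gene is present as a node.
    """
    genes = sorted(universe.gene_ids())
    module = set(spec.module_genes)
    if not module <= set(genes):
        raise ValueError("module genes must be a subset of the universe")
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    g.add_nodes_from(genes)

    idx = {gene: i for i, gene in enumerate(genes)}
    module_idx = np.array(sorted(idx[m] for m in module), dtype=int)
    in_module = np.zeros(len(genes), dtype=bool)
    in_module[module_idx] = True

    # vectorised Bernoulli over the upper triangle
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(in_module[iu] & in_module[ju],
                 spec.module_edge_prob, spec.background_edge_prob)
    keep = rng.random(p.size) < p
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep]))
    return g


def generate_orthology(
    fly_genes: GeneList | Iterable[str],
    mean_orthologues: float = 2.45,
    none_fraction: float = 0.115,
    seed: int = 0,
    source: str = "synthetic",
) -> OrthologyMap:
    """Zero-inflated shifted-Poisson orthologue counts per fly gene.

    ``mean_orthologues`` is the unconditional mean over *all* fly genes, so
    the expected total number of fly-human pairs is ``n_fly *
    mean_orthologues``.  A gene is unmapped with probability
    ``none_fraction``; otherwise its count is 1 + Poisson(lambda) with
    lambda chosen so the unconditional mean comes out right.  Human partners
    are drawn from a shared pool, so co-orthology (several fly genes hitting
    one human gene) occurs naturally.
    """
    genes = sorted(fly_genes.gene_ids() if isinstance(fly_genes, GeneList)
                   else set(fly_genes))
    if mean_orthologues <= 0:
        raise ValueError("mean_orthologues must be positive")
    if not 0 <= none_fraction <= 1:
        raise ValueError("none_fraction must be a probability")
    omap = OrthologyMap()
    if none_fraction == 1 or not genes:
        return omap
    lam = mean_orthologues / (1.0 - none_fraction) - 1.0
    if lam < 0:
        raise ValueError(
            "mean_orthologues / (1 - none_fraction) must be >= 1 for a shifted Poisson"
        )
    rng = np.random.default_rng(seed)
    pool_size = max(1, int(round(len(genes) * mean_orthologues * 0.8)))
    pool = [f"HS{i:05d}" for i in range(1, pool_size + 1)]
    for g in genes:
        if rng.random() < none_fraction:
            continue
        k = 1 + rng.poisson(lam)
        chosen = rng.choice(pool_size, size=min(k, pool_size), replace=False)
        for c in chosen:
            omap.add(g, pool[c], source)
    return omap


def generate_screen(universe: GeneList, spec: ScreenSpec) -> GeneList:
    """Noisy screen hit list: drop true hits at the FN rate, admit others at FP.

    Hits are labelled "blister" or "burned" arbitrarily half-and-half; the
    split carries no biological meaning in the synthetic setting, it only
    exercises downstream label handling.
    """
    tp = set(spec.true_positive_set)
    if not tp <= universe.gene_ids():
        raise ValueError("true positives must be a subset of the universe")
    rng = np.random.default_rng(spec.seed)
    members: dict[str, GeneEntry] = {}
    for g in sorted(universe.gene_ids()):
        if g in tp:
            take = rng.random() >= spec.false_negative_rate
        else:
            take = rng.random() < spec.false_positive_rate
        if take:
            label = "blister" if rng.random() < 0.5 else "burned"
            members[g] = GeneEntry(labels={label}, n_lines=1, sources={"screen"})
    return GeneList("screen_hits", members)


def generate_screen_records(
    universe: GeneList,
    hits: GeneList,
    lethal_rate: float = 0.011,
    other_visible_rate: float = 0.18,
    seed: int = 0,
) -> list[ScreenRecord]:
    """Line-level records for the whole universe, one line per gene.

    Non-hit genes are assigned 'lethal', 'other_visible' or 'none' so that
    phenotype fraction summaries have all categories populated.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, g in enumerate(sorted(universe.gene_ids()), start=1):
        if g in hits:
            ph = sorted(hits.members[g].labels)[0]
        else:
            u = rng.random()
            ph = "lethal" if u < lethal_rate else (
                "other_visible" if u < lethal_rate + other_visible_rate else "none")
        records.append(ScreenRecord(line_id=f"L{i:05d}", gene_id=g, phenotype=ph))
    return records


DEFAULT_ORGAN_SYSTEMS = (
    "musculoskeletal_and_skin", "cardiovascular", "cancer", "nervous",
    "sensory", "endocrine_metabolic", "immune", "blood", "respiratory",
    "digestive", "urogenital",
)


def generate_disease_table(
    human_genes: Iterable[str],
    disease_fraction: float = 190 / 877,
    n_systems: int = 11,
    mean_diseases: float = 1.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene/disease/organ-system table emulating OMIM/KEGG-style annotation.

    Each gene is disease-related with probability ``disease_fraction``; a
    related gene receives 1 + Poisson(mean_diseases - 1) diseases, each
    placed in one of ``n_systems`` organ-system categories (skewed so early
    categories dominate, as real disease classes do), so some genes span
    several systems.  Columns: human_gene, disease_name, source,
    icd_chapter, organ_system.
    """
    if n_systems < 1:
        raise ValueError("need at least one organ system")
    if not 0 <= disease_fraction <= 1:
        raise ValueError("disease_fraction must be a probability")
    systems = [DEFAULT_ORGAN_SYSTEMS[i] if i < len(DEFAULT_ORGAN_SYSTEMS)
               else f"system_{i + 1}" for i in range(n_systems)]
    weights = np.array([1.0 / (i + 1) for i in range(n_systems)])
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    rows = []
    disease_id = count(1)
    for g in sorted(set(human_genes)):
        if rng.random() >= disease_fraction:
            continue
        k = 1 + rng.poisson(max(0.0, mean_diseases - 1.0))
        for _ in range(k):
            d = next(disease_id)
            sys_idx = rng.choice(n_systems, p=weights)
            rows.append({
                "human_gene": g,
                "disease_name": f"disorder_{d:04d}",
                "source": "omim-like" if rng.random() < 0.7 else "kegg-like",
                "icd_chapter": f"ICD{sys_idx + 1:02d}",
                "organ_system": systems[sys_idx],
            })
    return pd.DataFrame(rows, columns=["human_gene", "disease_name", "source",
                                       "icd_chapter", "organ_system"])
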