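"""Fly-human orthology tables and interolog projection.

A human protein-protein interaction (H1, H2) is "translated" into fly space
by emitting a projected edge (A, B) for every fly pair with A orthologous to
H1 and B to H2.  Projected self-pairs (A == B) are discarded: they arise
when the two human partners are co-orthologues of the same fly gene, so an
apparent homodimerisation is usually an artefact of heterodimerisation
between duplicated human genes.  Native (fly) and projected edges are then
merged into one simple graph where each edge remembers the set of evidence
kinds supporting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

KINDS = ("genetic", "physical", "projected")


@dataclass(frozen=True)
class InteractionRecord:
    """An undirected interaction between two genes with an evidence kind."""

    gene_a: str
    gene_b: str
    kind: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not self.gene_a or not self.gene_b:
            raise ValueError("empty gene identifier in interaction record")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class OrthologyMap:
    """Many-to-many fly <-> human gene mapping with per-pair provenance."""

    forward: dict[str, set[str]] = field(default_factory=dict)
    reverse: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, fly_id: str, human_id: str, source: str = "") -> None:
        if not fly_id or not human_id:
            raise ValueError("empty identifier in orthology pair")
        self.forward.setdefault(fly_id, set()).add(human_id)
        self.reverse.setdefault(human_id, set()).add(fly_id)
        if source:
            self.provenance.setdefault((fly_id, human_id), set()).add(source)
        else:
            self.provenance.setdefault((fly_id, human_id), set())

    def n_pairs(self) -> int:
        return len(self.provenance)

    def fly_genes(self) -> set[str]:
        return set(self.forward)

    def human_genes(self) -> set[str]:
        return set(self.reverse)


def merge_orthology_sources(tables: Sequence[Iterable[tuple[str, str, str]]]) -> OrthologyMap:
    """Set-union of (fly, human, source) rows across source tables.

    Malformed rows (empty identifiers) are skipped with a warning; a table
    whose rows are all malformed raises, since silently dropping an entire
    source would bias the map.
    """
    omap = OrthologyMap()
    for idx, table in enumerate(tables):
        ok = bad = 0
        for row in table:
            try:
                fly, human, source = row
                omap.add(fly.strip(), human.strip(), source.strip())
                ok += 1
            except (ValueError, AttributeError) as exc:
                bad += 1
                logger.warning("orthology table %d: skipping row %r (%s)", idx, row, exc)
        if bad and not ok:
            raise ValueError(f"orthology table {idx} contained no parseable row")
    return omap


@dataclass
class TranslationReport:
    """Book-keeping from one projection run."""

    n_human_edges: int = 0
    n_untranslatable: int = 0     # at least one endpoint absent from the map
    n_self_loops_dropped: int = 0  # projected homodimer artefacts
    n_projected: int = 0           # unique fly pairs emitted


def translate_interactions(
    human_edges: Iterable[InteractionRecord],
    orthology: OrthologyMap,
    kinds: tuple[str, ...] = ("physical",),
    source: str = "interolog",
) -> tuple[list[InteractionRecord], TranslationReport]:
    """Project human interactions onto fly genes through the orthology map.

    Only records whose kind is in ``kinds`` are projected (physical by
    default; genetic interactions do not transfer across species the same
    way).  Human self-loops and projected fly self-pairs are discarded, and
    the output is deduplicated over unordered fly pairs.
    """
    report = TranslationReport()
    seen: set[tuple[str, str]] = set()
    out: list[InteractionRecord] = []
    for rec in human_edges:
        if rec.kind not in kinds:
            continue
        report.n_human_edges += 1
        if rec.gene_a == rec.gene_b:
            continue
        flies_a = orthology.reverse.get(rec.gene_a)
        flies_b = orthology.reverse.get(rec.gene_b)
        if not flies_a or not flies_b:
            report.n_untranslatable += 1
            continue
        for a in flies_a:
            for b in flies_b:
                if a == b:
                    report.n_self_loops_dropped += 1
                    continue
                pair = tuple(sorted((a, b)))
                if pair in seen:
                    continue
                seen.add(pair)
                out.append(InteractionRecord(pair[0], pair[1], "projected", source))
    report.n_projected = len(out)
    return out, report


def merge_networks(
    native: Iterable[InteractionRecord],
    projected: Iterable[InteractionRecord] = (),
) -> nx.Graph:
    """Merge interaction records into one undirected simple graph.

    Multiple records between the same unordered pair collapse into a single
    edge whose ``kinds`` attribute is the set of contributing evidence kinds
    and whose ``sources`` attribute unions the record sources.
    """
    g = nx.Graph()
    for rec in list(native) + list(projected):
        a, b = rec.pair
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["kinds"].add(rec.kind)
            if rec.source:
                g[a][b]["sources"].add(rec.source)
        else:
            g.add_edge(a, b, kinds={rec.kind}, sources={rec.source} if rec.source else set())
    return g
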