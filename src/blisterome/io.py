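"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular inputs are TSV with a header line; the ontology travels as a
minimal OBO subset (``id``, ``name``, ``namespace``, ``is_a`` only).  Graphs
export to SIF and GraphML.  Readers raise :class:`ParseError` with the file
and line of the first malformed record; ``write(read(x))`` preserves
canonical content for every format.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet
import pandas as pd

from .disease_mapping import DISEASE_COLUMNS
from .go_enrichment import AnnotationSet
from .go_semantics import GoDag
from .ortholog_projection import InteractionRecord, OrthologyMap, merge_orthology_sources
from .phenotype_screen import GeneEntry, GeneList, ScreenRecord


class ParseError(ValueError):
    def __init__(self, path: str | Path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _rows(path: str | Path, n_fields: int) -> Iterator[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_fields:
                raise ParseError(path, line_no,
                                 f"expected {n_fields} tab-separated fields, got {len(row)}")
            yield line_no, row


# ---------------------------------------------------------------- screen tables

def read_screen_table(path: str | Path) -> list[ScreenRecord]:
    """TSV with columns (line_id, gene_id, phenotype)."""
    records = []
    for line_no, row in _rows(path, 3):
        try:
            records.append(ScreenRecord(row[0].strip(), row[1].strip(), row[2].strip()))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
    return records


def write_screen_table(records: Iterable[ScreenRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["line_id", "gene_id", "phenotype"])
        for rec in records:
            w.writerow([rec.line_id, rec.gene_id, rec.phenotype])


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """TSV with columns (gene_id, labels, n_lines, sources); labels/sources ';'-joined."""
    members: dict[str, GeneEntry] = {}
    for line_no, row in _rows(path, 4):
        gene = row[0].strip()
        if not gene:
            raise ParseError(path, line_no, "empty gene_id")
        if gene in members:
            raise ParseError(path, line_no, f"duplicate gene_id {gene!r}")
        try:
            n_lines = int(row[2])
        except ValueError as exc:
            raise ParseError(path, line_no, f"bad line count {row[2]!r}") from exc
        members[gene] = GeneEntry(
            labels={s for s in row[1].split(";") if s},
            n_lines=n_lines,
            sources={s for s in row[3].split(";") if s},
        )
    return GeneList(name or Path(path).stem, members)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "labels", "n_lines", "sources"])
        for g in sorted(genes.members):
            e = genes.members[g]
            w.writerow([g, ";".join(sorted(e.labels)), e.n_lines,
                        ";".join(sorted(e.sources))])


def read_literature_list(path: str | Path, name: str = "literature") -> GeneList:
    """TSV with columns (gene_id, direction) where direction is lof or gof."""
    members: dict[str, GeneEntry] = {}
    for line_no, row in _rows(path, 2):
        gene, direction = row[0].strip(), row[1].strip()
        if direction not in ("lof", "gof"):
            raise ParseError(path, line_no, f"direction must be lof/gof, got {direction!r}")
        entry = members.setdefault(gene, GeneEntry(sources={"literature"}, n_lines=1))
        entry.labels.add(direction)
    return GeneList(name, members)


# ---------------------------------------------------------------- ontology / GAF

def write_obo(dag: GoDag, names: dict[str, str] | None, path: str | Path) -> None:
    """Minimal OBO: id, name, namespace, is_a stanzas only."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.parents):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {names.get(term, term)}\n")
            fh.write(f"namespace: {dag.namespace[term]}\n")
            for p in sorted(dag.parents[term]):
                fh.write(f"is_a: {p}\n")


def read_obo(path: str | Path) -> GoDag:
    """Parse an OBO file (is_a hierarchy); cycles are rejected with a report."""
    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        parents[term] = {v for _, v, k in graph.out_edges(term, keys=True) if k == "is_a"}
        namespace[term] = data.get("namespace", "default")
    return GoDag(parents=parents, namespace=namespace)  # GoDag validates acyclicity


def read_annotations(path: str | Path, dag: GoDag) -> AnnotationSet:
    """GAF-like TSV with columns (gene_id, term_id, namespace); propagates ancestors."""
    from .synthetic_data import propagate_annotations

    direct: dict[str, set[str]] = {}
    for line_no, row in _rows(path, 3):
        gene, term = row[0].strip(), row[1].strip()
        if term not in dag.terms:
            raise ParseError(path, line_no, f"unknown term {term!r}")
        direct.setdefault(gene, set()).add(term)
    propagated = {g: propagate_annotations(ts, dag) | set(dag.roots.values())
                  for g, ts in direct.items()}
    return AnnotationSet(direct=direct, propagated=propagated)


def write_annotations(annotations: AnnotationSet, dag: GoDag, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "term_id", "namespace"])
        for g in sorted(annotations.direct):
            for t in sorted(annotations.direct[g]):
                w.writerow([g, t, dag.namespace[t]])


# ---------------------------------------------------------------- interactions

def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """BioGRID TAB2-like TSV: (gene_a, gene_b, experimental_system_type, source)."""
    out = []
    for line_no, row in _rows(path, 4):
        try:
            out.append(InteractionRecord(row[0].strip(), row[1].strip(),
                                         row[2].strip(), row[3].strip()))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
    return out


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b", "experimental_system_type", "source"])
        for rec in records:
            w.writerow([rec.gene_a, rec.gene_b, rec.kind, rec.source])


def read_orthology(path: str | Path) -> OrthologyMap:
    """TSV with columns (fly_id, human_id, source)."""
    rows = [(row[0], row[1], row[2]) for _, row in _rows(path, 3)]
    return merge_orthology_sources([rows]) if rows else OrthologyMap()


def write_orthology(omap: OrthologyMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["fly_id", "human_id", "source"])
        for (fly, human), sources in sorted(omap.provenance.items()):
            w.writerow([fly, human, ";".join(sorted(sources))])


# ---------------------------------------------------------------- graphs / tables

def write_sif(graph: nx.Graph, path: str | Path,
              relation_attr: str | None = "kinds") -> None:
    """SIF export; the relation column joins the edge's evidence kinds."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            rel = data.get(relation_attr) if relation_attr else None
            rel = ";".join(sorted(rel)) if isinstance(rel, (set, frozenset)) else (rel or "pp")
            fh.write(f"{a}\t{rel}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        clean = {k: (";".join(sorted(v)) if isinstance(v, (set, frozenset)) else v)
                 for k, v in data.items()}
        g.add_edge(a, b, **clean)
    nx.write_graphml(g, path)


def read_disease_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DISEASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"disease table missing columns: {missing}")
    return df[DISEASE_COLUMNS]


def write_disease_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DISEASE_COLUMNS].to_csv(path, sep="\t", index=False)
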