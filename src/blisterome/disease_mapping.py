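"""Disease annotation of human orthologues and organ-system distributions.

A disease table holds one row per (gene, disease, organ-system) triple,
sourced from OMIM-like and KEGG-like records; the same gene-disease pair
reported by both sources collapses into one row with merged provenance.
Summaries count gene-to-system *assignments* (a gene affecting two systems
contributes two), which is the denominator under which the category shares
behave sensibly when genes are pleiotropic; per-gene counting is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._util import round_half_up

DISEASE_COLUMNS = ["human_gene", "disease_name", "source", "icd_chapter", "organ_system"]


@dataclass
class DistributionSummary:
    """Per-category counts/percentages and per-gene multiplicity histograms."""

    category_counts: dict[str, int]
    category_percent: dict[str, float]
    n_genes: int
    n_assignments: int
    genes_by_n_systems: dict[int, int]
    genes_by_n_diseases: dict[int, int]


def _as_frame(table: pd.DataFrame | Iterable[dict]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(list(table))
    if df.empty:
        return pd.DataFrame(columns=DISEASE_COLUMNS)
    missing = [c for c in DISEASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"disease table missing columns: {missing}")
    return df[DISEASE_COLUMNS]


def annotate_orthologues(orthologues: Iterable[str],
                         table: pd.DataFrame) -> pd.DataFrame:
    """Restrict the disease table to the supplied genes, collapsing duplicates.

    Rows with the same (gene, disease, organ_system) from different sources
    merge into one row whose ``source`` is the ';'-joined sorted union.
    """
    df = _as_frame(table)
    genes = set(orthologues)
    df = df[df["human_gene"].isin(genes)]
    if df.empty:
        return df.reset_index(drop=True)
    collapsed = (
        df.groupby(["human_gene", "disease_name", "organ_system"], as_index=False)
          .agg(source=("source", lambda s: ";".join(sorted(set(s)))),
               icd_chapter=("icd_chapter", "first"))
    )
    return collapsed[DISEASE_COLUMNS].sort_values(DISEASE_COLUMNS[:2]).reset_index(drop=True)


def system_distribution(annotated: pd.DataFrame,
                        per_gene: bool = False) -> DistributionSummary:
    """Organ-system distribution of disease-related genes.

    By default counts distinct (gene, organ_system) assignments; with
    ``per_gene=True`` the denominator is the number of distinct genes (so
    percentages may sum above 100 when genes are multi-system).
    """
    df = _as_frame(annotated)
    if df.empty:
        raise ValueError("empty disease table: no distribution to summarise")
    assignments = df[["human_gene", "organ_system"]].drop_duplicates()
    counts = assignments.groupby("organ_system").size().sort_values(ascending=False)
    n_genes = df["human_gene"].nunique()
    denom = n_genes if per_gene else len(assignments)
    percent = {cat: round_half_up(100.0 * n / denom, 1) for cat, n in counts.items()}
    hists = multiplicity_histogram(df)
    return DistributionSummary(
        category_counts=dict(counts),
        category_percent=percent,
        n_genes=n_genes,
        n_assignments=len(assignments),
        genes_by_n_systems=hists.genes_by_n_systems,
        genes_by_n_diseases=hists.genes_by_n_diseases,
    )


def multiplicity_histogram(annotated: pd.DataFrame) -> DistributionSummary:
    """Histogram of genes by the number of systems affected and diseases caused."""
    df = _as_frame(annotated)
    if df.empty:
        raise ValueError("empty disease table: no histogram to build")
    by_sys = df.groupby("human_gene")["organ_system"].nunique()
    by_dis = df.groupby("human_gene")["disease_name"].nunique()
    genes_by_n_systems = by_sys.value_counts().sort_index().to_dict()
    genes_by_n_diseases = by_dis.value_counts().sort_index().to_dict()
    assignments = df[["human_gene", "organ_system"]].drop_duplicates()
    return DistributionSummary(
        category_counts={}, category_percent={},
        n_genes=df["human_gene"].nunique(),
        n_assignments=len(assignments),
        genes_by_n_systems={int(k): int(v) for k, v in genes_by_n_systems.items()},
        genes_by_n_diseases={int(k): int(v) for k, v in genes_by_n_diseases.items()},
    )
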