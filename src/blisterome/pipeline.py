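"""End-to-end orchestration: screen lists -> enrichment -> term reduction ->
orthology projection -> network significance -> disease summary.

All randomness flows from one top-level seed through per-stage derived
seeds, so any single stage can be reproduced in isolation and two runs with
the same configuration emit byte-identical outputs.  Each run writes a
machine-readable manifest with the parameter values and per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as bio
from ._util import derive_seed
from .disease_mapping import annotate_orthologues, system_distribution
from .go_enrichment import NAMESPACES, enrich
from .go_semantics import information_content, reduce_terms, similarity_graph
from .network_analysis import (TESTED_STATS, connectivity_stats, induced_network,
                               ks_normality, monte_carlo_null, significance)
from .ortholog_projection import merge_networks, translate_interactions
from .phenotype_screen import combine_with_literature
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

STAGES = ("screen", "enrichment", "semantics", "projection", "network", "disease")


def _json(obj, **kwargs) -> str:
    """json.dumps tolerating numpy scalar types."""
    def default(o):
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    return json.dumps(obj, default=default, **kwargs)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    When the input paths are ``None`` the pipeline generates a synthetic
    bundle (via :mod:`blisterome.synthetic_data`) at the study-scale
    defaults; otherwise every stage reads the supplied files.
    """

    outdir: str = "blisterome_out"
    seed: int = 0
    # inputs (None -> synthesise)
    screen_table: str | None = None
    literature_list: str | None = None
    obo: str | None = None
    annotations: str | None = None
    fly_interactions: str | None = None
    human_interactions: str | None = None
    orthology: str | None = None
    disease_table: str | None = None
    # thresholds
    p_cutoff: float = 0.05
    reduction_cutoff: float = 0.5
    top_fraction: float = 0.03
    kappa_threshold: float = 0.35
    set_size: int = 358
    n_iter: int = 100
    # synthetic-bundle shape
    n_genes: int = 1573
    module_size: int = 358
    background_edge_prob: float = 0.002
    module_edge_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff <= 1 and 0 <= self.reduction_cutoff <= 1
                and 0 < self.top_fraction <= 1):
            raise ValueError("thresholds out of range")
        if self.n_iter < 1 or self.set_size < 1:
            raise ValueError("set_size and n_iter must be positive")


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dictionary.

    Outputs per stage land in ``config.outdir``; any stage failure aborts
    with a :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "parameters": asdict(config)}

    # ---- inputs ---------------------------------------------------------
    stage = "screen"
    try:
        bundle = _load_or_simulate(config, out)
        hits = bundle["hits"]
        combined = combine_with_literature(hits, bundle["literature"])
        bio.write_gene_list(combined, out / "combined_gene_list.tsv")
        manifest["stages"].append({"name": stage, "n_hits": len(hits),
                                   "n_combined": len(combined)})
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "enrichment"
    try:
        results_by_ns = {}
        for ns in NAMESPACES:
            ns_terms = bundle["dag"].terms_in(ns)
            res = enrich(combined.gene_ids() & bundle["universe"].gene_ids(),
                         bundle["annotations"], bundle["universe"].gene_ids(),
                         ns_terms, p_cutoff=config.p_cutoff)
            results_by_ns[ns] = res
            _write_enrichment(res, out / f"enrichment_{ns}.tsv")
        manifest["stages"].append({
            "name": stage,
            "significant": {ns: sum(r.significant for r in rs)
                            for ns, rs in results_by_ns.items()},
        })
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "semantics"
    try:
        ic = information_content(bundle["dag"], bundle["annotations"])
        significant = [r for rs in results_by_ns.values() for r in rs if r.significant]
        reduced = reduce_terms(significant, bundle["dag"], ic, cutoff=config.reduction_cutoff)
        _write_enrichment(reduced, out / "reduced_terms.tsv")
        if len(reduced) >= 2:
            tg = similarity_graph(reduced, bundle["dag"], ic,
                                  top_fraction=config.top_fraction)
            bio.write_graphml(tg, out / "term_graph.graphml")
            bio.write_sif(tg, out / "term_graph.sif", relation_attr=None)
        manifest["stages"].append({"name": stage, "n_significant": len(significant),
                                   "n_reduced": len(reduced)})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "projection"
    try:
        projected, report = translate_interactions(bundle["human_edges"],
                                                   bundle["orthology"])
        network = merge_networks(bundle["fly_edges"], projected)
        # keep all universe genes as potential nodes for the null sampling
        bio.write_sif(network, out / "merged_network.sif")
        bio.write_graphml(network, out / "merged_network.graphml")
        manifest["stages"].append({"name": stage, **asdict(report)})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "network"
    try:
        candidates = combined.gene_ids()
        observed = connectivity_stats(induced_network(candidates, network))
        null = monte_carlo_null(bundle["universe"].gene_ids(), network,
                                set_size=min(config.set_size, len(bundle["universe"])),
                                n_iter=config.n_iter,
                                seed=derive_seed(config.seed, "mc-null"))
        sig = significance(observed, null)
        normality = {k: ks_normality(null.samples[k])[0] for k in TESTED_STATS}
        stats_payload = {
            "observed": observed.as_dict(),
            "null_medians": {k: float(pd.Series(v).median())
                             for k, v in null.samples.items()},
            "significance": {k: {"fold_over_median": v.fold_over_median, "p": v.p}
                             for k, v in sig.items()},
            "ks_normality_p": normality,
        }
        (out / "network_stats.json").write_text(_json(stats_payload, indent=2))
        pd.DataFrame(null.samples).to_csv(out / "null_samples.tsv", sep="\t", index=False)
        manifest["stages"].append({"name": stage, **stats_payload})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "disease"
    try:
        orthologues = set().union(*(bundle["orthology"].forward.get(g, set())
                                    for g in combined.gene_ids())) \
            if bundle["orthology"].forward else set()
        annotated = annotate_orthologues(orthologues, bundle["disease_table"])
        if len(annotated):
            summary = system_distribution(annotated)
            payload = {
                "n_disease_genes": summary.n_genes,
                "n_assignments": summary.n_assignments,
                "category_percent": summary.category_percent,
                "genes_by_n_systems": summary.genes_by_n_systems,
                "genes_by_n_diseases": summary.genes_by_n_diseases,
            }
        else:
            payload = {"n_disease_genes": 0}
        (out / "disease_summary.json").write_text(_json(payload, indent=2))
        bio.write_disease_table(annotated, out / "disease_annotated.tsv")
        manifest["stages"].append({"name": stage, **payload})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(_json(manifest, indent=2, sort_keys=True))
    return manifest


def _write_enrichment(results, path) -> None:
    rows = [{"term": r.term_id, "count": r.k, "list_size": r.n,
             "background_count": r.K, "background_size": r.N,
             "p": r.p_raw, "benjamini": r.p_adjusted,
             "significant": r.significant,
             "genes": ";".join(sorted(r.gene_ids))} for r in results]
    pd.DataFrame(rows, columns=["term", "count", "list_size", "background_count",
                                "background_size", "p", "benjamini", "significant",
                                "genes"]).to_csv(path, sep="\t", index=False)


def _load_or_simulate(config: PipelineConfig, out: Path) -> dict:
    """Assemble the input bundle from files, synthesising whatever is missing."""
    seed = config.seed
    bundle: dict = {}
    if config.obo and config.annotations and config.screen_table:
        bundle["dag"] = bio.read_obo(config.obo)
        bundle["annotations"] = bio.read_annotations(config.annotations, bundle["dag"])
        records = bio.read_screen_table(config.screen_table)
        from .phenotype_screen import GeneList, GeneEntry
        bundle["universe"] = GeneList("universe", {
            r.gene_id: GeneEntry(sources={"screen"}, n_lines=1) for r in records})
        from .phenotype_screen import GeneList as GL
        bundle["hits"] = GL.from_records("screen_hits", records)
    else:
        uni, dag, ann = syn.generate_universe(syn.UniverseSpec(
            n_genes=config.n_genes, seed=derive_seed(seed, "universe")))
        bundle.update(universe=uni, dag=dag, annotations=ann)
        genes = sorted(uni.gene_ids())
        module = frozenset(genes[: config.module_size])
        bundle["module"] = module
        # the planted module is functionally coherent: shared deep terms
        bundle["planted_terms"] = syn.plant_enrichment(
            ann, dag, module, seed=derive_seed(seed, "plant"))
        bundle["hits"] = syn.generate_screen(uni, syn.ScreenSpec(
            true_positive_set=module, seed=derive_seed(seed, "screen")))

    if config.literature_list:
        bundle["literature"] = bio.read_literature_list(config.literature_list)
    else:
        # literature recovers a slice of the module, plus noise
        module = sorted(bundle.get("module", bundle["hits"].gene_ids()))
        from .phenotype_screen import GeneList
        lit_genes = module[: max(1, len(module) // 3)]
        bundle["literature"] = GeneList.from_genes("literature", lit_genes,
                                                   label="lof", source="literature")

    if config.fly_interactions:
        bundle["fly_edges"] = bio.read_interactions(config.fly_interactions)
    else:
        net = syn.generate_network(bundle["universe"], syn.NetworkSpec(
            background_edge_prob=config.background_edge_prob,
            module_genes=frozenset(bundle.get("module", set())),
            module_edge_prob=config.module_edge_prob,
            seed=derive_seed(seed, "network")))
        from .ortholog_projection import InteractionRecord
        rng_kind = (lambda i: "physical" if i % 2 else "genetic")
        bundle["fly_edges"] = [InteractionRecord(a, b, rng_kind(i), "synthetic")
                               for i, (a, b) in enumerate(sorted(net.edges()))]

    if config.orthology:
        try:
            bundle["orthology"] = bio.read_orthology(config.orthology)
        except Exception as exc:
            raise StageError("projection", exc) from exc
    else:
        bundle["orthology"] = syn.generate_orthology(
            bundle["universe"], seed=derive_seed(seed, "orthology"))

    if config.human_interactions:
        try:
            bundle["human_edges"] = bio.read_interactions(config.human_interactions)
        except Exception as exc:
            raise StageError("projection", exc) from exc
    else:
        from .ortholog_projection import InteractionRecord
        humans = sorted(bundle["orthology"].human_genes())
        bundle["human_edges"] = [
            InteractionRecord(humans[i], humans[i + 1], "physical", "synthetic")
            for i in range(0, len(humans) - 1, 7)
        ]

    if config.disease_table:
        bundle["disease_table"] = bio.read_disease_table(config.disease_table)
    else:
        bundle["disease_table"] = syn.generate_disease_table(
            bundle["orthology"].human_genes(), seed=derive_seed(seed, "disease"))
    return bundle
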