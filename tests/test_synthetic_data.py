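import math

import numpy as np
import pytest

from blisterome import synthetic_data as syn
from blisterome.phenotype_screen import GeneEntry, GeneList


def _universe(n):
    return GeneList("u", {f"CG{i:04d}": GeneEntry() for i in range(1, n + 1)})


class TestGenerateUniverse:
    def test_fixed_seed_determinism(self):
        a = syn.generate_universe(syn.UniverseSpec(n_genes=10, seed=1))
        b = syn.generate_universe(syn.UniverseSpec(n_genes=10, seed=1))
        assert a[0].gene_ids() == b[0].gene_ids()
        assert a[1].parents == b[1].parents
        assert a[2].direct == b[2].direct
        assert a[2].propagated == b[2].propagated

    def test_zero_annotation_rate_roots_only(self):
        _, dag, ann = syn.generate_universe(syn.UniverseSpec(
            n_genes=12, annotation_rate=0.0, seed=2))
        assert all(not ts for ts in ann.direct.values())
        roots = set(dag.roots.values())
        assert all(ts == roots for ts in ann.propagated.values())

    def test_study_scale_gene_count(self):
        uni, _, _ = syn.generate_universe(syn.UniverseSpec(n_genes=1573, seed=7))
        assert len(uni) == 1573

    def test_dag_shape(self):
        _, dag, _ = syn.generate_universe(syn.UniverseSpec(
            n_genes=20, n_terms_per_namespace=9, dag_depth=3, seed=3))
        assert len(dag.roots) == 3
        for ns, root in dag.roots.items():
            assert len(dag.terms_in(ns)) == 10  # 9 terms + root
        # every non-root term reaches its namespace root
        for t in dag.terms:
            root = dag.roots[dag.namespace[t]]
            assert root in dag.ancestors(t)

    def test_terms_near_root_annotate_more_genes(self):
        """Term sizes decay with depth (geometric spread for non-trivial IC)."""
        _, dag, ann = syn.generate_universe(syn.UniverseSpec(
            n_genes=800, n_terms_per_namespace=12, dag_depth=3,
            annotation_rate=0.3, seed=4))
        counts_by_depth: dict[int, list[int]] = {}
        term_genes = ann.term_to_genes()
        for t in dag.terms:
            d = dag.depth(t)
            if d > 0:
                counts_by_depth.setdefault(d, []).append(len(term_genes.get(t, set())))
        means = {d: np.mean(v) for d, v in counts_by_depth.items()}
        assert means[1] > means[3]

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            syn.UniverseSpec(n_genes=5)
        with pytest.raises(ValueError):
            syn.UniverseSpec(annotation_rate=1.5)


class TestGenerateNetwork:
    def test_forced_triangle(self):
        uni = _universe(10)
        module = frozenset(sorted(uni.gene_ids())[:3])
        g = syn.generate_network(uni, syn.NetworkSpec(
            background_edge_prob=0.0, module_edge_prob=1.0,
            module_genes=module, seed=0))
        assert g.number_of_edges() == 3
        assert set().union(*map(set, g.edges())) == set(module)

    def test_edgeless(self):
        g = syn.generate_network(_universe(10), syn.NetworkSpec(
            background_edge_prob=0.0, module_edge_prob=0.0, seed=0))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 10

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_network(_universe(5), syn.NetworkSpec(
                module_genes=frozenset({"ALIEN"}), seed=0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            syn.NetworkSpec(background_edge_prob=0.5, module_edge_prob=0.1)

    def test_study_scale_module_degree(self):
        """1600 genes, 358-gene module at p = 0.05: mean within-module degree
        within 20 % of the binomial expectation 0.05 x 357."""
        uni = _universe(1600)
        module = frozenset(sorted(uni.gene_ids())[:358])
        g = syn.generate_network(uni, syn.NetworkSpec(
            background_edge_prob=0.002, module_edge_prob=0.05,
            module_genes=module, seed=3))
        within = g.subgraph(module)
        mean_deg = 2 * within.number_of_edges() / 358
        assert abs(mean_deg - 0.05 * 357) / (0.05 * 357) < 0.2

    def test_within_module_density_converges(self):
        """Empirical module density within 3 s.e. of module_edge_prob."""
        uni = _universe(500)
        module = frozenset(sorted(uni.gene_ids())[:200])
        p = 0.07
        g = syn.generate_network(uni, syn.NetworkSpec(
            background_edge_prob=0.0, module_edge_prob=p,
            module_genes=module, seed=11))
        n_pairs = 200 * 199 // 2
        density = g.number_of_edges() / n_pairs
        se = math.sqrt(p * (1 - p) / n_pairs)
        assert abs(density - p) < 3 * se


class TestGenerateOrthology:
    def test_none_fraction_one_empty(self):
        omap = syn.generate_orthology(_universe(20), none_fraction=1.0, seed=0)
        assert omap.n_pairs() == 0

    def test_every_gene_mapped_mean_one(self):
        uni = _universe(30)
        omap = syn.generate_orthology(uni, mean_orthologues=1.0,
                                      none_fraction=0.0, seed=1)
        assert omap.fly_genes() == uni.gene_ids()
        assert all(len(v) >= 1 for v in omap.forward.values())

    def test_study_scale_total_mappings(self):
        """358 genes at mean 2.45 / 11.5 % unmapped: total pairs within 15 %
        of the Poisson expectation 877."""
        omap = syn.generate_orthology(_universe(358), mean_orthologues=2.45,
                                      none_fraction=0.115, seed=11)
        total = sum(len(v) for v in omap.forward.values())
        assert abs(total - 877) / 877 < 0.15

    def test_forward_reverse_consistency(self):
        omap = syn.generate_orthology(_universe(40), seed=5)
        for fly, humans in omap.forward.items():
            for h in humans:
                assert fly in omap.reverse[h]

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_orthology(_universe(10), mean_orthologues=0.5,
                                   none_fraction=0.1, seed=0)


class TestGenerateScreen:
    def test_perfect_screen_identity(self):
        uni = _universe(50)
        tp = frozenset(sorted(uni.gene_ids())[:20])
        out = syn.generate_screen(uni, syn.ScreenSpec(
            true_positive_set=tp, false_negative_rate=0.0,
            false_positive_rate=0.0, seed=0))
        assert out.gene_ids() == set(tp)

    def test_total_false_negative_empty(self):
        uni = _universe(50)
        tp = frozenset(sorted(uni.gene_ids())[:20])
        out = syn.generate_screen(uni, syn.ScreenSpec(
            true_positive_set=tp, false_negative_rate=1.0,
            false_positive_rate=0.0, seed=0))
        assert len(out) == 0

    def test_mean_recovery_at_study_rates(self):
        """208 true positives at FN = 0.29: mean recovered over seeds near
        208 x 0.71 = 147.7."""
        uni = _universe(300)
        tp = frozenset(sorted(uni.gene_ids())[:208])
        recovered = [len(syn.generate_screen(uni, syn.ScreenSpec(
            true_positive_set=tp, false_negative_rate=0.29,
            false_positive_rate=0.0, seed=s))) for s in range(60)]
        mean = np.mean(recovered)
        se = math.sqrt(208 * 0.29 * 0.71 / 60)
        assert abs(mean - 147.68) < 4 * se

    def test_recovery_rate_converges_to_one_minus_fn(self):
        uni = _universe(400)
        tp = frozenset(sorted(uni.gene_ids())[:300])
        for fn in (0.1, 0.5):
            rates = [len(syn.generate_screen(uni, syn.ScreenSpec(
                true_positive_set=tp, false_negative_rate=fn,
                false_positive_rate=0.0, seed=s)).gene_ids() & tp) / 300
                for s in range(40)]
            assert np.mean(rates) == pytest.approx(1 - fn, abs=0.03)

    def test_labels_half_half(self):
        uni = _universe(600)
        tp = frozenset(uni.gene_ids())
        out = syn.generate_screen(uni, syn.ScreenSpec(
            true_positive_set=tp, false_negative_rate=0.0,
            false_positive_rate=0.0, seed=3))
        labels = [next(iter(e.labels)) for e in out.members.values()]
        frac = labels.count("blister") / len(labels)
        assert 0.4 < frac < 0.6


class TestGenerateDiseaseTable:
    GENES = [f"HS{i:04d}" for i in range(877)]

    def test_zero_fraction_empty(self):
        df = syn.generate_disease_table(self.GENES, disease_fraction=0.0, seed=0)
        assert df.empty

    def test_full_fraction_single_system(self):
        genes = self.GENES[:30]
        df = syn.generate_disease_table(genes, disease_fraction=1.0,
                                        n_systems=1, seed=1)
        assert set(df["human_gene"]) == set(genes)
        assert set(df["organ_system"]) == {"musculoskeletal_and_skin"}

    def test_study_scale_disease_gene_count(self):
        """877 genes at fraction 190/877: disease-gene count within 15 % of
        the binomial expectation 190."""
        df = syn.generate_disease_table(self.GENES, disease_fraction=190 / 877,
                                        seed=5)
        n = df["human_gene"].nunique()
        assert abs(n - 190) / 190 < 0.15

    def test_some_genes_multi_system(self):
        df = syn.generate_disease_table(self.GENES, disease_fraction=0.5,
                                        mean_diseases=2.5, seed=2)
        per_gene = df.groupby("human_gene")["organ_system"].nunique()
        assert (per_gene > 1).any()

    def test_determinism(self):
        a = syn.generate_disease_table(self.GENES, seed=9)
        b = syn.generate_disease_table(self.GENES, seed=9)
        assert a.equals(b)


class TestPlantEnrichment:
    def test_planted_terms_enriched_in_module(self):
        uni, dag, ann = syn.generate_universe(syn.UniverseSpec(n_genes=300, seed=6))
        module = sorted(uni.gene_ids())[:60]
        terms = syn.plant_enrichment(ann, dag, module, rate=0.6, seed=7)
        assert len(terms) == 3  # one per namespace
        for t in terms:
            carriers = {g for g, ts in ann.propagated.items() if t in ts}
            in_mod = len(carriers & set(module)) / 60
            out_mod = len(carriers - set(module)) / (300 - 60)
            assert in_mod > out_mod + 0.2
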