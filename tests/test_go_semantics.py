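import math
from itertools import combinations

import pytest

from blisterome.go_enrichment import EnrichmentResult
from blisterome.go_semantics import (GoDag, information_content,
                                     normalized_resnik, reduce_terms, resnik,
                                     similarity_graph)
from conftest import TOY_DIRECT, TOY_PARENTS
from _oracles import ic_bruteforce, resnik_bruteforce


class TestGoDag:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GoDag(parents={"a": {"b"}, "b": {"a"}},
                  namespace={"a": "bp", "b": "bp"})

    def test_cross_namespace_parent_rejected(self):
        with pytest.raises(ValueError, match="cross-namespace"):
            GoDag(parents={"r1": set(), "r2": set(), "x": {"r2"}},
                  namespace={"r1": "bp", "r2": "cc", "x": "bp"})

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="multiple roots"):
            GoDag(parents={"r1": set(), "r2": set()},
                  namespace={"r1": "bp", "r2": "bp"})

    def test_ancestors(self, toy_dag):
        assert toy_dag.ancestors("D") == {"D", "A", "B", "R"}
        assert toy_dag.ancestors("R") == {"R"}


class TestInformationContent:
    def test_hand_propagated_toy_corpus(self, toy_dag, toy_annotations):
        """IC values equal -log of hand-propagated term frequencies."""
        ic = information_content(toy_dag, toy_annotations)
        expected = {"R": 0.0, "A": -math.log(5 / 8), "B": math.log(2),
                    "C": math.log(4), "D": math.log(4), "E": math.log(8)}
        for t, v in expected.items():
            assert ic[t] == pytest.approx(v)
        assert ic.max_ic == pytest.approx(math.log(8))

    def test_matches_recursive_oracle(self, toy_dag, toy_annotations):
        oracle = ic_bruteforce(TOY_PARENTS, "R", TOY_DIRECT)
        ic = information_content(toy_dag, toy_annotations)
        for t in TOY_PARENTS:
            assert ic[t] == pytest.approx(oracle[t])

    def test_root_zero_and_half_corpus(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        assert ic["R"] == 0.0
        assert ic["B"] == pytest.approx(math.log(2))  # covers 4 of 8 genes

    def test_unannotated_term_infinite(self, toy_dag):
        from blisterome.go_enrichment import AnnotationSet
        ann = AnnotationSet(direct={"g": {"C"}}, propagated={"g": {"C", "A", "R"}})
        ic = information_content(toy_dag, ann)
        assert math.isinf(ic["E"])

    def test_unknown_term_rejected(self, toy_dag):
        from blisterome.go_enrichment import AnnotationSet
        ann = AnnotationSet(direct={"g": {"Z"}}, propagated={"g": {"Z"}})
        with pytest.raises(ValueError, match="unknown term"):
            information_content(toy_dag, ann)

    def test_monotone_from_root_to_leaves(self, toy_dag, toy_annotations):
        """IC never decreases along any parent -> child edge."""
        ic = information_content(toy_dag, toy_annotations)
        for child, parents in TOY_PARENTS.items():
            for p in parents:
                assert ic[child] >= ic[p] - 1e-12


class TestResnik:
    def test_self_similarity_is_own_ic(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        for t in ("C", "D", "E", "A"):
            assert resnik(t, t, toy_dag, ic) == pytest.approx(ic[t])

    def test_root_only_common_ancestor(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        assert resnik("C", "E", toy_dag, ic) == 0.0

    def test_mid_level_mica(self, toy_dag, toy_annotations):
        """For (C, D) the MICA is A; for (D, E) it is B."""
        ic = information_content(toy_dag, toy_annotations)
        assert resnik("C", "D", toy_dag, ic) == pytest.approx(ic["A"])
        assert resnik("D", "E", toy_dag, ic) == pytest.approx(ic["B"])

    def test_matches_bruteforce_on_all_toy_pairs(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        ic_flat = {t: ic[t] for t in TOY_PARENTS}
        for a, b in combinations(TOY_PARENTS, 2):
            assert resnik(a, b, toy_dag, ic) == pytest.approx(
                resnik_bruteforce(a, b, TOY_PARENTS, ic_flat))

    def test_matches_bruteforce_on_synthetic_dag(self):
        from blisterome import synthetic_data as syn
        _, dag, ann = syn.generate_universe(syn.UniverseSpec(
            n_genes=60, n_terms_per_namespace=12, seed=5))
        ic = information_content(dag, ann)
        ic_flat = dict(ic.items())
        ns_terms = sorted(dag.terms_in("biological_process"))
        for a, b in combinations(ns_terms, 2):
            assert resnik(a, b, dag, ic) == pytest.approx(
                resnik_bruteforce(a, b, dag.parents, ic_flat))

    def test_mica_bound(self, toy_dag, toy_annotations):
        """resnik(a, b) <= min(IC(a), IC(b)) for every pair."""
        ic = information_content(toy_dag, toy_annotations)
        for a, b in combinations(TOY_PARENTS, 2):
            assert resnik(a, b, toy_dag, ic) <= min(ic[a], ic[b]) + 1e-12

    def test_cross_namespace_rejected(self):
        dag = GoDag(parents={"r1": set(), "r2": set()},
                    namespace={"r1": "bp", "r2": "cc"})
        from blisterome.go_enrichment import AnnotationSet
        ic = information_content(dag, AnnotationSet(
            direct={"g": set()}, propagated={"g": {"r1", "r2"}}))
        with pytest.raises(ValueError):
            resnik("r1", "r2", dag, ic)


def _res(term, p_adj):
    return EnrichmentResult(term_id=term, k=2, n=10, K=5, N=100,
                            p_raw=p_adj, p_adjusted=p_adj,
                            gene_ids=frozenset())


class TestReduceTerms:
    def test_all_dissimilar_unchanged(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        results = [_res("C", 0.01), _res("E", 0.02)]  # similarity 0 via root
        assert reduce_terms(results, toy_dag, ic, cutoff=0.5) == results

    def test_duplicate_term_keeps_smaller_p(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        keep, drop = _res("C", 0.01), _res("C", 0.02)
        assert reduce_terms([drop, keep], toy_dag, ic, cutoff=0.5) == [keep]

    def test_redundant_pair_reduced_to_bruteforce_minimum(self, toy_dag,
                                                          toy_annotations):
        """The D/E/B triangle has pairwise normalised similarity 1/3, above
        a cutoff of 0.3; survivors match the exhaustive minimum-loss
        reduction ({C} plus one triangle member)."""
        ic = information_content(toy_dag, toy_annotations)
        results = [_res("C", 0.01), _res("D", 0.03), _res("E", 0.02),
                   _res("B", 0.04)]
        cutoff = 0.3
        reduced = reduce_terms(results, toy_dag, ic, cutoff=cutoff)

        def ok(subset):
            return all(normalized_resnik(a.term_id, b.term_id, toy_dag, ic) <= cutoff
                       for a, b in combinations(subset, 2))

        best = max((s for r in range(len(results) + 1)
                    for s in combinations(results, r) if ok(s)), key=len)
        assert len(reduced) == len(best)
        assert ok(reduced)

    def test_no_surviving_pair_above_cutoff(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        results = [_res(t, 0.01 * i) for i, t in enumerate(["A", "B", "C", "D", "E"], 1)]
        for cutoff in (0.2, 0.5, 0.8):
            reduced = reduce_terms(results, toy_dag, ic, cutoff=cutoff)
            assert set(r.term_id for r in reduced) <= {r.term_id for r in results}
            for a, b in combinations(reduced, 2):
                assert normalized_resnik(a.term_id, b.term_id, toy_dag, ic) <= cutoff

    def test_empty_input(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        assert reduce_terms([], toy_dag, ic) == []


class TestSimilarityGraph:
    def test_two_terms_single_edge(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        g = similarity_graph([_res("C", 0.01), _res("D", 0.02)], toy_dag, ic)
        assert g.number_of_edges() == 1
        assert g.has_edge("C", "D")

    def test_equal_similarities_forced_edge_count(self):
        """With all pairwise similarities equal the kept-edge count is
        exactly ceil(top_fraction * n_pairs)."""
        parents = {"r": set(), **{f"t{i}": {"r"} for i in range(10)}}
        dag = GoDag(parents=parents, namespace={t: "bp" for t in parents})
        from blisterome.go_enrichment import AnnotationSet
        ann = AnnotationSet(direct={"g": {"t0"}}, propagated={"g": {"t0", "r"}})
        ic = information_content(dag, ann)
        results = [_res(f"t{i}", 0.01) for i in range(10)]
        g = similarity_graph(results, dag, ic, top_fraction=0.03)
        assert g.number_of_edges() == math.ceil(0.03 * 45)

    def test_edges_are_the_top_ranked_pairs(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        results = [_res(t, 0.01) for t in ("C", "D", "E", "B")]
        g = similarity_graph(results, toy_dag, ic, top_fraction=0.3)
        sims = {(a, b): resnik(a, b, toy_dag, ic)
                for a, b in combinations(sorted(r.term_id for r in results), 2)}
        ranked = sorted(sims, key=lambda p: (-sims[p], p))
        n_keep = math.ceil(0.3 * len(sims))
        assert set(map(frozenset, g.edges())) == set(map(frozenset, ranked[:n_keep]))

    def test_node_attributes(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        g = similarity_graph([_res("C", 0.01), _res("D", 0.02)], toy_dag, ic)
        assert g.nodes["C"]["ic"] == pytest.approx(ic["C"])
        assert g.nodes["D"]["p_adjusted"] == 0.02

    def test_single_term_rejected(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, toy_annotations)
        with pytest.raises(ValueError):
            similarity_graph([_res("C", 0.01)], toy_dag, ic)
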