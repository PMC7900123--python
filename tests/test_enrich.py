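import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom, kstest

from crossvar.enrich import (
    AnnotationMap,
    EnrichmentConfig,
    EnrichmentResult,
    OntologyDAG,
    elim_enrichment,
    enrichment_report,
    fisher_classic,
    load_ontology,
    propagate_annotations,
    run_enrichment,
    weight_enrichment,
)


def dag_from_edges(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)  # child -> parent
    return OntologyDAG(g)


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            dag_from_edges([("a", "b"), ("b", "a")])

    def test_levels_put_children_below_parents(self):
        dag = dag_from_edges([("c", "b"), ("b", "a"), ("c", "a")])
        lv = dag.levels()
        assert lv["a"] == 0 and lv["b"] == 1 and lv["c"] == 2

    def test_obo_round_trip(self, tmp_path, bundle):
        p = tmp_path / "x.obo"
        p.write_text(bundle.obo)
        dag = load_ontology(str(p))
        assert len(dag) == bundle.config.n_go_terms
        assert dag.roots == ["GO:0000001"]
        # every term reaches the root
        for t in dag.graph.nodes:
            assert t == "GO:0000001" or "GO:0000001" in dag.ancestors(t)


class TestPropagation:
    def test_chain_propagates_to_all_ancestors(self):
        dag = dag_from_edges([("c", "b"), ("b", "a")])
        direct = AnnotationMap.from_pairs([("g", "c")])
        prop = propagate_annotations(direct, dag)
        assert prop.gene2terms["g"] == {"a", "b", "c"}

    def test_idempotent(self):
        dag = dag_from_edges([("c", "b"), ("b", "a")])
        prop = propagate_annotations(AnnotationMap.from_pairs([("g", "c")]), dag)
        again = propagate_annotations(prop, dag)
        assert again.gene2terms == prop.gene2terms

    def test_unknown_term_dropped_or_raises(self):
        dag = dag_from_edges([("b", "a")])
        direct = AnnotationMap.from_pairs([("g", "zzz"), ("g", "b")])
        prop = propagate_annotations(direct, dag)
        assert prop.gene2terms["g"] == {"a", "b"}
        with pytest.raises(KeyError):
            propagate_annotations(direct, dag, on_unknown="error")

    def test_subset_invariant_on_random_dag(self, bundle, tmp_path):
        """True-path rule: genes(child) is a subset of genes(parent) for
        every is_a edge after propagation."""
        p = tmp_path / "b.obo"
        p.write_text(bundle.obo)
        dag = load_ontology(str(p))
        direct = AnnotationMap.from_pairs(bundle.gene2go)
        prop = propagate_annotations(direct, dag)
        for child, parent in dag.graph.edges:
            assert prop.term2genes.get(child, set()) <= prop.term2genes.get(parent, set())


class TestFisherClassic:
    def test_hand_enumerated_table(self):
        # universe 10, term 5 genes, study of 4 all inside the term:
        # p = C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        study = {f"g{i}" for i in range(4)}
        p = fisher_classic(study, universe, {"t": term})["t"]
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_term_covering_universe_is_one(self):
        universe = {f"g{i}" for i in range(8)}
        p = fisher_classic({"g0", "g1"}, universe, {"t": set(universe)})["t"]
        assert p == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_classic(set(), {"g"}, {})
        with pytest.raises(ValueError):
            fisher_classic({"x"}, {"g"}, {})  # study not inside universe

    def test_matches_exhaustive_enumeration_small_universes(self):
        """p equals the exact hypergeometric tail summed term by term for
        every random table with universe <= 25."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            N = int(rng.integers(2, 26))
            genes = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(genes, size=K, replace=False))
            study = set(rng.choice(genes, size=n, replace=False))
            x = len(term & study)
            exact = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(x, min(K, n) + 1)
            )
            p = fisher_classic(study, set(genes), {"t": term})["t"]
            assert p == pytest.approx(exact, rel=1e-9, abs=1e-12)

    def test_null_pvalues_approximately_uniform(self):
        """Random study sets give near-uniform p-values (the test is exact,
        so its null distribution is uniform up to discreteness)."""
        rng = np.random.default_rng(41)
        N, K, n = 5000, 2500, 1000
        genes = np.arange(N)
        universe = set(genes.tolist())
        term = set(rng.choice(genes, size=K, replace=False).tolist())
        pvals = []
        for _ in range(1000):
            study = set(rng.choice(genes, size=n, replace=False).tolist())
            pvals.append(fisher_classic(study, universe, {"t": term})["t"])
        assert kstest(pvals, "uniform").pvalue > 0.01


def _weighted_fisher_oracle(weights, study, N, n):
    K = round(sum(weights.values()))
    x = round(sum(w for g, w in weights.items() if g in study))
    if K == 0 or n == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(x - 1, N, K, n)))


class TestWeight:
    def test_flat_ontology_equals_classic(self):
        """With all terms as direct children of the root and disjoint gene
        sets, no decorrelation is possible."""
        edges = [(f"t{i}", "root") for i in range(4)]
        dag = dag_from_edges(edges)
        genes = [f"g{i}" for i in range(20)]
        term2genes = {f"t{i}": set(genes[5 * i: 5 * i + 5]) for i in range(4)}
        term2genes["root"] = set(genes)
        universe = set(genes)
        study = {"g0", "g1", "g2", "g5"}
        classic = fisher_classic(study, universe, term2genes)
        method = weight_enrichment(dag, study, universe, term2genes)
        for t in term2genes:
            if t == "root":
                # the universe term stays uninformative (its significant
                # children are decorrelated from it)
                assert method[t] > 0.9
            else:
                assert method[t] == pytest.approx(classic[t], abs=1e-12)

    def test_child_explains_parent_signal(self):
        """Five-term DAG executed step by step with an independent weighted
        Fisher: the child holding all study genes keeps its classic p; the
        parent, annotated partly through the child, is decorrelated to 1."""
        dag = dag_from_edges([("C", "P"), ("P", "R"), ("X", "R"), ("Y", "R")])
        genes = [f"g{i}" for i in range(20)]
        universe = set(genes)
        study = set(genes[:5])
        term2genes = {
            "C": set(genes[:5]),
            "P": set(genes[:10]),  # C's genes plus five more (propagated)
            "X": set(genes[10:15]),
            "Y": set(genes[15:20]),
            "R": set(genes),
        }
        N, n = 20, 5
        # independent execution: C is a leaf, its p stays classic
        p_c = float(hypergeom.sf(4, N, 5, n))
        # P initially: 5 of 10 annotated in study
        p_p0 = float(hypergeom.sf(4, N, 10, n))
        assert p_p0 > p_c  # the child is more significant
        # C's genes are down-weighted in P by p_c / p_p0, then P is retested
        w_p = {g: (p_c / p_p0 if g in term2genes["C"] else 1.0) for g in term2genes["P"]}
        p_p_expect = _weighted_fisher_oracle(w_p, study, N, n)

        method = weight_enrichment(dag, study, universe, term2genes)
        assert method["C"] == pytest.approx(p_c, abs=1e-12)
        assert method["P"] == pytest.approx(p_p_expect, abs=1e-12)
        assert method["P"] >= fisher_classic(study, universe, term2genes)["P"]

    def test_planted_term_reported_ancestors_not(self):
        dag = dag_from_edges([("C", "P"), ("P", "R"), ("X", "R")])
        genes = [f"g{i}" for i in range(40)]
        universe = set(genes)
        study = set(genes[:8])
        term2genes = {
            "C": set(genes[:8]),
            "P": set(genes[:20]),
            "X": set(genes[20:30]),
            "R": set(genes),
        }
        results = []
        method = weight_enrichment(dag, study, universe, term2genes)
        classic = fisher_classic(study, universe, term2genes)
        for t in method:
            ann = term2genes[t]
            results.append(EnrichmentResult(t, t, len(ann), len(ann & study),
                                            len(ann) * len(study) / len(universe),
                                            classic[t], method[t]))
        table = enrichment_report(results, EnrichmentConfig(alpha=0.001, method="weight"))
        assert list(table.term) == ["C"]


class TestElim:
    def test_significant_child_genes_removed_from_ancestors(self):
        dag = dag_from_edges([("C", "P"), ("P", "R")])
        genes = [f"g{i}" for i in range(30)]
        universe = set(genes)
        study = set(genes[:6])
        term2genes = {"C": set(genes[:6]), "P": set(genes[:12]), "R": set(genes)}
        method = elim_enrichment(dag, study, universe, term2genes, elim_cutoff=0.01)
        classic = fisher_classic(study, universe, term2genes)
        assert method["C"] == pytest.approx(classic["C"])
        assert method["P"] > classic["P"]  # C's genes were eliminated


class TestReport:
    def _results(self, pvals):
        return [EnrichmentResult(t, t, 10, 5, 2.5, p, p) for t, p in pvals.items()]

    def test_empty_when_nothing_significant(self):
        table = enrichment_report(self._results({"a": 0.5, "b": 0.02}),
                                  EnrichmentConfig(alpha=0.001))
        assert table.empty

    def test_alpha_one_reports_everything_sorted(self):
        table = enrichment_report(self._results({"a": 0.5, "b": 0.02, "c": 0.9}),
                                  EnrichmentConfig(alpha=0.999999))
        assert list(table.term) == ["b", "a", "c"]

    def test_run_enrichment_on_bundle_annotations(self, bundle, tmp_path):
        p = tmp_path / "b.obo"
        p.write_text(bundle.obo)
        dag = load_ontology(str(p))
        ann = AnnotationMap.from_pairs(bundle.gene2go)
        term = bundle.enriched_terms[0]
        study = set(bundle.enriched_genes[term])
        results = run_enrichment(dag, ann, study, EnrichmentConfig(method="weight"))
        by_term = {r.term: r for r in results}
        assert by_term[term].significant == len(study)
        assert by_term[term].p_method <= 1e-6
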