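"""Topology-aware GO-term enrichment.

Candidate gene sets are tested for over-represented GO terms against the
universe of all genes with at least one annotation, using the one-sided
Fisher exact (hypergeometric) test.  Because annotations propagate to
ancestor terms (the true-path rule), parent and child terms are strongly
correlated; the *weight* algorithm decorrelates them by comparing each
term with its children and down-weighting genes in the less significant
node before recomputing a weighted test, and the simpler *elim* algorithm
removes the genes of significant children from their ancestors outright.
No multiple-testing correction is applied by default: terms are reported
at a raw p-value cutoff (0.001 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationMap",
    "EnrichmentConfig",
    "EnrichmentResult",
    "load_ontology",
    "read_gene2go",
    "propagate_annotations",
    "fisher_classic",
    "weight_enrichment",
    "elim_enrichment",
    "run_enrichment",
    "enrichment_report",
]


class OntologyDAG:
    """is_a-linked GO terms as a directed acyclic graph (edges child->parent)."""

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph is cyclic")
        self.graph = graph
        self.roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        for n in graph.nodes:
            if graph.out_degree(n) == 0:
                continue
            # reachability to a root is implied by acyclicity + finite graph
        self._levels: dict[str, int] | None = None

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term: str) -> set:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set:
        """All terms reachable via is_a edges (excluding the term itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set:
        return nx.ancestors(self.graph, term)

    def levels(self) -> dict:
        """Term -> longest is_a path length from a root (roots are level 0).

        Guarantees level(child) > level(parent), so processing terms in
        decreasing level order visits every child before its parents.
        """
        if self._levels is None:
            lv: dict[str, int] = {}
            for n in nx.topological_sort(self.graph.reverse(copy=False)):
                preds = list(self.graph.successors(n))  # parents
                lv[n] = 0 if not preds else 1 + max(lv[p] for p in preds)
            self._levels = lv
        return self._levels

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)


def load_ontology(path: str) -> OntologyDAG:
    """Read an OBO file, keeping only is_a edges."""
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    g.add_nodes_from((n, d) for n, d in multi.nodes(data=True))
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    return OntologyDAG(g)


@dataclass
class AnnotationMap:
    """Gene -> term sets and the inverse, optionally true-path propagated."""

    gene2terms: dict = field(default_factory=dict)
    term2genes: dict = field(default_factory=dict)
    propagated: bool = False

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "AnnotationMap":
        m = cls()
        for gene, term in pairs:
            m.gene2terms.setdefault(gene, set()).add(term)
            m.term2genes.setdefault(term, set()).add(gene)
        return m

    @property
    def genes(self) -> set:
        return set(self.gene2terms)


def read_gene2go(path: str) -> AnnotationMap:
    """Read a two-column gene<TAB>term file (comment lines start with #)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            pairs.append((gene, term))
    return AnnotationMap.from_pairs(pairs)


def propagate_annotations(
    direct: AnnotationMap,
    dag: OntologyDAG,
    on_unknown: str = "drop",
) -> AnnotationMap:
    """Close annotations under is_a ancestry (true-path rule); idempotent.

    Annotations to terms absent from the ontology are dropped with a
    warning (``on_unknown='drop'``) or raise (``'error'``).
    """
    out = AnnotationMap(propagated=True)
    for gene, terms in direct.gene2terms.items():
        full: set = set()
        for t in terms:
            if t not in dag:
                if on_unknown == "error":
                    raise KeyError(f"annotation to unknown term {t}")
                logger.warning("gene %s annotated to unknown term %s: dropped", gene, t)
                continue
            full.add(t)
            full |= dag.ancestors(t)
        if full:
            out.gene2terms[gene] = full
            for t in full:
                out.term2genes.setdefault(t, set()).add(gene)
    return out


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.001
    method: str = "weight"  # classic | weight | elim
    elim_cutoff: float = 0.01
    min_annotated: int = 2  # terms with fewer universe genes are untestable

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("classic", "weight", "elim"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    annotated: int
    significant: int
    expected: float
    p_classic: float
    p_method: float


def _fisher_p(x: int, big_n: int, big_k: int, n: int) -> float:
    """One-sided over-representation p: P(X >= x), X ~ Hypergeom(N, K, n)."""
    if big_k == 0 or n == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(x - 1, big_n, big_k, n)))


def fisher_classic(study: set, universe: set, term2genes: Mapping) -> dict:
    """Classic one-sided Fisher test per term; no topology adjustment."""
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    big_n, n = len(universe), len(study)
    out = {}
    for term, genes in term2genes.items():
        ann = genes & universe
        out[term] = _fisher_p(len(ann & study), big_n, len(ann), n)
    return out


def _weighted_fisher(weights: Mapping, study: set, big_n: int, n: int) -> float:
    big_k = round(sum(weights.values()))
    x = round(sum(w for g, w in weights.items() if g in study))
    return _fisher_p(x, big_n, big_k, n)


def weight_enrichment(
    dag: OntologyDAG,
    study: set,
    universe: set,
    term2genes: Mapping,
    min_annotated: int = 2,
) -> dict:
    """Decorrelating *weight* algorithm over the annotation-induced DAG.

    Terms are processed bottom-up (children before parents).  At each term
    u its significance is compared with each child's: genes belonging to a
    more significant child are down-weighted in u and all of u's ancestors
    by the p-value ratio before u's weighted test is recomputed; children
    less significant than u have their genes down-weighted locally and
    their p recomputed.  On a flat ontology the result equals the classic
    Fisher test.
    """
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    big_n, n = len(universe), len(study)
    tested = {
        t: genes & universe
        for t, genes in term2genes.items()
        if t in dag and len(genes & universe) >= min_annotated
    }
    skipped = set(term2genes) - set(tested)
    if skipped:
        logger.info("skipping %d terms with < %d annotated genes", len(skipped), min_annotated)

    weights: dict[str, dict] = {t: {g: 1.0 for g in genes} for t, genes in tested.items()}
    sig: dict[str, float] = {}

    def term_sig(t: str) -> float:
        return _weighted_fisher(weights[t], study, big_n, n)

    def compute_term_sig(u: str, children: set):
        sig[u] = term_sig(u)
        if not children:
            return
        ratios = {v: sig[u] / sig[v] if sig[v] > 0 else float("inf") for v in children}
        more_sig = {v for v in children if ratios[v] >= 1.0}
        if not more_sig:
            # u is locally most significant: its children inherit a penalty
            for v in children:
                f = ratios[v]  # p_u / p_v < 1
                for g in weights[v]:
                    weights[v][g] *= f
                sig[v] = term_sig(v)
            return
        # children more significant than u: down-weight their genes in u
        # and everything above u, then retest u against remaining children
        up = (dag.ancestors(u) & set(tested)) | {u}
        for v in more_sig:
            f = 1.0 / ratios[v] if ratios[v] != float("inf") else 0.0  # p_v / p_u <= 1
            for g in weights[v]:
                for a in up:
                    if g in weights[a]:
                        weights[a][g] *= f
        compute_term_sig(u, children - more_sig)

    levels = dag.levels()
    order = sorted(tested, key=lambda t: levels[t], reverse=True)
    for u in order:
        children = dag.children(u) & set(tested)
        compute_term_sig(u, children)
    return sig


def elim_enrichment(
    dag: OntologyDAG,
    study: set,
    universe: set,
    term2genes: Mapping,
    elim_cutoff: float = 0.01,
    min_annotated: int = 2,
) -> dict:
    """*elim* algorithm: genes of a significant term are removed from all
    of its ancestors before those are tested."""
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    big_n, n = len(universe), len(study)
    tested = {
        t: set(genes & universe)
        for t, genes in term2genes.items()
        if t in dag and len(genes & universe) >= min_annotated
    }
    eliminated: dict[str, set] = {t: set() for t in tested}
    sig: dict[str, float] = {}
    levels = dag.levels()
    for u in sorted(tested, key=lambda t: levels[t], reverse=True):
        genes = tested[u] - eliminated[u]
        sig[u] = _fisher_p(len(genes & study), big_n, len(genes), n)
        if sig[u] <= elim_cutoff:
            for a in dag.ancestors(u):
                if a in eliminated:
                    eliminated[a] |= tested[u]
    return sig


def run_enrichment(
    dag: OntologyDAG,
    annotations: AnnotationMap,
    study: set,
    cfg: EnrichmentConfig | None = None,
) -> list:
    """Full enrichment of a study set: propagation, classic p, method p.

    The universe is every gene with at least one (propagated) annotation;
    study genes without annotations are ignored.  Returns a list of
    :class:`EnrichmentResult` for every testable term.
    """
    cfg = cfg or EnrichmentConfig()
    ann = annotations if annotations.propagated else propagate_annotations(annotations, dag)
    universe = ann.genes
    study = set(study) & universe
    if not study:
        raise ValueError("study set has no annotated genes")
    classic = fisher_classic(study, universe, ann.term2genes)
    if cfg.method == "classic":
        method_p = classic
    elif cfg.method == "weight":
        method_p = weight_enrichment(dag, study, universe, ann.term2genes, cfg.min_annotated)
    else:
        method_p = elim_enrichment(dag, study, universe, ann.term2genes, cfg.elim_cutoff, cfg.min_annotated)
    results = []
    for term, p in method_p.items():
        genes = ann.term2genes[term] & universe
        annotated = len(genes)
        significant = len(genes & study)
        results.append(EnrichmentResult(
            term=term,
            name=dag.name(term),
            annotated=annotated,
            significant=significant,
            expected=annotated * len(study) / len(universe),
            p_classic=classic[term],
            p_method=p,
        ))
    return results


def enrichment_report(results: Iterable[EnrichmentResult], cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Terms at p_method <= alpha, sorted ascending by p_method."""
    cfg = cfg or EnrichmentConfig()
    rows = [
        {
            "term": r.term, "name": r.name, "annotated": r.annotated,
            "significant": r.significant, "expected": round(r.expected, 2),
            "p_classic": r.p_classic, "p_method": r.p_method,
        }
        for r in sorted(results, key=lambda r: (r.p_method, r.term))
        if r.p_method <= cfg.alpha
    ]
    return pd.DataFrame(rows, columns=[
        "term", "name", "annotated", "significant", "expected", "p_classic", "p_method",
    ])
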