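"""Protein-GO association scoring: RandomWalk, Degree, One-Hop, Hypergeometric.

The RandomWalk score runs personalized PageRank restarting from the
proteins annotated to the query GO term t, with damping factor
alpha = 0.7 (the walk follows an edge with probability alpha and
restarts with probability 1 - alpha).  The stationary visitation
probability of the query protein s measures how "near" s is to the
term's annotated proteins.  Three comparators rank s by raw degree
(degree-bias control, ignores t), by the count of s's neighbors
annotated to t (one-hop overlap), and by the hypergeometric upper-tail
probability of that overlap given the term size and s's degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np
from scipy import stats

from .graph_model import EdgeTypeFilter, MixedGraph
from .ontology import AnnotationSet, annotated_proteins

class WalkUniverse(str, Enum):
    FULL = "full"                        # proteins + GO nodes + annotation edges
    ANNOTATIONS_ONLY = "annotations_only"
    INTERACTIONS_ONLY = "interactions_only"


class ScoringMethod(str, Enum):
    RANDOM_WALK = "random_walk"
    DEGREE = "degree"
    ONE_HOP = "one_hop"
    HYPERGEOMETRIC = "hypergeometric"


#: methods whose scores are better when smaller
LOWER_IS_BETTER = {ScoringMethod.HYPERGEOMETRIC}


@dataclass(frozen=True)
class WalkConfig:
    alpha: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000
    universe: WalkUniverse = WalkUniverse.FULL

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


class ConvergenceError(RuntimeError):
    pass


def build_walk_graph(graph: MixedGraph, annots: AnnotationSet,
                     universe: WalkUniverse = WalkUniverse.FULL,
                     dag=None) -> nx.Graph:
    """Undirected walk substrate for the chosen universe.

    ``full`` carries protein nodes, GO-term nodes, annotation edges
    (direct and inferred) and — when a DAG is supplied — the GO
    hierarchy's term-term edges, on top of the interactions; the two
    ablation universes drop the annotation edges or the interaction
    edges.
    """
    universe = WalkUniverse(universe)
    g = nx.Graph()
    if universe in (WalkUniverse.FULL, WalkUniverse.INTERACTIONS_ONLY):
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(graph.ppi_edges())
        g.add_edges_from((a, b) for a, b in graph.reg_edges() if a != b)
    if universe in (WalkUniverse.FULL, WalkUniverse.ANNOTATIONS_ONLY):
        if universe is WalkUniverse.ANNOTATIONS_ONLY:
            g.add_nodes_from(graph.nodes)
        annotated_terms = set()
        for rec in annots.records():
            if rec.protein in graph:
                g.add_edge(rec.protein, rec.term)
                annotated_terms.add(rec.term)
        if dag is not None:
            # GO hierarchy edges among terms reachable from the annotated ones
            for child, parent, _ in dag.parent_edges():
                if child in annotated_terms or child in g:
                    g.add_edge(child, parent)
    return g


def personalized_pagerank(walk_graph: nx.Graph, restart: set[str],
                          cfg: WalkConfig = WalkConfig()) -> dict[str, float]:
    """Stationary distribution of a random walk with restart.

    Solves p = (1 - alpha) r + alpha W^T p by power iteration, where r is
    uniform over the restart set and W is the column-normalized adjacency
    of the undirected walk graph.  Mass leaving dangling (isolated) nodes
    is redistributed to the restart vector.  Stops when the L1 change
    falls below the configured tolerance; raises ConvergenceError with
    the residual otherwise.
    """
    restart_nodes = [n for n in restart if n in walk_graph]
    if not restart_nodes:
        raise ValueError("restart set is empty (no member is in the walk graph)")
    nodes = sorted(walk_graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = nx.to_scipy_sparse_array(walk_graph, nodelist=nodes, format="csr",
                                 dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    dangling = deg == 0
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=~dangling)
    # W^T p computed as A @ (p / deg) since A is symmetric
    r = np.zeros(n)
    r[[index[m] for m in restart_nodes]] = 1.0 / len(restart_nodes)
    alpha = cfg.alpha
    p = r.copy()
    for _ in range(cfg.max_iter):
        walked = a @ (p * inv_deg)
        walked += p[dangling].sum() * r
        p_next = (1.0 - alpha) * r + alpha * walked
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < cfg.tol:
            break
    else:
        raise ConvergenceError(
            f"personalized PageRank did not converge in {cfg.max_iter} "
            f"iterations (L1 residual {residual:.3e})")
    return {node: float(p[index[node]]) for node in nodes}


@dataclass
class RankingReport:
    method: ScoringMethod
    query: str
    term: str
    scores: dict[str, float]       # candidate protein -> score
    query_rank: int                # competition rank among candidates, 1 = best
    total_candidates: int


def _candidates(graph: MixedGraph, annots: AnnotationSet, s: str,
                term: str) -> list[str]:
    """Proteins not annotated (direct or inferred) to the term, plus s itself."""
    members = annotated_proteins(annots, term, include_inferred=True)
    member_keys = {m.lower() for m in members}
    out = [p for p in graph.nodes if p.lower() not in member_keys]
    if s not in out:
        out.append(s)
    return sorted(out)


def score_candidates(graph: MixedGraph, annots: AnnotationSet, term: str,
                     method: ScoringMethod, candidates: list[str],
                     cfg: WalkConfig = WalkConfig(),
                     pagerank_scores: dict[str, float] | None = None,
                     dag=None) -> dict[str, float]:
    """Score a candidate list for association with ``term`` by one method."""
    method = ScoringMethod(method)
    if method is ScoringMethod.RANDOM_WALK:
        if pagerank_scores is None:
            pagerank_scores = term_pagerank(graph, annots, term, cfg, dag=dag)
        return {c: pagerank_scores.get(c, 0.0) for c in candidates}
    if method is ScoringMethod.DEGREE:
        return {c: float(graph.degree(c, EdgeTypeFilter.MIXED)) for c in candidates}
    members = annotated_proteins(annots, term, include_inferred=True)
    member_keys = {m.lower() for m in members}
    if method is ScoringMethod.ONE_HOP:
        return {
            c: float(sum(1 for nbr in graph.neighbors(c, EdgeTypeFilter.MIXED)
                         if nbr.lower() in member_keys))
            for c in candidates}
    # hypergeometric: P[X >= x] of drawing x term-annotated neighbors when
    # deg(c) neighbors are drawn from N proteins containing K members
    n_pop = graph.number_of_nodes()
    k_succ = len(member_keys & {p.lower() for p in graph.nodes})
    out = {}
    for c in candidates:
        nbrs = graph.neighbors(c, EdgeTypeFilter.MIXED)
        x = sum(1 for nbr in nbrs if nbr.lower() in member_keys)
        out[c] = float(stats.hypergeom.sf(x - 1, n_pop, k_succ, len(nbrs)))
    return out


def term_pagerank(graph: MixedGraph, annots: AnnotationSet, term: str,
                  cfg: WalkConfig = WalkConfig(), dag=None) -> dict[str, float]:
    """Personalized PageRank restarting from the term's annotated proteins."""
    walk_graph = build_walk_graph(graph, annots, cfg.universe, dag=dag)
    restart = {p for p in annotated_proteins(annots, term, include_inferred=True)
               if p in walk_graph}
    return personalized_pagerank(walk_graph, restart, cfg)


def rank_among(scores: dict[str, float], query: str,
               method: ScoringMethod) -> int:
    """Competition rank of the query (ties share the best rank)."""
    q = scores[query]
    if ScoringMethod(method) in LOWER_IS_BETTER:
        better = sum(1 for v in scores.values() if v < q)
    else:
        better = sum(1 for v in scores.values() if v > q)
    return better + 1


def rank_query(graph: MixedGraph, annots: AnnotationSet, s: str, t: str,
               method: ScoringMethod = ScoringMethod.RANDOM_WALK,
               cfg: WalkConfig = WalkConfig(),
               pagerank_scores: dict[str, float] | None = None,
               dag=None) -> RankingReport:
    """Rank the query protein s among proteins not annotated to term t."""
    s = graph.resolve(s)
    method = ScoringMethod(method)
    candidates = _candidates(graph, annots, s, t)
    scores = score_candidates(graph, annots, t, method, candidates, cfg,
                              pagerank_scores, dag=dag)
    return RankingReport(
        method=method, query=s, term=t, scores=scores,
        query_rank=rank_among(scores, s, method),
        total_candidates=len(candidates))


def batch_rank(graph: MixedGraph, annots: AnnotationSet,
               pairs: list[tuple[str, str]],
               method: ScoringMethod = ScoringMethod.RANDOM_WALK,
               cfg: WalkConfig = WalkConfig(), dag=None) -> list[RankingReport]:
    """Rank many (protein, term) pairs; PageRank vectors are cached per term."""
    method = ScoringMethod(method)
    cache: dict[str, dict[str, float]] = {}
    reports = []
    for s, t in pairs:
        pr = None
        if method is ScoringMethod.RANDOM_WALK:
            if t not in cache:
                cache[t] = term_pagerank(graph, annots, t, cfg, dag=dag)
            pr = cache[t]
        reports.append(rank_query(graph, annots, s, t, method, cfg, pr, dag=dag))
    return reports
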