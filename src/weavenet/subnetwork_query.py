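"""Subnetwork queries connecting a protein s to proteins annotated to a GO term t.

Two modes, both parameterized by a small integer k (typical UI range
5-25):

* **k unique paths** — the k globally shortest loopless paths from s to
  *any* protein annotated to t, by edge count.  Several paths may share a
  terminal node.
* **k unique nodes** — the k annotated proteins closest to s by
  shortest-path distance, each connected back to s by one witness
  shortest path.

Regulatory edges are traversed as undirected during search; their true
direction is preserved in the returned typed edge list.  Ties (equal
length / equal distance) are broken lexicographically by node-id
sequence, which makes results reproducible and gives prefix stability:
the first k paths of a (k+1)-query equal the k-query's paths.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .graph_model import EdgeTypeFilter, MixedGraph
from .ontology import AnnotationSet, annotated_proteins

logger = logging.getLogger(__name__)


class QueryMode(str, Enum):
    K_UNIQUE_PATHS = "k_unique_paths"
    K_UNIQUE_NODES = "k_unique_nodes"


@dataclass(frozen=True)
class QuerySpec:
    source: str
    term: str
    k: int = 10
    mode: QueryMode = QueryMode.K_UNIQUE_PATHS
    filter: EdgeTypeFilter = EdgeTypeFilter.MIXED
    include_inferred: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class QuerySubnetwork:
    """Result of a query: witness paths plus the induced typed subnetwork.

    ``roles`` maps each node to source / annotated / intermediate;
    ``edges`` lists (u, v, type) with regulatory edges in true direction.
    """
    spec: QuerySpec
    paths: list[tuple[str, ...]] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    diagnostic: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.roles)

    def __len__(self) -> int:
        return len(self.paths)


def traversal_view(graph: MixedGraph, filter: EdgeTypeFilter) -> nx.Graph:
    """Undirected search view of the mixed graph under an edge-type filter.

    Regulatory edges become traversable in both directions; regulatory
    self-loops are dropped (paths are simple anyway).  All graph nodes are
    present even if isolated under the filter.
    """
    filter = EdgeTypeFilter(filter)
    view = nx.Graph()
    view.add_nodes_from(graph.nodes)
    if filter in (EdgeTypeFilter.PHYSICAL, EdgeTypeFilter.MIXED):
        view.add_edges_from(graph.ppi_edges())
    if filter in (EdgeTypeFilter.REGULATORY, EdgeTypeFilter.MIXED):
        view.add_edges_from((a, b) for a, b in graph.reg_edges() if a != b)
    return view


def _typed_edges_between(graph: MixedGraph, u: str, v: str,
                         filter: EdgeTypeFilter) -> list[tuple[str, str, str]]:
    """All filtered edges realizing the step u-v (parallel edges included)."""
    out = []
    if filter in (EdgeTypeFilter.PHYSICAL, EdgeTypeFilter.MIXED):
        if graph.has_ppi_edge(u, v):
            out.append((u, v, "physical"))
    if filter in (EdgeTypeFilter.REGULATORY, EdgeTypeFilter.MIXED):
        if graph.has_reg_edge(u, v):
            out.append((u, v, "regulatory"))
        if graph.has_reg_edge(v, u):
            out.append((v, u, "regulatory"))
    return out


def _assemble(graph: MixedGraph, spec: QuerySpec, source: str,
              targets: set[str], paths: list[tuple[str, ...]],
              diagnostic: str = "") -> QuerySubnetwork:
    roles: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    seen_edges: set[tuple[str, str, str]] = set()
    for path in paths:
        for node in path:
            if node == source:
                roles[node] = "source"
            elif node in targets and roles.get(node) != "source":
                roles[node] = "annotated"
            else:
                roles.setdefault(node, "intermediate")
        for u, v in zip(path, path[1:]):
            for edge in _typed_edges_between(graph, u, v, spec.filter):
                if edge not in seen_edges:
                    seen_edges.add(edge)
                    edges.append(edge)
    if not paths and not diagnostic:
        roles[source] = "source"
    result = QuerySubnetwork(spec=spec, paths=paths, roles=roles,
                             edges=edges, diagnostic=diagnostic)
    if paths:
        result.roles.setdefault(source, "source")
    return result


def _target_set(graph: MixedGraph, annots: AnnotationSet,
                spec: QuerySpec, source: str) -> set[str]:
    targets = {
        graph.resolve(p)
        for p in annotated_proteins(annots, spec.term, spec.include_inferred)
        if p in graph
    }
    # a source annotated to its own query term is excluded from the target
    # set: paths connect it to *other* members of the term
    targets.discard(source)
    return targets


def k_unique_paths(graph: MixedGraph, annots: AnnotationSet,
                   spec: QuerySpec, *,
                   max_expansions: int = 2_000_000) -> QuerySubnetwork:
    """The k shortest simple paths from s to any t-annotated protein.

    Best-first enumeration over partial simple paths ordered by
    (edge count, node-id sequence); pops arrive in globally sorted order,
    so the first k paths ending in the target set are exactly the k
    shortest with deterministic lexicographic tie-breaks.  If fewer than k
    simple paths exist, all are returned.  Paths may pass through
    annotated nodes as intermediates.
    """
    source = graph.resolve(spec.source)
    targets = _target_set(graph, annots, spec, source)
    if not targets:
        return _assemble(graph, spec, source, targets, [],
                         diagnostic=f"no proteins annotated to {spec.term}")
    view = traversal_view(graph, spec.filter)
    found: list[tuple[str, ...]] = []
    heap: list[tuple[int, tuple[str, ...]]] = [(0, (source,))]
    expansions = 0
    while heap and len(found) < spec.k:
        length, path = heapq.heappop(heap)
        tail = path[-1]
        if tail in targets and length > 0:
            found.append(path)
        on_path = set(path)
        for nbr in view.neighbors(tail):
            if nbr not in on_path:
                heapq.heappush(heap, (length + 1, path + (nbr,)))
                expansions += 1
                if expansions > max_expansions:
                    raise RuntimeError(
                        f"path enumeration exceeded {max_expansions} expansions; "
                        "reduce k or restrict the edge filter")
    diagnostic = "" if found else (
        f"{spec.source} cannot reach any protein annotated to {spec.term} "
        f"under the {spec.filter.value} filter")
    return _assemble(graph, spec, source, targets, found, diagnostic)


def _lex_smallest_shortest_path(view: nx.Graph, source: str, target: str,
                                dist_from_source: dict[str, int]) -> tuple[str, ...]:
    """Lexicographically smallest among all shortest source->target paths."""
    dist_to_target = nx.single_source_shortest_path_length(view, target)
    total = dist_from_source[target]
    path = [source]
    cur = source
    for step in range(1, total + 1):
        remaining = total - step
        nxt = min(
            n for n in view.neighbors(cur)
            if dist_to_target.get(n, -1) == remaining
            and dist_from_source.get(n) == step
        )
        path.append(nxt)
        cur = nxt
    return tuple(path)


def k_unique_nodes(graph: MixedGraph, annots: AnnotationSet,
                   spec: QuerySpec) -> QuerySubnetwork:
    """The k t-annotated proteins closest to s, each with one witness path.

    Breadth-first search from s ranks reachable annotated nodes by
    (distance, node id); the witness for each selected node is the
    lexicographically smallest shortest path, keeping the subnetwork
    connected to the query protein.  Paths are returned sorted by length.
    """
    source = graph.resolve(spec.source)
    targets = _target_set(graph, annots, spec, source)
    if not targets:
        return _assemble(graph, spec, source, targets, [],
                         diagnostic=f"no proteins annotated to {spec.term}")
    view = traversal_view(graph, spec.filter)
    dist = nx.single_source_shortest_path_length(view, source)
    reachable = sorted(
        ((dist[t], t) for t in targets if t in dist and dist[t] > 0))
    selected = reachable[:spec.k]
    paths = [_lex_smallest_shortest_path(view, source, t, dist)
             for _, t in selected]
    paths.sort(key=lambda p: (len(p), p))
    diagnostic = "" if paths else (
        f"{spec.source} cannot reach any protein annotated to {spec.term} "
        f"under the {spec.filter.value} filter")
    return _assemble(graph, spec, source, targets, paths, diagnostic)


def run_query(graph: MixedGraph, annots: AnnotationSet,
              spec: QuerySpec) -> QuerySubnetwork:
    if QueryMode(spec.mode) is QueryMode.K_UNIQUE_PATHS:
        return k_unique_paths(graph, annots, spec)
    return k_unique_nodes(graph, annots, spec)


def requery(result: QuerySubnetwork, new_source: str, graph: MixedGraph,
            annots: AnnotationSet) -> QuerySubnetwork:
    """Re-run the query from a node inside the current subnetwork."""
    resolved = graph.resolve(new_source)
    if resolved not in result.nodes:
        raise ValueError(f"{new_source!r} is not in the current subnetwork")
    new_spec = QuerySpec(source=resolved, term=result.spec.term,
                         k=result.spec.k, mode=result.spec.mode,
                         filter=result.spec.filter,
                         include_inferred=result.spec.include_inferred)
    return run_query(graph, annots, new_spec)
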