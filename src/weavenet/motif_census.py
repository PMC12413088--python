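"""Three-node mixed-motif census and enrichment against the background graph.

Five motif classes over the mixed graph:

* ``protein_clique`` — all three protein pairs physically interact.
* ``feed_forward_loop`` — TF X regulates TF Y, both regulate Z, and X
  and Y do *not* physically interact.
* ``mixed_feedback_loop`` — a feed-forward loop whose two TFs physically
  interact.  A purely regulatory view would misclassify this as a
  feed-forward loop, which is exactly what the mixed representation
  prevents.
* ``interacting_coregulators`` — X and Y physically interact and both
  regulate Z.
* ``coregulated_interactors`` — TF X regulates both Y and Z, which
  physically interact.

The protein-clique pattern is assessed independently of the
regulatory/mixed patterns (a triple can tally in both); among the
regulatory/mixed patterns at most one is assigned per triple, with
precedence mixed_feedback_loop > feed_forward_loop >
interacting_coregulators > coregulated_interactors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .graph_model import MixedGraph


class MotifClass(str, Enum):
    PROTEIN_CLIQUE = "protein_clique"
    FEED_FORWARD_LOOP = "feed_forward_loop"
    INTERACTING_COREGULATORS = "interacting_coregulators"
    COREGULATED_INTERACTORS = "coregulated_interactors"
    MIXED_FEEDBACK_LOOP = "mixed_feedback_loop"


#: precedence among the regulatory/mixed patterns (first match wins)
_REGULATORY_PRECEDENCE = (
    MotifClass.MIXED_FEEDBACK_LOOP,
    MotifClass.FEED_FORWARD_LOOP,
    MotifClass.INTERACTING_COREGULATORS,
    MotifClass.COREGULATED_INTERACTORS,
)


def _classify_pattern(ppi: set[frozenset[str]], reg: set[tuple[str, str]],
                      triple: tuple[str, str, str]) -> frozenset[MotifClass]:
    """Classify the induced pattern given pair-level edge presence sets."""
    a, b, c = triple
    out: set[MotifClass] = set()
    if (frozenset((a, b)) in ppi and frozenset((a, c)) in ppi
            and frozenset((b, c)) in ppi):
        out.add(MotifClass.PROTEIN_CLIQUE)

    def ffl_roles():
        # (x, y, z) with x->y, x->z, y->z; each regulatory direction of a
        # reciprocal pair is considered separately
        for x, y, z in itertools.permutations(triple):
            if (x, y) in reg and (x, z) in reg and (y, z) in reg:
                yield x, y, z

    matched: MotifClass | None = None
    for cls in _REGULATORY_PRECEDENCE:
        if cls is MotifClass.MIXED_FEEDBACK_LOOP:
            hit = any(frozenset((x, y)) in ppi for x, y, z in ffl_roles())
        elif cls is MotifClass.FEED_FORWARD_LOOP:
            hit = any(frozenset((x, y)) not in ppi for x, y, z in ffl_roles())
        elif cls is MotifClass.INTERACTING_COREGULATORS:
            hit = any(
                frozenset((x, y)) in ppi and (x, z) in reg and (y, z) in reg
                for x, y, z in itertools.permutations(triple))
        else:  # COREGULATED_INTERACTORS
            hit = any(
                (x, y) in reg and (x, z) in reg and frozenset((y, z)) in ppi
                for x, y, z in itertools.permutations(triple))
        if hit:
            matched = cls
            break
    if matched is not None:
        out.add(matched)
    return frozenset(out)


def _pair_sets(graph: MixedGraph, nodes: tuple[str, str, str]):
    ppi = {frozenset((u, v)) for u, v in itertools.combinations(nodes, 2)
           if graph.has_ppi_edge(u, v)}
    reg = {(u, v) for u, v in itertools.permutations(nodes, 2)
           if graph.has_reg_edge(u, v)}
    return ppi, reg


def classify_triple(graph: MixedGraph, a: str, b: str, c: str) -> frozenset[MotifClass]:
    """Motif classes of the induced mixed subgraph on {a, b, c}.

    Returns the empty frozenset when no pattern matches.  Class identity
    depends only on the unlabeled pattern (symmetric under relabeling).
    """
    triple = (graph.resolve(a), graph.resolve(b), graph.resolve(c))
    if len(set(triple)) != 3:
        raise ValueError("motif classification requires three distinct proteins")
    ppi, reg = _pair_sets(graph, triple)
    return _classify_pattern(ppi, reg, triple)


def census(graph: MixedGraph, nodes: set[str] | None = None) -> dict[MotifClass, int]:
    """Per-class motif counts over unordered triples of the induced subgraph.

    Every motif class requires all three pairs to be adjacent in the
    union (PPI + regulatory, undirected) view, so only union-triangles
    are classified — equivalent to full triple enumeration but pivoted
    on edges for efficiency.
    """
    if nodes is None:
        node_set = graph.nodes
    else:
        node_set = {graph.resolve(n) for n in nodes}
    # union adjacency restricted to the subset, self-loops dropped
    adj: dict[str, set[str]] = {n: set() for n in node_set}
    for u, v in graph.ppi_edges():
        if u in node_set and v in node_set:
            adj[u].add(v)
            adj[v].add(u)
    for u, v in graph.reg_edges():
        if u != v and u in node_set and v in node_set:
            adj[u].add(v)
            adj[v].add(u)
    counts = {cls: 0 for cls in MotifClass}
    order = sorted(node_set)
    rank = {n: i for i, n in enumerate(order)}
    for u in order:
        higher_u = {w for w in adj[u] if rank[w] > rank[u]}
        for v in sorted(higher_u):
            for w in sorted(higher_u & adj[v]):
                if rank[w] > rank[v]:
                    for cls in classify_triple(graph, u, v, w):
                        counts[cls] += 1
    return counts


def background_distribution(graph: MixedGraph) -> tuple[dict[MotifClass, int],
                                                        dict[MotifClass, float]]:
    """Whole-graph census plus proportions normalized over the five classes."""
    counts = census(graph)
    total = sum(counts.values())
    props = {cls: (counts[cls] / total if total else 0.0) for cls in MotifClass}
    return counts, props


@dataclass
class MotifClassStats:
    observed: int
    null_mean: float
    null_sd: float
    enrichment: float | None   # observed / null mean; None when null mean is 0
    z: float | None            # None when sd == 0 and observed != mean
    p: float                   # empirical upper tail, +1 corrected


@dataclass
class MotifReport:
    per_class: dict[MotifClass, MotifClassStats]
    background_counts: dict[MotifClass, int]
    background_proportions: dict[MotifClass, float]
    reps: int
    seed: int
    sub_node_count: int

    def rows(self) -> list[dict]:
        out = []
        for cls in MotifClass:
            s = self.per_class[cls]
            out.append({
                "class": cls.value, "observed": s.observed,
                "null_mean": s.null_mean, "null_sd": s.null_sd,
                "enrichment": s.enrichment, "z": s.z, "p": s.p,
            })
        return out


def sample_connected_subgraph(graph: MixedGraph, size: int,
                              rng: np.random.Generator,
                              max_tries: int = 200) -> set[str]:
    """Snowball-sample a connected induced node set of the union view."""
    nodes = sorted(graph.nodes)
    if size > len(nodes):
        raise ValueError("requested subgraph larger than the graph")
    for _ in range(max_tries):
        start = nodes[rng.integers(len(nodes))]
        sample = {start}
        frontier = set(graph.neighbors(start))
        while len(sample) < size and frontier:
            pick = sorted(frontier)[rng.integers(len(frontier))]
            sample.add(pick)
            frontier |= graph.neighbors(pick)
            frontier -= sample
        if len(sample) == size:
            return sample
    raise RuntimeError(
        f"could not sample a connected induced subgraph of {size} nodes "
        f"after {max_tries} attempts")


def enrichment(sub_counts: dict[MotifClass, int], graph: MixedGraph,
               sub_node_count: int, reps: int = 999,
               seed: int = 0) -> MotifReport:
    """Score a subnetwork's motif counts against a size-matched null.

    The null distribution per class is the census on ``reps`` random
    connected induced subgraphs of ``sub_node_count`` nodes snowballed
    from the background graph (queried subnetworks are connected by
    construction, so the null is connectivity-matched).  Empirical p uses
    the +1 correction; Z is undefined (None) when the null is degenerate
    and the observation deviates from it.
    """
    if sub_node_count < 3:
        raise ValueError("sub_node_count must be >= 3")
    if sub_node_count > graph.number_of_nodes():
        raise ValueError("sub_node_count exceeds the background graph size")
    rng = np.random.default_rng(seed)
    null = {cls: np.empty(reps) for cls in MotifClass}
    for i in range(reps):
        sample = sample_connected_subgraph(graph, sub_node_count, rng)
        c = census(graph, sample)
        for cls in MotifClass:
            null[cls][i] = c[cls]
    per_class: dict[MotifClass, MotifClassStats] = {}
    for cls in MotifClass:
        obs = int(sub_counts.get(cls, 0))
        mean = float(null[cls].mean())
        sd = float(null[cls].std(ddof=1)) if reps > 1 else 0.0
        if sd > 0:
            z = (obs - mean) / sd
        elif math.isclose(obs, mean):
            z = 0.0
        else:
            z = None
        ratio = (obs / mean) if mean > 0 else None
        p = (1 + int((null[cls] >= obs).sum())) / (reps + 1)
        per_class[cls] = MotifClassStats(obs, mean, sd, ratio, z, p)
    bg_counts, bg_props = background_distribution(graph)
    return MotifReport(per_class, bg_counts, bg_props, reps, seed, sub_node_count)
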