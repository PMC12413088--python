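"""Independent reference implementations used only to check the package.

Everything here is deliberately written the dumb way — exhaustive
enumeration, dense linear algebra, recursive closures — and must stay
independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- path queries -----------------------------------------------------------

def all_simple_paths_to_targets(adj: dict[str, set[str]], source: str,
                                targets: set[str]) -> list[tuple[str, ...]]:
    """Every simple path from source to any target, by recursive DFS."""
    out: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        tail = path[-1]
        if tail in targets and len(path) > 1:
            out.append(tuple(path))
        for nxt in sorted(adj.get(tail, ())):
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([source])
    out.sort(key=lambda p: (len(p), p))
    return out


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for nbr in adj.get(node, ()):
                if nbr not in dist:
                    dist[nbr] = d
                    nxt.append(nbr)
        frontier = nxt
    return dist


# -- motif classification ---------------------------------------------------

def motif_rule_table(ppi_ab: bool, ppi_ac: bool, ppi_bc: bool,
                     reg: set[tuple[str, str]]) -> set[str]:
    """Classify the labeled triple (A, B, C) from raw edge booleans.

    Independent formulation: checks each unlabeled pattern by explicitly
    trying all 6 role assignments against the edge configuration.
    """
    ppi = set()
    if ppi_ab:
        ppi.add(("A", "B"))
    if ppi_ac:
        ppi.add(("A", "C"))
    if ppi_bc:
        ppi.add(("B", "C"))

    def has_ppi(x, y):
        return (x, y) in ppi or (y, x) in ppi

    classes: set[str] = set()
    if ppi_ab and ppi_ac and ppi_bc:
        classes.add("protein_clique")

    perms = list(itertools.permutations("ABC"))
    mfl = any((x, y) in reg and (x, z) in reg and (y, z) in reg and has_ppi(x, y)
              for x, y, z in perms)
    ffl = any((x, y) in reg and (x, z) in reg and (y, z) in reg and not has_ppi(x, y)
              for x, y, z in perms)
    ic = any(has_ppi(x, y) and (x, z) in reg and (y, z) in reg
             for x, y, z in perms)
    ci = any((x, y) in reg and (x, z) in reg and has_ppi(y, z)
             for x, y, z in perms)
    if mfl:
        classes.add("mixed_feedback_loop")
    elif ffl:
        classes.add("feed_forward_loop")
    elif ic:
        classes.add("interacting_coregulators")
    elif ci:
        classes.add("coregulated_interactors")
    return classes


def brute_force_census(nodes: list[str], ppi: set[frozenset[str]],
                       reg: set[tuple[str, str]]) -> dict[str, int]:
    """O(n^3) census by classifying every unordered triple."""
    counts = {c: 0 for c in ("protein_clique", "feed_forward_loop",
                             "interacting_coregulators",
                             "coregulated_interactors", "mixed_feedback_loop")}
    for a, b, c in itertools.combinations(sorted(nodes), 3):
        relabel = {a: "A", b: "B", c: "C"}
        local_reg = {(relabel[u], relabel[v]) for u, v in reg
                     if u in relabel and v in relabel and u != v}
        classes = motif_rule_table(
            frozenset((a, b)) in ppi, frozenset((a, c)) in ppi,
            frozenset((b, c)) in ppi, local_reg)
        for cls in classes:
            counts[cls] += 1
    return counts


# -- pagerank ---------------------------------------------------------------

def dense_pagerank(adj_matrix: np.ndarray, restart_vec: np.ndarray,
                   alpha: float) -> np.ndarray:
    """Direct solve of (I - alpha W) p = (1 - alpha) r with dangling -> r."""
    deg = adj_matrix.sum(axis=0)
    w = np.zeros_like(adj_matrix, dtype=float)
    for j in range(adj_matrix.shape[1]):
        if deg[j] > 0:
            w[:, j] = adj_matrix[:, j] / deg[j]
        else:
            w[:, j] = restart_vec
    n = adj_matrix.shape[0]
    return np.linalg.solve(np.eye(n) - alpha * w, (1 - alpha) * restart_vec)


# -- ontology ---------------------------------------------------------------

def recursive_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    out: set[str] = set()
    for p in parents.get(term, ()):
        if p not in out:
            out.add(p)
            out |= recursive_ancestors(parents, p)
    return out


# -- evaluation -------------------------------------------------------------

def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the normalized U statistic with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def hypergeom_upper_tail(x: int, n_pop: int, k_succ: int, draws: int) -> float:
    """P[X >= x] by explicit factorial summation."""
    from math import comb
    total = comb(n_pop, draws)
    acc = 0
    for i in range(x, min(k_succ, draws) + 1):
        acc += comb(k_succ, i) * comb(n_pop - k_succ, draws - i)
    return acc / total
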