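"""Synthetic ontologies, mixed graphs, and annotation sets with known ground truth.

The generator emulates the structure that makes guilt-by-association
work in real interactomes: each planted GO "module" is a set of proteins
whose pairwise physical-interaction probability is boosted over the
background, with a transcription factor wired to a few members to
exercise mixed queries.  Annotation completeness < 1 hides a fraction of
true members from the annotation set — those hidden members are the
learnable targets for the ranking benchmark.

Defaults reflect a dense, yeast-like interactome scaled to desk size:
600 proteins at background edge probability 0.05 (mean physical degree
~30), 20 disjoint modules of 25 members with a 3x within-module density
boost, 10% of proteins designated TFs with ~1 random regulatory edge per
protein, and 80% annotation completeness.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .graph_model import MixedGraph
from .motif_census import MotifClass
from .ontology import (
    DIRECT,
    AnnotationSet,
    OntologyDag,
    Term,
    propagate_annotations,
)


@dataclass(frozen=True)
class FixtureSpec:
    protein_count: int = 600
    ppi_edge_p: float = 0.05
    reg_edge_count: int = 600
    tf_fraction: float = 0.10
    ontology_depth: int = 2
    ontology_branching: int = 7
    cross_link_p: float = 0.0
    module_terms: int = 20
    members_per_term: int = 25
    density_boost: float = 3.0
    planted_reg_per_module: int = 3
    annotation_completeness: float = 0.8
    companion_terms_per_module: int = 1
    seed: int = 0

    def __post_init__(self):
        for p in (self.ppi_edge_p, self.tf_fraction, self.cross_link_p,
                  self.annotation_completeness):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.protein_count <= 0 or self.members_per_term <= 0:
            raise ValueError("counts must be positive")
        if self.module_terms * self.members_per_term > self.protein_count:
            raise ValueError("disjoint modules cannot exceed the protein count")


@dataclass
class GroundTruth:
    members: dict[str, list[str]]        # term -> true member proteins
    hidden: dict[str, list[str]]         # term -> members left unannotated
    tfs: list[str]
    n_ppi_edges: int
    n_reg_edges: int
    module_term_ids: list[str]
    companion_terms: dict[str, list[str]] = field(default_factory=dict)


SYNTHETIC_ROOT = "GO:0008150"  # synthetic namespace root, biological_process


def make_ontology(depth: int = 2, branching: int = 5, cross_link_p: float = 0.0,
                  seed: int = 0, namespace: str = "biological_process",
                  n_obsolete: int = 0) -> OntologyDag:
    """A rooted synthetic GO-like tree with optional second parents.

    Term count for a pure tree is 1 + branching + ... + branching^depth.
    Cross-links give a term a second is_a parent drawn from the level
    above, making the DAG a genuine non-tree when cross_link_p > 0.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    dag = OntologyDag()
    dag.add_term(Term(SYNTHETIC_ROOT, "synthetic root", namespace))
    levels: list[list[str]] = [[SYNTHETIC_ROOT]]
    counter = itertools.count(1)
    for d in range(1, depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                tid = f"GO:{7000000 + next(counter):07d}"
                dag.add_term(Term(tid, f"synthetic term {tid}", namespace))
                dag.add_parent(tid, parent, "is_a")
                level.append(tid)
        levels.append(level)
    if cross_link_p > 0:
        for d in range(2, depth + 1):
            for tid in levels[d]:
                if rng.random() < cross_link_p:
                    extra = levels[d - 1][rng.integers(len(levels[d - 1]))]
                    if extra not in dag.parents(tid):
                        dag.add_parent(tid, extra, "is_a")
    for i in range(n_obsolete):
        tid = f"GO:{7900000 + i:07d}"
        dag.add_term(Term(tid, f"obsolete term {tid}", namespace, obsolete=True))
    dag.validate()
    return dag


def _leaf_terms(dag: OntologyDag) -> list[str]:
    children: set[str] = set()
    parents: set[str] = set()
    for c, p, _ in dag.parent_edges():
        children.add(c)
        parents.add(p)
    return sorted(t for t in dag.terms
                  if t in children and t not in parents
                  and not dag.terms[t].obsolete)


def make_mixed_graph(spec: FixtureSpec = FixtureSpec()
                     ) -> tuple[MixedGraph, OntologyDag, AnnotationSet, GroundTruth]:
    """Generate graph + ontology + direct annotations + ground truth.

    Deterministic in the spec (including seed).  Module members are
    annotated to distinct leaf terms of the synthetic ontology; a
    ``completeness`` fraction of members get annotation records, the
    rest are recorded as hidden ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.protein_count))
    proteins = [f"P{i:0{width}d}" for i in range(spec.protein_count)]
    graph = MixedGraph(species="synthetic")
    for p in proteins:
        graph.add_protein(p)

    dag = make_ontology(spec.ontology_depth, spec.ontology_branching,
                        spec.cross_link_p, seed=spec.seed + 1)
    leaves = _leaf_terms(dag)
    needed = spec.module_terms * (1 + spec.companion_terms_per_module)
    if needed > len(leaves):
        raise ValueError(
            f"ontology has {len(leaves)} leaf terms but {needed} are needed "
            "for module + companion terms; increase depth/branching")
    module_ids = leaves[:spec.module_terms]
    # companion terms: each module's proteins share additional annotations
    # beyond the module term itself, emulating the correlated multi-term
    # annotation profiles of real proteins (members of one process also
    # share related annotations) that the walk's annotation edges exploit
    companions: dict[str, list[str]] = {}
    cursor = spec.module_terms
    for term in module_ids:
        companions[term] = leaves[cursor:cursor + spec.companion_terms_per_module]
        cursor += spec.companion_terms_per_module

    # disjoint module membership over a shuffled protein list
    shuffled = list(proteins)
    rng.shuffle(shuffled)
    members: dict[str, list[str]] = {}
    cursor = 0
    for term in module_ids:
        members[term] = sorted(shuffled[cursor:cursor + spec.members_per_term])
        cursor += spec.members_per_term

    # PPI edges: Bernoulli per pair, boosted within modules (vectorized
    # over the upper-triangular pair ordering)
    n = spec.protein_count
    p_in = min(1.0, spec.density_boost * spec.ppi_edge_p)
    index = {p: i for i, p in enumerate(proteins)}

    def pair_pos(ia: int, ib: int) -> int:
        # linear position of pair (ia < ib) in np.triu_indices(n, 1) order
        return ia * n - ia * (ia + 1) // 2 + (ib - ia - 1)

    prob = np.full(n * (n - 1) // 2, spec.ppi_edge_p)
    for term_members in members.values():
        for a, b in itertools.combinations(term_members, 2):
            ia, ib = sorted((index[a], index[b]))
            prob[pair_pos(ia, ib)] = p_in
    idx_a, idx_b = np.triu_indices(n, k=1)
    hit = rng.random(prob.size) < prob
    for ia, ib in zip(idx_a[hit], idx_b[hit]):
        graph.add_ppi_edge(proteins[ia], proteins[ib], ["synthetic"])

    # regulatory edges: random TF -> target, plus planted TF -> member edges
    n_tf = max(1, int(round(spec.tf_fraction * spec.protein_count)))
    tfs = sorted(proteins[i] for i in rng.choice(spec.protein_count,
                                                 size=n_tf, replace=False))
    for _ in range(spec.reg_edge_count):
        tf = tfs[rng.integers(len(tfs))]
        target = proteins[rng.integers(spec.protein_count)]
        if target != tf:
            graph.add_reg_edge(tf, target, ["synthetic"])
    for term in module_ids:
        tf = tfs[rng.integers(len(tfs))]
        pick = rng.choice(len(members[term]),
                          size=min(spec.planted_reg_per_module, len(members[term])),
                          replace=False)
        for j in pick:
            target = members[term][j]
            if target != tf:
                graph.add_reg_edge(tf, target, ["planted"])

    # annotations: completeness fraction of members annotated directly to
    # the module term, and independently to each companion term
    annots = AnnotationSet()
    hidden: dict[str, list[str]] = {}
    for term in module_ids:
        hid = []
        for protein in members[term]:
            if rng.random() < spec.annotation_completeness:
                annots.add(protein, term, DIRECT, ["IEA"])
            else:
                hid.append(protein)
            for companion in companions[term]:
                if rng.random() < spec.annotation_completeness:
                    annots.add(protein, companion, DIRECT, ["IEA"])
        hidden[term] = hid

    truth = GroundTruth(members=members, hidden=hidden, tfs=tfs,
                        n_ppi_edges=graph.number_of_ppi_edges(),
                        n_reg_edges=graph.number_of_reg_edges(),
                        module_term_ids=module_ids,
                        companion_terms=companions)
    return graph, dag, annots, truth


# ---------------------------------------------------------------------------
# Motif planting

_MOTIF_EDGES: dict[MotifClass, tuple[list[tuple[int, int]], list[tuple[int, int]]]] = {
    # (ppi pairs, regulatory ordered pairs) over node roles 0, 1, 2
    MotifClass.PROTEIN_CLIQUE: ([(0, 1), (0, 2), (1, 2)], []),
    MotifClass.FEED_FORWARD_LOOP: ([], [(0, 1), (0, 2), (1, 2)]),
    MotifClass.MIXED_FEEDBACK_LOOP: ([(0, 1)], [(0, 1), (0, 2), (1, 2)]),
    MotifClass.INTERACTING_COREGULATORS: ([(0, 1)], [(0, 2), (1, 2)]),
    MotifClass.COREGULATED_INTERACTORS: ([(1, 2)], [(0, 1), (0, 2)]),
}


def plant_motifs(graph: MixedGraph, motif_class: MotifClass, count: int,
                 seed: int = 0) -> list[tuple[str, str, str]]:
    """Add ``count`` disjoint instances of a motif class on free triples.

    Instances are planted on mutually non-adjacent nodes (no existing
    edges among or between chosen triples), so a subsequent census finds
    exactly the planted instances on those nodes.  Raises when too few
    free nodes remain.
    """
    motif_class = MotifClass(motif_class)
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    free = []
    for n in sorted(graph.nodes):
        if not graph.neighbors(n):
            free.append(n)
    rng.shuffle(free)
    if len(free) < 3 * count:
        raise ValueError(
            f"need {3 * count} isolated nodes to plant {count} motifs, "
            f"found {len(free)}")
    locations = []
    ppi_pairs, reg_pairs = _MOTIF_EDGES[motif_class]
    for i in range(count):
        triple = tuple(sorted(free[3 * i:3 * i + 3]))
        for a, b in ppi_pairs:
            graph.add_ppi_edge(triple[a], triple[b], ["planted"])
        for a, b in reg_pairs:
            graph.add_reg_edge(triple[a], triple[b], ["planted"])
        locations.append(triple)
        used.update(triple)
    return locations


# ---------------------------------------------------------------------------
# Serialization


def write_fixture(out_dir: str, graph: MixedGraph, dag: OntologyDag,
                  annots: AnnotationSet, truth: GroundTruth | None = None,
                  spec: FixtureSpec | None = None) -> None:
    """Emit ppi.tsv, reg.tsv, ontology.obo, annotations.gaf and truth.json."""
    from .graph_model import write_edges
    from .ontology import write_gaf, write_obo

    os.makedirs(out_dir, exist_ok=True)
    write_edges(graph, os.path.join(out_dir, "ppi.tsv"),
                os.path.join(out_dir, "reg.tsv"))
    write_obo(dag, os.path.join(out_dir, "ontology.obo"))
    write_gaf(annots, os.path.join(out_dir, "annotations.gaf"))
    doc: dict = {}
    if truth is not None:
        doc["truth"] = asdict(truth)
    if spec is not None:
        doc["spec"] = asdict(spec)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(doc, fh, indent=2)
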