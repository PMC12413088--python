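"""Reloadable graph bundles: a directory of canonical TSV/OBO/GAF parts.

A bundle is the on-disk unit the CLI passes between steps: ppi.tsv,
reg.tsv, ontology.obo, annotations.gaf plus a meta.json with counts.
Loading re-parses the canonical parts and re-propagates annotations, so
a bundle is always self-consistent.
"""

from __future__ import annotations

import json
import os

from .graph_model import MixedGraph, load_edges, write_edges
from .ontology import (
    AnnotationSet,
    OntologyDag,
    parse_gaf,
    parse_obo,
    propagate_annotations,
    write_gaf,
    write_obo,
)

PARTS = ("ppi.tsv", "reg.tsv", "ontology.obo", "annotations.gaf", "meta.json")


def save_bundle(out_dir: str, graph: MixedGraph, dag: OntologyDag,
                annots: AnnotationSet) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    write_edges(graph, os.path.join(out_dir, "ppi.tsv"),
                os.path.join(out_dir, "reg.tsv"))
    write_obo(dag, os.path.join(out_dir, "ontology.obo"))
    write_gaf(annots, os.path.join(out_dir, "annotations.gaf"))
    meta = {
        "species": graph.species,
        "nodes": graph.number_of_nodes(),
        "ppi_edges": graph.number_of_ppi_edges(),
        "reg_edges": graph.number_of_reg_edges(),
        "terms": len(dag),
        "direct_annotations": len(list(annots.records("direct"))),
    }
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta


def load_bundle(bundle_dir: str) -> tuple[MixedGraph, OntologyDag, AnnotationSet]:
    """Load a bundle; returns the graph, DAG and *propagated* annotations."""
    for part in ("ppi.tsv", "reg.tsv", "ontology.obo", "annotations.gaf"):
        if not os.path.exists(os.path.join(bundle_dir, part)):
            raise FileNotFoundError(f"bundle {bundle_dir} is missing {part}")
    meta_path = os.path.join(bundle_dir, "meta.json")
    species = ""
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            species = json.load(fh).get("species", "")
    graph = load_edges(os.path.join(bundle_dir, "ppi.tsv"),
                       os.path.join(bundle_dir, "reg.tsv"), species=species)
    dag = parse_obo(os.path.join(bundle_dir, "ontology.obo"))
    annots = parse_gaf(os.path.join(bundle_dir, "annotations.gaf"), dag)
    annots = propagate_annotations(annots, dag)
    return graph, dag, annots
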