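"""The mixed interaction graph: undirected PPI edges plus directed regulatory edges.

A single node set (proteins) carries two parallel edge sets.  A protein
pair may simultaneously have a physical edge and regulatory edge(s);
these are distinct edges and are never merged — the distinction is what
makes mixed-motif classification possible.  Evidence strings (PubMed /
STRING refs) are opaque pass-through metadata.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd


class EdgeTypeFilter(str, Enum):
    PHYSICAL = "physical"
    REGULATORY = "regulatory"
    MIXED = "mixed"


class GraphFormatError(ValueError):
    """Raised when an edge-list file is missing a required column."""


class MixedGraph:
    """Proteins with undirected physical and directed regulatory edges.

    Protein ids are matched case-insensitively and stored in first-seen
    form.  PPI edges are deduplicated regardless of input order and carry
    no self-loops; regulatory edges are directed, so (a,b) and (b,a) are
    distinct, and self-loops (autoregulation) are retained in the edge set
    but ignored by path queries and the motif census.
    """

    def __init__(self, species: str = "") -> None:
        self.species = species
        self._ppi = nx.Graph()
        self._reg = nx.DiGraph()
        self._display: dict[str, str] = {}

    # -- node/edge construction ---------------------------------------

    def _canon(self, protein: str) -> str:
        key = protein.lower()
        display = self._display.setdefault(key, protein)
        return display

    def add_protein(self, protein: str) -> str:
        p = self._canon(protein)
        self._ppi.add_node(p)
        self._reg.add_node(p)
        return p

    def add_ppi_edge(self, a: str, b: str, evidence: Iterable[str] = ()) -> None:
        a, b = self.add_protein(a), self.add_protein(b)
        if a == b:
            return  # physical self-loops are meaningless
        ev = set(evidence)
        if self._ppi.has_edge(a, b):
            ev |= self._ppi.edges[a, b]["evidence"]
        self._ppi.add_edge(a, b, evidence=ev)

    def add_reg_edge(self, regulator: str, target: str,
                     evidence: Iterable[str] = ()) -> None:
        a, b = self.add_protein(regulator), self.add_protein(target)
        ev = set(evidence)
        if self._reg.has_edge(a, b):
            ev |= self._reg.edges[a, b]["evidence"]
        self._reg.add_edge(a, b, evidence=ev)

    # -- accessors -----------------------------------------------------

    def __contains__(self, protein: str) -> bool:
        return protein.lower() in self._display

    def resolve(self, protein: str) -> str:
        key = protein.lower()
        if key not in self._display:
            raise KeyError(f"unknown protein {protein!r}")
        return self._display[key]

    @property
    def nodes(self) -> set[str]:
        return set(self._ppi.nodes)

    def number_of_nodes(self) -> int:
        return self._ppi.number_of_nodes()

    def ppi_edges(self) -> Iterator[tuple[str, str]]:
        yield from self._ppi.edges

    def reg_edges(self) -> Iterator[tuple[str, str]]:
        yield from self._reg.edges

    def number_of_ppi_edges(self) -> int:
        return self._ppi.number_of_edges()

    def number_of_reg_edges(self) -> int:
        return self._reg.number_of_edges()

    def has_ppi_edge(self, a: str, b: str) -> bool:
        try:
            return self._ppi.has_edge(self.resolve(a), self.resolve(b))
        except KeyError:
            return False

    def has_reg_edge(self, a: str, b: str) -> bool:
        try:
            return self._reg.has_edge(self.resolve(a), self.resolve(b))
        except KeyError:
            return False

    def edge_evidence(self, a: str, b: str, edge_type: str) -> set[str]:
        a, b = self.resolve(a), self.resolve(b)
        g = self._ppi if edge_type == "physical" else self._reg
        return set(g.edges[a, b]["evidence"])

    def degree(self, protein: str, filter: EdgeTypeFilter = EdgeTypeFilter.MIXED) -> int:
        """Incident edge count under the filter.

        physical = PPI incidences; regulatory = in-degree + out-degree (a
        reciprocal pair (a,b)+(b,a) contributes 2); mixed = sum of both.
        """
        p = self.resolve(protein)
        filter = EdgeTypeFilter(filter)
        d = 0
        if filter in (EdgeTypeFilter.PHYSICAL, EdgeTypeFilter.MIXED):
            d += self._ppi.degree(p)
        if filter in (EdgeTypeFilter.REGULATORY, EdgeTypeFilter.MIXED):
            d += self._reg.in_degree(p) + self._reg.out_degree(p)
        return d

    def neighbors(self, protein: str,
                  filter: EdgeTypeFilter = EdgeTypeFilter.MIXED) -> set[str]:
        """Union of PPI partners and/or regulatory partners (both directions)."""
        p = self.resolve(protein)
        filter = EdgeTypeFilter(filter)
        out: set[str] = set()
        if filter in (EdgeTypeFilter.PHYSICAL, EdgeTypeFilter.MIXED):
            out |= set(self._ppi.neighbors(p))
        if filter in (EdgeTypeFilter.REGULATORY, EdgeTypeFilter.MIXED):
            out |= set(self._reg.successors(p)) | set(self._reg.predecessors(p))
        out.discard(p)
        return out


# ---------------------------------------------------------------------------
# TSV loading


def _read_edge_tsv(path: str, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source", "target"):
        if col not in df.columns:
            raise GraphFormatError(f"{kind} edge list {path} missing column {col!r}")
    return df


def load_edges(ppi_path: str | None, reg_path: str | None,
               species: str = "") -> MixedGraph:
    """Load PPI and regulatory TSV edge lists (columns source, target[, evidence])."""
    graph = MixedGraph(species=species)
    if ppi_path is not None:
        df = _read_edge_tsv(ppi_path, "PPI")
        has_ev = "evidence" in df.columns
        for row in df.itertuples(index=False):
            ev = [row.evidence] if has_ev and row.evidence else []
            graph.add_ppi_edge(row.source, row.target, ev)
    if reg_path is not None:
        df = _read_edge_tsv(reg_path, "regulatory")
        has_ev = "evidence" in df.columns
        for row in df.itertuples(index=False):
            ev = [row.evidence] if has_ev and row.evidence else []
            graph.add_reg_edge(row.source, row.target, ev)
    return graph


def write_edges(graph: MixedGraph, ppi_path: str, reg_path: str) -> None:
    rows = [{"source": a, "target": b,
             "evidence": "|".join(sorted(graph.edge_evidence(a, b, "physical")))}
            for a, b in sorted(map(lambda e: tuple(sorted(e)), graph.ppi_edges()))]
    pd.DataFrame(rows, columns=["source", "target", "evidence"]).to_csv(
        ppi_path, sep="\t", index=False)
    rows = [{"source": a, "target": b,
             "evidence": "|".join(sorted(graph.edge_evidence(a, b, "regulatory")))}
            for a, b in sorted(graph.reg_edges())]
    pd.DataFrame(rows, columns=["source", "target", "evidence"]).to_csv(
        reg_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Subnetwork export

EXPORT_FORMATS = ("json", "graphml", "cytoscape-json")


def _result_digraph(result) -> nx.DiGraph:
    """Typed-edge DiGraph view of a QuerySubnetwork for serialization.

    Physical edges are stored once in sorted-endpoint order with
    ``directed=False``; regulatory edges keep their true direction.
    """
    g = nx.DiGraph()
    for node, role in sorted(result.roles.items()):
        g.add_node(node, role=role)
    for u, v, etype in result.edges:
        if etype == "physical":
            a, b = sorted((u, v))
            g.add_edge(a, b, type="physical", directed=False)
        else:
            g.add_edge(u, v, type="regulatory", directed=True)
    return g


def export_subnetwork(result, format: str = "json") -> str:
    """Serialize a query result to JSON, GraphML or Cytoscape JSON text."""
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}")
    g = _result_digraph(result)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(g, named_key_ids=True))
    if format == "cytoscape-json":
        return json.dumps(nx.cytoscape_data(g), indent=2)
    doc = {
        "nodes": [{"id": n, "role": d["role"]} for n, d in g.nodes(data=True)],
        "edges": [{"source": u, "target": v, "type": d["type"],
                   "directed": d["directed"]} for u, v, d in g.edges(data=True)],
        "paths": [list(p) for p in result.paths],
    }
    return json.dumps(doc, indent=2)


def import_subnetwork(text: str, format: str = "json"):
    """Parse an exported subnetwork back to (roles, typed edge set) for round-trips."""
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}")
    if format == "graphml":
        g = nx.parse_graphml(text)
        roles = {n: d["role"] for n, d in g.nodes(data=True)}
        edges = {(u, v, d["type"]) for u, v, d in g.edges(data=True)}
        return roles, edges
    if format == "cytoscape-json":
        g = nx.cytoscape_graph(json.loads(text))
        roles = {n: d["role"] for n, d in g.nodes(data=True)}
        edges = {(u, v, d["type"]) for u, v, d in g.edges(data=True)}
        return roles, edges
    doc = json.loads(text)
    roles = {n["id"]: n["role"] for n in doc["nodes"]}
    edges = {(e["source"], e["target"], e["type"]) for e in doc["edges"]}
    return roles, edges
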