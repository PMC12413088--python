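"""Gene Ontology handling: OBO parsing, GAF annotations, true-path propagation.

The ontology is a rooted DAG of GO terms connected by ``is_a`` (and
optionally ``part_of``) child->parent relations.  A protein directly
annotated to a term is, by the true-path rule, implicitly annotated to
every ancestor of that term; :func:`propagate_annotations` materializes
those implicit records as *inferred* annotations so that downstream
queries ("which proteins belong to term t?") can treat the two uniformly.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relation types traversed when computing ancestors / propagating annotations.
DEFAULT_RELATIONS = ("is_a", "part_of")

#: The three canonical GO namespace roots (biological_process,
#: molecular_function, cellular_component).  These, plus any term without
#: parents, are excluded from inferred annotations: every protein would
#: otherwise be annotated to them, which destroys ranking specificity.
NAMESPACE_ROOTS = frozenset({"GO:0008150", "GO:0003674", "GO:0005575"})


class OboFormatError(ValueError):
    """Raised for malformed OBO input; message names the offending line."""


class OntologyValidationError(ValueError):
    """Raised when the parsed ontology violates a structural invariant."""


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False


class OntologyDag:
    """A GO term DAG with child->parent edges labeled by relation type."""

    def __init__(self) -> None:
        self.terms: dict[str, Term] = {}
        # child -> {(parent, relation), ...}
        self._parents: dict[str, set[tuple[str, str]]] = {}

    # -- construction -------------------------------------------------

    def add_term(self, term: Term) -> None:
        self.terms[term.id] = term
        self._parents.setdefault(term.id, set())

    def add_parent(self, child: str, parent: str, relation: str = "is_a") -> None:
        if child not in self.terms or parent not in self.terms:
            raise KeyError(f"unknown term in parent edge {child} -> {parent}")
        self._parents[child].add((parent, relation))

    # -- queries ------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parent_edges(self) -> Iterator[tuple[str, str, str]]:
        for child, pairs in self._parents.items():
            for parent, relation in pairs:
                yield child, parent, relation

    def parents(self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        rels = set(relations)
        return {p for p, r in self._parents.get(term_id, ()) if r in rels}

    def ancestors(self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """All ancestors of ``term_id`` (excluding itself) via the given relations."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id}")
        rels = tuple(relations)
        seen: set[str] = set()
        frontier = deque(self.parents(term_id, rels))
        while frontier:
            t = frontier.popleft()
            if t in seen:
                continue
            seen.add(t)
            frontier.extend(self.parents(t, rels))
        return seen

    def roots(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """Non-obsolete terms with no parent via the traversed relations."""
        return {
            t for t, term in self.terms.items()
            if not term.obsolete and not self.parents(t, relations)
        }

    def excluded_roots(self) -> set[str]:
        """Terms excluded from inferred annotations: DAG roots plus the GO namespace roots."""
        return self.roots() | (NAMESPACE_ROOTS & set(self.terms))

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.parent_edges())
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(f"cyclic parent relations: {cycle}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDag):
            return NotImplemented
        return self.terms == other.terms and self._parents == other._parents


# ---------------------------------------------------------------------------
# OBO I/O


def _prevalidate_obo(path: str) -> None:
    """Cheap line-level syntax scan so format errors can name the line."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                continue
            if ":" in line:
                continue
            raise OboFormatError(f"malformed OBO stanza at line {lineno}: {raw.rstrip()!r}")


def parse_obo(path: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> OntologyDag:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDag`.

    Obsolete terms are retained but flagged; their parent edges are not
    traversed.  Raises :class:`OboFormatError` on malformed stanzas and
    :class:`OntologyValidationError` on cyclic ``is_a`` relations.
    """
    _prevalidate_obo(path)
    graph = obonet.read_obo(path, ignore_obsolete=False)
    dag = OntologyDag()
    for node, data in graph.nodes(data=True):
        dag.add_term(Term(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        ))
    wanted = set(relations)
    for child, parent, key in graph.edges(keys=True):
        if key in wanted and not dag.terms[child].obsolete:
            dag.add_parent(child, parent, key)
    dag.validate()
    return dag


def write_obo(dag: OntologyDag, path: str) -> None:
    """Serialize a DAG back to OBO (round-trips through :func:`parse_obo`)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: weavenet-synthetic\n")
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            if term.namespace:
                fh.write(f"namespace: {term.namespace}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
            for parent, relation in sorted(dag._parents[tid]):
                if relation == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {relation} {parent}\n")


# ---------------------------------------------------------------------------
# Annotations

DIRECT = "direct"
INFERRED = "inferred"


@dataclass
class AnnotationRecord:
    protein: str          # display form (first seen)
    term: str
    provenance: str       # DIRECT or INFERRED
    evidence: frozenset[str] = frozenset()


@dataclass
class IngestStats:
    kept: int = 0
    dropped_not_qualifier: int = 0
    dropped_obsolete: int = 0
    dropped_unknown_term: int = 0


class AnnotationSet:
    """Protein -> GO term associations, each flagged direct or inferred.

    Protein identifiers are matched case-insensitively and stored in their
    first-seen form (species mix gene symbols and locus ids).
    """

    def __init__(self) -> None:
        # (protein_key, term) -> AnnotationRecord, per provenance
        self._records: dict[str, dict[tuple[str, str], AnnotationRecord]] = {
            DIRECT: {}, INFERRED: {},
        }
        self._display: dict[str, str] = {}
        self.ingest_stats = IngestStats()

    @staticmethod
    def _key(protein: str) -> str:
        return protein.lower()

    def display_name(self, protein: str) -> str:
        return self._display.get(self._key(protein), protein)

    def add(self, protein: str, term: str, provenance: str = DIRECT,
            evidence: Iterable[str] = ()) -> None:
        if provenance not in (DIRECT, INFERRED):
            raise ValueError(f"bad provenance {provenance!r}")
        key = self._key(protein)
        display = self._display.setdefault(key, protein)
        table = self._records[provenance]
        prev = table.get((key, term))
        ev = frozenset(evidence)
        if prev is not None:
            ev = prev.evidence | ev
        table[(key, term)] = AnnotationRecord(display, term, provenance, ev)

    def discard(self, protein: str, term: str, provenance: str) -> None:
        self._records[provenance].pop((self._key(protein), term), None)

    def has(self, protein: str, term: str, provenance: str | None = None) -> bool:
        key = (self._key(protein), term)
        if provenance is not None:
            return key in self._records[provenance]
        return key in self._records[DIRECT] or key in self._records[INFERRED]

    def records(self, provenance: str | None = None) -> Iterator[AnnotationRecord]:
        if provenance is None:
            yield from self._records[DIRECT].values()
            yield from self._records[INFERRED].values()
        else:
            yield from self._records[provenance].values()

    def direct_pairs(self) -> list[tuple[str, str]]:
        return [(r.protein, r.term) for r in self._records[DIRECT].values()]

    def terms_for_protein(self, protein: str, include_inferred: bool = True) -> set[str]:
        key = self._key(protein)
        out = {t for (p, t) in self._records[DIRECT] if p == key}
        if include_inferred:
            out |= {t for (p, t) in self._records[INFERRED] if p == key}
        return out

    def __len__(self) -> int:
        return len(self._records[DIRECT]) + len(self._records[INFERRED])

    def copy(self) -> "AnnotationSet":
        new = AnnotationSet()
        for prov in (DIRECT, INFERRED):
            new._records[prov] = dict(self._records[prov])
        new._display = dict(self._display)
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._records == other._records


def annotated_proteins(annots: AnnotationSet, term: str,
                       include_inferred: bool = True) -> set[str]:
    """Proteins annotated to ``term`` (display forms); optionally direct-only.

    Unknown terms yield an empty set with a logged warning rather than an
    error, since users routinely probe terms outside the annotation corpus.
    """
    provs = (DIRECT, INFERRED) if include_inferred else (DIRECT,)
    out = {
        r.protein
        for prov in provs
        for r in annots._records[prov].values()
        if r.term == term
    }
    if not out and not any(r.term == term for r in annots.records()):
        logger.warning("term %s has no annotation records", term)
    return out


# ---------------------------------------------------------------------------
# GAF / TSV readers

_GAF_COLUMNS = 17


def parse_gaf(path: str, dag: OntologyDag) -> AnnotationSet:
    """Read GAF 2.x (or a 2-column protein<TAB>GO-id TSV) into direct records.

    GAF columns used: 2 (object id), 4 (qualifier), 5 (GO id), 7 (evidence
    code).  Records with a NOT qualifier are dropped; records to obsolete or
    unknown terms are dropped and counted in ``ingest_stats``.
    """
    annots = AnnotationSet()
    stats = annots.ingest_stats
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("!"):
                continue
            if len(row) >= 7:
                protein, qualifier, term, evidence = row[1], row[3], row[4], row[6]
            elif len(row) == 2:  # fallback dialect
                protein, qualifier, term, evidence = row[0], "", row[1], ""
            else:
                raise OboFormatError(
                    f"annotation row with {len(row)} columns is neither GAF nor "
                    f"2-column TSV: {row!r}")
            if "NOT" in qualifier.split("|"):
                stats.dropped_not_qualifier += 1
                continue
            if term not in dag:
                stats.dropped_unknown_term += 1
                continue
            if dag.terms[term].obsolete:
                stats.dropped_obsolete += 1
                continue
            annots.add(protein, term, DIRECT, [evidence] if evidence else [])
            stats.kept += 1
    if stats.dropped_obsolete or stats.dropped_unknown_term:
        logger.info(
            "dropped %d records to obsolete terms, %d to unknown terms",
            stats.dropped_obsolete, stats.dropped_unknown_term)
    return annots


def write_gaf(annots: AnnotationSet, path: str, db: str = "weavenet") -> None:
    """Write the direct records as minimal GAF 2.2 (round-trips with parse_gaf)."""
    with open(path, "w", newline="") as fh:
        fh.write("!gaf-version: 2.2\n")
        writer = csv.writer(fh, delimiter="\t")
        for rec in sorted(annots.records(DIRECT), key=lambda r: (r.protein, r.term)):
            evidence = sorted(rec.evidence)[0] if rec.evidence else "IEA"
            row = [""] * _GAF_COLUMNS
            row[0], row[1], row[2] = db, rec.protein, rec.protein
            row[3], row[4] = "involved_in", rec.term
            row[5], row[6] = "PMID:0", evidence
            row[8], row[11] = "P", "protein"
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Propagation


def propagate_annotations(annots: AnnotationSet, dag: OntologyDag,
                          relations: Iterable[str] = DEFAULT_RELATIONS) -> AnnotationSet:
    """Materialize inferred records for every ancestor of each direct record.

    Excluded roots (namespace roots / parentless terms) receive no inferred
    records.  A (protein, ancestor) pair that is itself directly annotated
    stays direct — never downgraded.  Idempotent.
    """
    out = AnnotationSet()
    out._display = dict(annots._display)
    excluded = dag.excluded_roots()
    for rec in annots.records(DIRECT):
        if rec.term not in dag:
            raise KeyError(f"annotated term {rec.term} not in ontology")
        out.add(rec.protein, rec.term, DIRECT, rec.evidence)
    for rec in annots.records(DIRECT):
        for anc in dag.ancestors(rec.term, relations):
            if anc in excluded or out.has(rec.protein, anc, DIRECT):
                continue
            out.add(rec.protein, anc, INFERRED)
    out.ingest_stats = annots.ingest_stats
    return out
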