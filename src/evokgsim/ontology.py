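"""Ontology and annotation handling.

Parses OBO ontologies restricted to ``is_a`` edges, builds per-aspect rooted
sub-DAGs (the semantic aspects, e.g. GO's biological process, cellular
component and molecular function), computes intrinsic information content
from descendant counts, and loads GAF 2.x annotation files into an
:class:`AnnotationStore`.

The internal graph convention is a :class:`networkx.DiGraph` whose edges run
child -> parent, so *ontological ancestors* of a term are the nodes reachable
from it.
"""

from __future__ import annotations

import hashlib
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio.UniProt.GOA import gafiterator

logger = logging.getLogger("evokgsim")

#: canonical short labels for the Gene Ontology namespaces
_NAMESPACE_LABELS = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


class OntologyStructureError(ValueError):
    """Raised for cycles, unrooted terms, or degenerate aspects."""


@dataclass
class OntologyGraph:
    """A multi-aspect ontology: a DAG of is-a edges with per-term IC.

    Parameters
    ----------
    graph:
        DiGraph with child -> parent ``is_a`` edges.
    aspect_of:
        term id -> aspect label (e.g. ``"BP"``).
    roots:
        aspect label -> root term id.
    ic:
        term id -> information content in [0, 1]; filled by
        :func:`compute_ic`.
    alt_ids:
        alternate id -> canonical id, from OBO ``alt_id`` lines.
    """

    graph: nx.DiGraph
    aspect_of: dict[str, str]
    roots: dict[str, str]
    ic: dict[str, float] = field(default_factory=dict)
    ic_raw: dict[str, float] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    # ancestor-closure cache; observationally equivalent to recomputation
    # because the graph is treated as immutable once built
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def is_a_edges(self) -> set[tuple[str, str]]:
        """Set of (child, parent) pairs."""
        return set(self.graph.edges)

    @property
    def aspects(self) -> tuple[str, ...]:
        return tuple(sorted(self.roots))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical term id (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def aspect_terms(self, aspect: str) -> set[str]:
        return {t for t, a in self.aspect_of.items() if a == aspect}

    def checksum(self) -> str:
        """Stable digest of the term and edge sets, for provenance."""
        h = hashlib.sha256()
        for t in sorted(self.graph.nodes):
            h.update(t.encode())
        for c, p in sorted(self.graph.edges):
            h.update(f"{c}>{p}".encode())
        return h.hexdigest()[:16]

    def validate(self) -> None:
        """Check the structural invariants (DAG, one root per term)."""
        _check_structure(self.graph, self.roots)


def _aspect_label_for_root(root: str, namespace: str | None) -> str:
    if namespace:
        return _NAMESPACE_LABELS.get(namespace, namespace)
    return root


def _check_structure(graph: nx.DiGraph, roots: Mapping[str, str]) -> dict[str, str]:
    """Validate acyclicity and single-root reachability; return aspect map."""
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyStructureError(
            f"ontology contains a cycle through term {cycle[0][0]!r}"
        )
    aspect_of: dict[str, str] = {}
    for aspect, root in roots.items():
        # nodes that reach the root, i.e. the aspect sub-DAG
        for term in nx.ancestors(graph, root) | {root}:
            if term in aspect_of:
                raise OntologyStructureError(
                    f"term {term!r} reaches more than one aspect root"
                )
            aspect_of[term] = aspect
    unrooted = set(graph.nodes) - set(aspect_of)
    if unrooted:
        term = sorted(unrooted)[0]
        raise OntologyStructureError(f"term {term!r} has no path to any aspect root")
    return aspect_of


def build_graph(
    edges: Iterable[tuple[str, str]],
    terms: Iterable[str] | None = None,
    names: Mapping[str, str] | None = None,
    namespaces: Mapping[str, str] | None = None,
) -> OntologyGraph:
    """Assemble an :class:`OntologyGraph` from (child, parent) is-a edges.

    Roots are detected as terms with no parent; aspect labels come from
    ``namespaces`` (term -> OBO namespace) when given, else the root id.
    """
    g = nx.DiGraph()
    if terms is not None:
        g.add_nodes_from(terms)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyStructureError(
            f"ontology contains a cycle through term {cycle[0][0]!r}"
        )
    roots = {}
    for node in g.nodes:
        if g.out_degree(node) == 0:
            ns = (namespaces or {}).get(node)
            label = _aspect_label_for_root(node, ns)
            if label in roots:
                raise OntologyStructureError(
                    f"two roots share the aspect label {label!r}"
                )
            roots[label] = node
    if not roots:
        raise OntologyStructureError("ontology has no root term")
    aspect_of = _check_structure(g, roots)
    return OntologyGraph(
        graph=g, aspect_of=aspect_of, roots=roots, names=dict(names or {})
    )


def parse_obo(path, relations: frozenset[str] | set[str] = frozenset({"is_a"})) -> OntologyGraph:
    """Parse an OBO file keeping only the requested relations (default is-a).

    Obsolete terms are dropped (obonet's default), ``alt_id`` entries are
    recorded for canonical-id mapping, and each aspect root is detected as a
    term with no parent.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key in relations
    ]
    names = {
        n: data["name"] for n, data in multigraph.nodes(data=True) if "name" in data
    }
    namespaces = {
        n: data["namespace"]
        for n, data in multigraph.nodes(data=True)
        if "namespace" in data
    }
    og = build_graph(
        edges, terms=multigraph.nodes, names=names, namespaces=namespaces
    )
    for node, data in multigraph.nodes(data=True):
        for alt in data.get("alt_id", []):
            og.alt_ids[alt] = node
    return og


def write_obo(graph: OntologyGraph, path) -> None:
    """Write the graph back out as a minimal OBO 1.2 flat file."""
    inverse_labels = {v: k for k, v in _NAMESPACE_LABELS.items()}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(graph.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {graph.names.get(term, term)}\n")
            aspect = graph.aspect_of[term]
            fh.write(f"namespace: {inverse_labels.get(aspect, aspect)}\n")
            for _, parent in sorted(graph.graph.out_edges(term)):
                fh.write(f"is_a: {parent} ! {graph.names.get(parent, parent)}\n")
            fh.write("\n")


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Reflexive-transitive is-a closure of ``term`` (includes the term)."""
    term = graph.canonical(term)
    cached = graph._anc_cache.get(term)
    if cached is not None:
        return cached
    if term not in graph.graph:
        raise KeyError(f"unknown term {term!r}")
    result = frozenset(nx.descendants(graph.graph, term)) | {term}
    graph._anc_cache[term] = result
    return result


def compute_ic(
    graph: OntologyGraph,
    per_aspect: bool = True,
    clamp: bool = True,
) -> OntologyGraph:
    """Fill intrinsic (descendant-count) information content in place.

    For each term, ``hypo(t)`` is the number of descendants including the
    term itself and ``maxnodes`` the term count of its aspect sub-ontology
    (or of the whole ontology when ``per_aspect`` is False)::

        IC(t) = 1 - log(hypo(t) + 1) / log(maxnodes)

    The root's raw value is slightly negative because ``hypo(root) + 1``
    exceeds ``maxnodes``; it is clamped to 0 by default so every IC lies in
    [0, 1].  The unclamped value is kept in ``ic_raw``.
    """
    sizes = {a: len(graph.aspect_terms(a)) for a in graph.roots}
    total = len(graph.terms)
    for aspect, n in sizes.items():
        if (n if per_aspect else total) < 2:
            raise OntologyStructureError(
                f"aspect {aspect!r} has fewer than 2 terms; IC undefined"
            )
    g = graph.graph
    for term in g.nodes:
        hypo = len(nx.ancestors(g, term)) + 1  # descendants incl. the term
        maxnodes = sizes[graph.aspect_of[term]] if per_aspect else total
        raw = 1.0 - math.log(hypo + 1) / math.log(maxnodes)
        graph.ic_raw[term] = raw
        graph.ic[term] = max(raw, 0.0) if clamp else raw
    return graph


@dataclass
class AnnotationStore:
    """Direct annotations: entity -> aspect -> set of term ids."""

    direct: dict[str, dict[str, set[str]]]
    graph_ref: OntologyGraph

    @property
    def entities(self) -> set[str]:
        return set(self.direct)

    def add(self, entity: str, term: str) -> None:
        graph = self.graph_ref
        term = graph.canonical(term)
        if term not in graph:
            raise KeyError(f"term {term!r} not in ontology")
        aspect = graph.aspect_of[term]
        self.direct.setdefault(entity, {}).setdefault(aspect, set()).add(term)

    def validate(self) -> None:
        for entity, by_aspect in self.direct.items():
            for aspect, terms in by_aspect.items():
                for t in terms:
                    if t not in self.graph_ref:
                        raise KeyError(f"{entity}: term {t!r} not in ontology")
                    if self.graph_ref.aspect_of[t] != aspect:
                        raise ValueError(
                            f"{entity}: term {t!r} filed under wrong aspect"
                        )


class EmptyAnnotationError(ValueError):
    """Raised when a GAF file yields zero usable records."""


def parse_gaf(
    path,
    graph: OntologyGraph,
    exclude_not: bool = True,
    evidence_codes: set[str] | None = None,
) -> AnnotationStore:
    """Load a GAF 2.x file into an :class:`AnnotationStore`.

    NOT-qualified records are excluded (configurable); records whose term —
    after alt_id mapping — is absent from the graph are dropped with a
    logged count.  The aspect is taken from the graph, not the GAF aspect
    column.  Malformed lines are skipped with a warning count.
    """
    clean = io.StringIO()
    malformed = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                clean.write(line)
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                malformed += 1
                continue
            clean.write(line)
    clean.seek(0)
    store = AnnotationStore(direct={}, graph_ref=graph)
    dropped_unknown = 0
    excluded_not = 0
    excluded_evidence = 0
    usable = 0
    for rec in gafiterator(clean):
        if exclude_not and any(q.upper() == "NOT" or q.upper().startswith("NOT|") for q in rec["Qualifier"]):
            excluded_not += 1
            continue
        if evidence_codes is not None and rec["Evidence"] not in evidence_codes:
            excluded_evidence += 1
            continue
        term = graph.canonical(rec["GO_ID"])
        if term not in graph:
            dropped_unknown += 1
            continue
        store.add(rec["DB_Object_ID"], term)
        usable += 1
    if malformed:
        logger.warning("parse_gaf: skipped %d malformed lines", malformed)
    if dropped_unknown:
        logger.info("parse_gaf: dropped %d records with unknown terms", dropped_unknown)
    if excluded_not:
        logger.info("parse_gaf: excluded %d NOT-qualified records", excluded_not)
    if usable == 0:
        raise EmptyAnnotationError(f"no usable annotation records in {path}")
    store.drop_counts = {  # type: ignore[attr-defined]
        "malformed": malformed,
        "unknown_term": dropped_unknown,
        "not_qualified": excluded_not,
        "evidence_filtered": excluded_evidence,
    }
    return store


def write_gaf(store: AnnotationStore, path) -> None:
    """Write direct annotations as a minimal GAF 2.1 file."""
    aspect_code = {"BP": "P", "CC": "C", "MF": "F"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for entity in sorted(store.direct):
            for aspect in sorted(store.direct[entity]):
                for term in sorted(store.direct[entity][aspect]):
                    cols = [
                        "SYN",            # DB
                        entity,           # DB Object ID
                        entity,           # DB Object Symbol
                        "",               # Qualifier
                        term,             # GO ID
                        "SYN:0000",       # DB:Reference
                        "IEA",            # Evidence
                        "",               # With/From
                        aspect_code.get(aspect, aspect[:1]),  # Aspect
                        "",               # DB Object Name
                        "",               # Synonym
                        "protein",        # DB Object Type
                        "taxon:0",        # Taxon
                        "20190101",       # Date
                        "SYN",            # Assigned By
                        "",               # Annotation Extension
                        "",               # Gene Product Form ID
                    ]
                    fh.write("\t".join(cols) + "\n")


def annotations(
    store: AnnotationStore, entity: str, aspect: str, mode: str = "direct"
) -> frozenset[str]:
    """Annotation set of an entity in one aspect.

    ``direct`` returns the GAF-derived set; ``extended`` the union of the
    ancestor closures of the direct terms ("direct and inherited").  Unknown
    entities yield the empty set so the pair filter can run downstream.
    """
    terms = store.direct.get(entity, {}).get(aspect, set())
    if mode == "direct":
        return frozenset(terms)
    if mode == "extended":
        out: set[str] = set()
        for t in terms:
            out |= ancestors(store.graph_ref, t)
        return frozenset(out)
    raise ValueError(f"unknown annotation mode {mode!r}")
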