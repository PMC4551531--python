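"""Gene Ontology DAG: OBO parsing, reachability queries, true-path closure.

The term graph is held as a directed graph with parent -> child edges, so a
"descendant" is anything reachable by following edges forward.  Only
non-obsolete ``[Term]`` stanzas are retained, and edges are derived from a
configurable relation set (``is_a`` and ``part_of`` by default).
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Iterator, TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .annotations import AnnotationTable

logger = logging.getLogger(__name__)

#: Relation types turned into parent -> child edges by default.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


class OntologyIntegrityError(ValueError):
    """The parsed term graph violates a structural requirement (e.g. a cycle)."""


class UnknownTermError(KeyError):
    """A term identifier is not present in the ontology."""


class OntologyDag:
    """An immutable-ish view of a GO-style term DAG.

    Parameters
    ----------
    edges:
        Iterable of ``(parent, child)`` term-id pairs.
    terms:
        All term ids, including isolated ones.
    names:
        Optional per-term label text.
    namespaces:
        Optional per-term sub-ontology tag (``biological_process`` etc. for
        real GO, or any tag for synthetic ontologies).
    """

    def __init__(
        self,
        terms: Iterable[str],
        edges: Iterable[tuple[str, str]],
        names: dict[str, str] | None = None,
        namespaces: dict[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for parent, child in edges:
            if parent not in g or child not in g:
                raise UnknownTermError(f"edge ({parent!r}, {child!r}) references an unknown term")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyIntegrityError(f"term graph contains a cycle: {cycle}")
        self._graph = g
        self.names: dict[str, str] = dict(names or {})
        self.namespaces: dict[str, str] = dict(namespaces or {})
        self._desc_cache: dict[str, frozenset[str]] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges)

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def _require(self, term: str) -> None:
        if term not in self._graph:
            raise UnknownTermError(f"unknown term {term!r}")

    def has_edge(self, parent: str, child: str) -> bool:
        return self._graph.has_edge(parent, child)

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._graph.predecessors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._graph.successors(term))

    def is_leaf(self, term: str) -> bool:
        self._require(term)
        return self._graph.out_degree(term) == 0

    def descendants(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` by >= 1 downward edge (excl. itself)."""
        self._require(term)
        cached = self._desc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term))
            self._desc_cache[term] = cached
        return cached

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms from which ``term`` is reachable (excl. itself)."""
        self._require(term)
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term))
            self._anc_cache[term] = cached
        return cached

    def ancestors_or_self(self, term: str) -> frozenset[str]:
        return self.ancestors(term) | {term}

    def roots(self, namespace: str | None = None) -> list[str]:
        """Terms without parents, optionally restricted to one namespace."""
        out = [t for t in self._graph.nodes if self._graph.in_degree(t) == 0]
        if namespace is not None:
            out = [t for t in out if self.namespaces.get(t) == namespace]
        return sorted(out)

    def depth(self, term: str) -> int:
        """Length of the longest path from a root down to ``term``."""
        anc = self.ancestors(term)
        if not anc:
            return 0
        return _longest_to(self._graph.subgraph(anc | {term}), term)

    def subgraph_namespace(self, namespace: str) -> "OntologyDag":
        """The per-namespace sub-DAG (cross-namespace edges are dropped)."""
        keep = [t for t in self._graph.nodes if self.namespaces.get(t) == namespace]
        keep_set = set(keep)
        edges = [(u, v) for u, v in self._graph.edges if u in keep_set and v in keep_set]
        return OntologyDag(
            keep,
            edges,
            {t: self.names[t] for t in keep if t in self.names},
            {t: namespace for t in keep},
        )


def _longest_to(graph: nx.DiGraph, term: str) -> int:
    # longest path ending at `term` in a small ancestor-closed subgraph
    order = list(nx.topological_sort(graph))
    dist = {t: 0 for t in order}
    for t in order:
        for c in graph.successors(t):
            dist[c] = max(dist[c], dist[t] + 1)
    return dist[term]


# -- OBO parsing ---------------------------------------------------------


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        if "\n" in stream or "[Term]" in stream:
            yield from stream.splitlines()
        else:
            with open(stream, "rt", encoding="utf-8") as fh:
                yield from fh
    else:
        yield from stream


def parse_obo(
    stream: str | IO[str] | Iterable[str],
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> OntologyDag:
    """Parse OBO 1.2/1.4 stanza text into an :class:`OntologyDag`.

    Obsolete terms are dropped, together with every edge touching them.
    ``relations`` selects which relationship types become parent -> child
    edges; ``is_a`` is always taken from its dedicated tag line.
    """
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    default_namespace: str | None = None
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n").strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {"_line": lineno, "parents": []} if in_term else None
            if in_term:
                stanzas.append(current)
            continue
        if ":" not in line:
            if in_term:
                raise OboParseError(f"line {lineno}: malformed tag line {line!r}")
            continue  # tolerate odd header/typedef content
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.split("!")[0].strip()
        if current is None or not in_term:
            if key == "default-namespace":
                default_namespace = value
            continue
        if key == "id":
            current["id"] = value
        elif key == "name":
            current["name"] = value
        elif key == "namespace":
            current["namespace"] = value
        elif key == "is_obsolete":
            current["obsolete"] = value.lower() == "true"
        elif key == "is_a":
            if "is_a" in relations:
                if not value:
                    raise OboParseError(f"line {lineno}: empty is_a target")
                current["parents"].append(value)
        elif key == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"line {lineno}: malformed relationship {value!r}")
            rel, target = parts[0], parts[1]
            if rel in relations:
                current["parents"].append(target)

    terms: list[str] = []
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    obsolete = set()
    for st in stanzas:
        tid = st.get("id")
        if tid is None:
            raise OboParseError(f"line {st['_line']}: [Term] stanza without an id")
        if st.get("obsolete", False):
            obsolete.add(tid)
            continue
        terms.append(tid)
        if "name" in st:
            names[tid] = st["name"]
        namespaces[tid] = st.get("namespace", default_namespace or "unknown")
        parents[tid] = st["parents"]

    term_set = set(terms)
    edges = []
    dropped = 0
    for child, ps in parents.items():
        for p in ps:
            if p in term_set:
                edges.append((p, child))
            else:
                dropped += 1
    if dropped:
        logger.info("parse_obo: dropped %d edges to obsolete/unknown parents", dropped)
    return OntologyDag(terms, edges, names, namespaces)


# -- true path rule ------------------------------------------------------


def propagate_true_path(dag: OntologyDag, table: "AnnotationTable") -> "AnnotationTable":
    """Upward-close every protein's annotation set (the true path rule).

    Idempotent; the returned table's universe is extended with any ancestor
    terms the closure introduces.
    """
    from .annotations import AnnotationTable

    new_sets: dict[str, set[str]] = {}
    universe = set(table.universe)
    for protein in table.proteins:
        closed: set[str] = set()
        for t in table.term_sets[protein]:
            if t not in dag:
                raise UnknownTermError(
                    f"protein {protein!r} is annotated to unknown term {t!r}"
                )
            closed.add(t)
            closed |= dag.ancestors(t)
        new_sets[protein] = closed
        universe |= closed
    return AnnotationTable(list(table.proteins), new_sets, universe)


def protein_leaf_terms(dag: OntologyDag, terms: set[str] | frozenset[str]) -> set[str]:
    """Members of an upward-closed set having no child inside the set.

    These are the leaves of the protein-specific sub-hierarchy: the only
    terms that may be masked away (or extended downward).
    """
    return {t for t in terms if not (dag.children(t) & terms)}
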