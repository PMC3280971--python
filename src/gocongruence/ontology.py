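"""Gene Ontology DAG parsing and ancestor-closure computation.

The ontology is read from OBO 1.2 text into a validated :class:`OntologyGraph`
— a directed acyclic graph whose edges point from child term to parent term
and carry a relation type (``is_a`` or ``part_of``). Annotation propagation
(the "true path rule") is the reflexive transitive closure over those two
relations: an experimental annotation to a term implies annotation to every
ancestor up to the aspect root. Other relation types (``regulates`` and kin)
are parsed but never traversed, matching the GO annotation-propagation
convention.

Obsolete terms are kept in the term map so they can be reported helpfully,
but they carry no edges and cannot enter a closure.
"""

from __future__ import annotations

import io
import logging
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Relations traversed by annotation propagation, per GO convention.
CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

#: Aspect code (GAF column 9) per GO namespace.
NAMESPACE_TO_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}
ASPECT_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}


class OntologyError(Exception):
    """Base class for ontology parsing/validation/lookup failures."""


class OntologyParseError(OntologyError):
    """A stanza is malformed (missing id or namespace, bad accession)."""


class OntologyValidationError(OntologyError):
    """The parsed graph violates a structural invariant (cycle, dangling edge)."""


class UnknownTermError(OntologyError, KeyError):
    """A term id is neither a primary id nor an alt_id."""


class ObsoleteTermError(OntologyError):
    """The term exists but is obsolete; carries a replacement hint if any."""

    def __init__(self, term_id: str, replaced_by: tuple[str, ...] = ()):
        hint = f"; replaced_by {', '.join(replaced_by)}" if replaced_by else ""
        super().__init__(f"term {term_id} is obsolete{hint}")
        self.term_id = term_id
        self.replaced_by = replaced_by


class AltIdCollisionError(OntologyError):
    """One alt_id maps to more than one primary term — ambiguous, refuse."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single GO term as read from a [Term] stanza."""

    id: str
    name: str
    namespace: str
    is_obsolete: bool = False
    alt_ids: tuple[str, ...] = ()
    replaced_by: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise OntologyParseError(f"{self.id!r} is not a GO accession")
        if self.namespace not in NAMESPACE_TO_ASPECT:
            raise OntologyParseError(
                f"term {self.id}: unknown namespace {self.namespace!r}"
            )

    @property
    def aspect(self) -> str:
        return NAMESPACE_TO_ASPECT[self.namespace]


@dataclass
class OntologyGraph:
    """Validated GO DAG with alt-id resolution and closure queries.

    ``edges`` maps each child id to tuples ``(parent_id, relation)`` with
    relation restricted to is_a/part_of; edges never touch obsolete terms.
    """

    terms: dict[str, OntologyTerm]
    edges: dict[str, tuple[tuple[str, str], ...]]
    roots: tuple[str, ...]
    alt_id_index: dict[str, str] = field(default_factory=dict)

    # -- lookup ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Resolve a primary or alternate id to the primary id.

        Raises :class:`UnknownTermError` or :class:`ObsoleteTermError`.
        """
        if term_id in self.terms:
            primary = term_id
        elif term_id in self.alt_id_index:
            primary = self.alt_id_index[term_id]
        else:
            raise UnknownTermError(f"unknown term {term_id!r}")
        term = self.terms[primary]
        if term.is_obsolete:
            raise ObsoleteTermError(primary, term.replaced_by)
        return primary

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_id_index

    def aspect_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].aspect

    def root_of_aspect(self, aspect: str) -> str | None:
        ns = ASPECT_TO_NAMESPACE[aspect]
        for r in self.roots:
            if self.terms[r].namespace == ns:
                return r
        return None

    # -- closure --------------------------------------------------------

    def ancestors(
        self,
        term_id: str,
        relations: Iterable[str] = CLOSURE_RELATIONS,
    ) -> frozenset[str]:
        """Reflexive transitive closure of ``term_id`` over ``relations``.

        Always contains the term itself and (for a connected term) its
        aspect root. Breadth-first over the child→parent edges.
        """
        relations = frozenset(relations)
        start = self.resolve(term_id)
        seen = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for parent, rel in self.edges.get(node, ()):
                if rel in relations and parent not in seen:
                    seen.add(parent)
                    queue.append(parent)
        return frozenset(seen)

    def term_depth(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> int:
        """Length of the shortest directed path to the aspect root (root = 0)."""
        relations = frozenset(relations)
        start = self.resolve(term_id)
        root_set = set(self.roots)
        depth = 0
        frontier = {start}
        seen = set(frontier)
        while frontier:
            if frontier & root_set:
                return depth
            nxt: set[str] = set()
            for node in frontier:
                for parent, rel in self.edges.get(node, ()):
                    if rel in relations and parent not in seen:
                        seen.add(parent)
                        nxt.add(parent)
            frontier = nxt
            depth += 1
        raise OntologyValidationError(f"term {start} is not connected to a root")

    def parents(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> frozenset[str]:
        relations = frozenset(relations)
        primary = self.resolve(term_id)
        return frozenset(p for p, rel in self.edges.get(primary, ()) if rel in relations)

    # -- export ---------------------------------------------------------

    def write_closure_tsv(self, handle: TextIO, relations: Iterable[str] = CLOSURE_RELATIONS) -> None:
        """Dump the full closure as TSV: term_id, ancestor_id, path length."""
        handle.write("term_id\tancestor_id\trelation_path_length\n")
        for tid in sorted(self.terms):
            term = self.terms[tid]
            if term.is_obsolete:
                continue
            depths = self._closure_depths(tid, frozenset(relations))
            for anc in sorted(depths):
                handle.write(f"{tid}\t{anc}\t{depths[anc]}\n")

    def _closure_depths(self, term_id: str, relations: frozenset[str]) -> dict[str, int]:
        depths = {term_id: 0}
        queue = deque([term_id])
        while queue:
            node = queue.popleft()
            for parent, rel in self.edges.get(node, ()):
                if rel in relations and parent not in depths:
                    depths[parent] = depths[node] + 1
                    queue.append(parent)
        return depths


def parse_obo(stream: TextIO | str) -> OntologyGraph:
    """Parse OBO 1.2 text into a validated :class:`OntologyGraph`.

    Obsolete terms are retained in the term map but excluded from edges;
    unknown stanza keys and non-closure relationship types are ignored.

    Raises
    ------
    OntologyParseError
        on a stanza missing ``id`` or ``namespace``.
    OntologyValidationError
        on a directed cycle (the message lists one) or a dangling edge.
    AltIdCollisionError
        when one alt_id maps to two different primary terms.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        multigraph = obonet.read_obo(stream, ignore_obsolete=False)
    except KeyError as exc:  # obonet raises bare KeyError('id') on id-less stanza
        raise OntologyParseError(f"stanza missing required key: {exc}") from exc

    terms: dict[str, OntologyTerm] = {}
    for node, data in multigraph.nodes(data=True):
        if "namespace" not in data:
            raise OntologyParseError(f"stanza {node}: missing namespace")
        terms[node] = OntologyTerm(
            id=node,
            name=data.get("name", node),
            namespace=data["namespace"],
            is_obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            alt_ids=tuple(data.get("alt_id", ())),
            replaced_by=tuple(data.get("replaced_by", ())),
        )

    alt_index: dict[str, str] = {}
    for term in terms.values():
        for alt in term.alt_ids:
            if alt in alt_index and alt_index[alt] != term.id:
                raise AltIdCollisionError(
                    f"alt_id {alt} maps to both {alt_index[alt]} and {term.id}"
                )
            alt_index[alt] = term.id

    edges: dict[str, list[tuple[str, str]]] = {}
    closure_graph = nx.DiGraph()
    closure_graph.add_nodes_from(t for t in terms)
    n_dropped_obsolete_edges = 0
    for child, parent, relation in multigraph.edges(keys=True):
        if relation not in CLOSURE_RELATIONS:
            continue
        if parent not in terms:
            raise OntologyValidationError(
                f"edge {child} -[{relation}]-> {parent}: unknown parent term"
            )
        if terms[child].is_obsolete or terms[parent].is_obsolete:
            n_dropped_obsolete_edges += 1
            continue
        edges.setdefault(child, []).append((parent, relation))
        closure_graph.add_edge(child, parent)
    if n_dropped_obsolete_edges:
        logger.warning(
            "dropped %d edges touching obsolete terms", n_dropped_obsolete_edges
        )

    if not nx.is_directed_acyclic_graph(closure_graph):
        cycle = nx.find_cycle(closure_graph)
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyValidationError(f"ontology contains a cycle: {path}")

    roots = tuple(
        sorted(
            t
            for t, term in terms.items()
            if not term.is_obsolete and not edges.get(t)
        )
    )
    return OntologyGraph(
        terms=terms,
        edges={c: tuple(ps) for c, ps in edges.items()},
        roots=roots,
        alt_id_index=alt_index,
    )
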