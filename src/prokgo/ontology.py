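"""Gene Ontology DAG loading and traversal.

The ontology is read from an OBO 1.2 flat file into a directed graph whose
edges point child -> parent. ``is_a`` edges are always kept; ``part_of``
edges are optional at load time. Obsolete terms are retained in the term
table (so stale identifiers can still be resolved) but excluded from the
graph. The graph is validated on load: it must be acyclic, every edge must
join known non-obsolete terms, and ``is_a`` edges must stay inside a single
namespace.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed; carries the offending line."""


class OntologyValidationError(ValueError):
    """Raised when a parsed ontology violates a structural invariant."""


class UnknownTermError(KeyError):
    """Raised when a term identifier is not present in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """An acyclic term graph partitioned into the three GO namespaces.

    Attributes
    ----------
    terms : mapping of term_id -> OntologyTerm (obsolete terms included)
    alt_ids : mapping of secondary id -> primary term_id
    graph : networkx DiGraph over non-obsolete terms, edges child -> parent
        with a ``relation`` attribute (``is_a`` or ``part_of``)
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- lookups ---------------------------------------------------------

    def resolve(self, term_id: str) -> str | None:
        """Map a (possibly secondary) accession to its primary term_id."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def _require(self, term_id: str) -> str:
        if term_id not in self.graph:
            raise UnknownTermError(f"term {term_id!r} not in ontology graph")
        return term_id

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self._require(term_id)].namespace

    # -- traversal -------------------------------------------------------

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable by following child->parent edges; excludes self."""
        return nx.descendants(self.graph, self._require(term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All terms from which ``term_id`` is reachable; excludes self."""
        return nx.ancestors(self.graph, self._require(term_id))

    def roots(self, namespace: str | None = None) -> set[str]:
        """Terms with no parent, optionally restricted to one namespace."""
        out = {t for t in self.graph if self.graph.out_degree(t) == 0}
        if namespace is not None:
            _check_namespace(namespace)
            out = {t for t in out if self.terms[t].namespace == namespace}
        return out

    def namespace_subgraph(self, namespace: str) -> "OntologyGraph":
        """Induced subgraph of one GO domain."""
        _check_namespace(namespace)
        keep = {t for t in self.graph if self.terms[t].namespace == namespace}
        sub = OntologyGraph()
        sub.terms = {t: self.terms[t] for t in keep}
        sub.alt_ids = {a: p for a, p in self.alt_ids.items() if p in keep}
        sub.graph = self.graph.subgraph(keep).copy()
        return sub

    # -- export ----------------------------------------------------------

    def write_edge_tsv(self, path: str | Path) -> None:
        """Dump the edge list (child, parent, relation) for debugging."""
        with open(path, "w") as fh:
            fh.write("child\tparent\trelation\n")
            for c, p, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{c}\t{p}\t{d['relation']}\n")


def _check_namespace(namespace: str) -> None:
    if namespace not in NAMESPACES:
        raise ValueError(
            f"unknown namespace {namespace!r}; valid values: {', '.join(NAMESPACES)}"
        )


def _prevalidate_obo_lines(lines: Iterable[str]) -> None:
    """Cheap structural check so parse failures can name a line number."""
    in_stanza = False
    for i, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {i}: malformed stanza header {raw.strip()!r}")
            in_stanza = True
            continue
        if in_stanza and ":" not in line:
            raise OboParseError(f"line {i}: expected 'tag: value', got {raw.strip()!r}")


def load_obo(path: str | Path, include_part_of: bool = True) -> OntologyGraph:
    """Load an OBO 1.2 ontology file into a validated :class:`OntologyGraph`.

    Parameters
    ----------
    path : path to an OBO flat file.
    include_part_of : if True (default), ``relationship: part_of`` lines
        become traversable edges alongside ``is_a``.

    Raises
    ------
    OboParseError : malformed stanza content (names the offending line).
    OntologyValidationError : cycle detected, edge to an unknown or obsolete
        term, or an ``is_a`` edge crossing namespaces.
    """
    return load_obo_text(Path(path).read_text(), include_part_of=include_part_of)


def load_obo_text(text: str, include_part_of: bool = True) -> OntologyGraph:
    """Parse OBO content given as a string; see :func:`load_obo`."""
    _prevalidate_obo_lines(text.splitlines())
    try:
        multi = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except OboParseError:
        raise
    except Exception as exc:  # pragma: no cover - obonet error text varies
        raise OboParseError(f"failed to parse OBO content: {exc}") from exc

    onto = OntologyGraph()
    for term_id, data in multi.nodes(data=True):
        ns = data.get("namespace", "")
        if ns and ns not in NAMESPACES:
            raise OntologyValidationError(
                f"term {term_id} has unknown namespace {ns!r}"
            )
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        onto.terms[term_id] = OntologyTerm(
            term_id=term_id, name=data.get("name", ""), namespace=ns, obsolete=obsolete
        )
        for alt in data.get("alt_id", []):
            onto.alt_ids[alt] = term_id

    live = {t for t, term in onto.terms.items() if not term.obsolete}
    onto.graph.add_nodes_from(live)
    for child, parent, rel in multi.edges(keys=True):
        if rel == "is_a":
            pass
        elif rel == "part_of" and include_part_of:
            pass
        else:
            continue
        for endpoint in (child, parent):
            if endpoint not in onto.terms:
                raise OntologyValidationError(
                    f"edge {child}->{parent} ({rel}) references unknown term {endpoint}"
                )
            if onto.terms[endpoint].obsolete:
                raise OntologyValidationError(
                    f"edge {child}->{parent} ({rel}) references obsolete term {endpoint}"
                )
        if rel == "is_a" and onto.terms[child].namespace != onto.terms[parent].namespace:
            raise OntologyValidationError(
                f"is_a edge {child}->{parent} crosses namespaces"
            )
        # is_a wins if both relations link the same pair
        if not (onto.graph.has_edge(child, parent) and rel == "part_of"):
            onto.graph.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(onto.graph):
        cycle = nx.find_cycle(onto.graph)
        pretty = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise OntologyValidationError(f"ontology graph contains a cycle: {pretty}")
    return onto
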