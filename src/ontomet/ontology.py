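"""OBO-backed ontology graphs with subclass-closure queries.

Ontologies such as the Gene Ontology (GO), the NCBI organismal taxonomy
(NCBITaxon) and the Environment Ontology (ENVO) encode terms as classes
linked by ``is_a`` (subclass) relations, which gives them a directed acyclic
graph structure.  The recursive subclass closure of a class — every term
reachable downward through ``is_a`` — is the primitive that turns an
ontology into a data-discovery index: asking for "cellular metabolic
process" annotations means asking for annotations with *any* term in that
closure.

This module parses a restricted but sufficient subset of the OBO 1.2/1.4
flat-file format (``id``, ``name``, ``is_a``, ``is_obsolete`` and
``property_value: has_rank`` lines), validates acyclicity at load time, and
provides closure queries, label resolution and MIREOT-style subset
extraction (a chosen set of terms plus all their recursive superclasses).

Only ``is_a`` edges define the hierarchy; relationship edges such as
``part_of`` or ``regulates`` are deliberately ignored, matching subclass
query semantics.  Obsolete terms are retained for bookkeeping but excluded
from every closure.  Parents that do not resolve to a term in the file are
recorded in a dangling-parent report rather than dropped or treated as
fatal, since real ontology releases contain both situations.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "TermId",
    "OntologyTerm",
    "OntologyGraph",
    "OntologyError",
    "OboParseError",
    "CycleError",
    "UnknownTermError",
    "AmbiguousLabelError",
    "parse_curie",
    "parse_obo",
    "descendants",
    "ancestors",
    "extract_subset",
    "resolve",
    "write_obo",
]

TermId = str

_CURIE_RE = re.compile(r"^([^:\s]+):([^:\s]+)$")


class OntologyError(Exception):
    """Base class for ontology-layer errors."""


class OboParseError(OntologyError):
    """Malformed OBO input; message names the offending line."""


class CycleError(OntologyError):
    """The is_a relation contains a cycle; message lists one."""


class UnknownTermError(OntologyError, KeyError):
    """A queried term id is not present in the graph."""


class AmbiguousLabelError(OntologyError):
    """A label query matched more than one term."""

    def __init__(self, label: str, candidates: Iterable[TermId]):
        self.candidates = sorted(candidates)
        super().__init__(
            f"label {label!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


def parse_curie(s: str) -> tuple[str, str]:
    """Split a CURIE into (prefix, local), validating its shape.

    A CURIE has exactly one colon with nonempty prefix and local part,
    e.g. ``GO:0015979`` or ``NCBITaxon:1218``.
    """
    m = _CURIE_RE.match(s)
    if m is None:
        raise OntologyError(f"malformed CURIE: {s!r}")
    return m.group(1), m.group(2)


def is_curie(s: str) -> bool:
    return _CURIE_RE.match(s) is not None


@dataclass(frozen=True)
class OntologyTerm:
    id: TermId
    label: str = ""
    parent_ids: frozenset[TermId] = frozenset()
    rank: str = "no rank"
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """Immutable-by-convention DAG of CURIE-identified ontology terms.

    ``dangling_parents`` maps a term id to the subset of its declared
    parents that did not resolve to any term in the source; those edges are
    excluded from traversal but never silently forgotten.
    """

    terms: dict[TermId, OntologyTerm] = field(default_factory=dict)
    dangling_parents: dict[TermId, frozenset[TermId]] = field(default_factory=dict)
    _children: dict[TermId, set[TermId]] | None = field(
        default=None, repr=False, compare=False
    )

    def __contains__(self, term_id: TermId) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term_id: TermId) -> frozenset[TermId]:
        term = self._get(term_id)
        if term.obsolete:
            return frozenset()
        return frozenset(p for p in term.parent_ids if p in self.terms)

    def children_index(self) -> Mapping[TermId, set[TermId]]:
        if self._children is None:
            idx: dict[TermId, set[TermId]] = {t: set() for t in self.terms}
            for t in self.terms.values():
                if t.obsolete:
                    continue
                for p in t.parent_ids:
                    if p in self.terms:
                        idx[p].add(t.id)
            self._children = idx
        return self._children

    def label_of(self, term_id: TermId) -> str:
        return self._get(term_id).label

    def roots(self) -> set[TermId]:
        return {
            t.id
            for t in self.terms.values()
            if not t.obsolete and not self.parents(t.id)
        }

    def non_obsolete(self) -> set[TermId]:
        return {t.id for t in self.terms.values() if not t.obsolete}

    def _get(self, term_id: TermId) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term: {term_id}") from None

    def validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            if t.obsolete:
                continue
            for p in t.parent_ids:
                if p in self.terms:
                    g.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise CycleError(f"is_a cycle detected: {path}")


def _new_term(stanza: dict, line_no: int) -> OntologyTerm:
    if "id" not in stanza:
        raise OboParseError(f"[Term] stanza ending at line {line_no} has no id")
    obsolete = stanza.get("is_obsolete", "false").strip().lower() == "true"
    parents = frozenset() if obsolete else frozenset(stanza.get("is_a", ()))
    return OntologyTerm(
        id=stanza["id"],
        label=stanza.get("name", ""),
        parent_ids=parents,
        rank=stanza.get("rank", "no rank"),
        obsolete=obsolete,
    )


def parse_obo(stream) -> OntologyGraph:
    """Parse OBO flat-file text into a validated :class:`OntologyGraph`.

    ``stream`` may be a string or an iterable of lines (an open file).
    Interpreted tag lines inside ``[Term]`` stanzas: ``id``, ``name``,
    ``is_a`` (trailing ``! comment`` stripped), ``is_obsolete`` and
    ``property_value: has_rank``.  Everything else is ignored.  Raises
    :class:`OboParseError` for a stanza without an id (naming the line) and
    :class:`CycleError` if the is_a relation is cyclic.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    terms: dict[TermId, OntologyTerm] = {}
    stanza: dict | None = None
    stanza_is_term = False
    line_no = 0

    def flush(end_line: int) -> None:
        nonlocal stanza
        if stanza is not None and stanza_is_term:
            term = _new_term(stanza, end_line)
            if term.id in terms:
                raise OboParseError(
                    f"duplicate term id {term.id} at line {end_line}"
                )
            terms[term.id] = term
        stanza = None

    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("["):
            flush(line_no - 1)
            stanza = {}
            stanza_is_term = line == "[Term]"
            continue
        if stanza is None or not stanza_is_term or not line or line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            parse_curie(value)  # validates shape
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "is_a":
            target = value.split("!", 1)[0].strip()
            parse_curie(target)
            stanza.setdefault("is_a", []).append(target)
        elif tag == "is_obsolete":
            stanza["is_obsolete"] = value
        elif tag == "property_value":
            parts = value.split()
            if len(parts) >= 2 and parts[0].endswith("has_rank"):
                rank = parts[1].strip('"')
                if is_curie(rank):  # NCBITaxon:species style
                    rank = parse_curie(rank)[1]
                stanza["rank"] = rank.replace("_", " ")
    flush(line_no)

    dangling = {
        t.id: frozenset(p for p in t.parent_ids if p not in terms)
        for t in terms.values()
        if any(p not in terms for p in t.parent_ids)
    }
    graph = OntologyGraph(terms=terms, dangling_parents=dangling)
    graph.validate_acyclic()
    return graph


def _closure(
    start: TermId, neighbors, include_start: bool
) -> set[TermId]:
    seen: set[TermId] = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nxt in neighbors(node):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    if not include_start:
        seen.discard(start)
    return seen


def descendants(g: OntologyGraph, t: TermId, include_self: bool = True) -> set[TermId]:
    """Recursive subclasses of ``t``: all terms from which ``t`` is reachable
    via is_a edges.  Obsolete terms never appear in the result."""
    if t not in g:
        raise UnknownTermError(f"unknown term: {t}")
    idx = g.children_index()
    out = _closure(t, lambda n: idx[n], include_self)
    if include_self and g.terms[t].obsolete:
        out.discard(t)
    return out


def ancestors(g: OntologyGraph, t: TermId) -> set[TermId]:
    """Recursive superclasses of ``t`` (excluding ``t`` itself)."""
    if t not in g:
        raise UnknownTermError(f"unknown term: {t}")
    return _closure(t, g.parents, include_start=False)


def extract_subset(g: OntologyGraph, used: Iterable[TermId]) -> OntologyGraph:
    """MIREOT-style extraction: ``used`` plus all recursive parent classes.

    is_a edges are restricted to the retained node set; labels and ranks are
    preserved.  Unknown ids in ``used`` raise listing every offender.
    """
    used = set(used)
    unknown = sorted(u for u in used if u not in g)
    if unknown:
        raise UnknownTermError(f"unknown terms in extraction seed: {', '.join(unknown)}")
    keep = set(used)
    for u in used:
        keep |= ancestors(g, u)
    terms = {}
    for tid in keep:
        t = g.terms[tid]
        terms[tid] = OntologyTerm(
            id=t.id,
            label=t.label,
            parent_ids=frozenset(p for p in t.parent_ids if p in keep),
            rank=t.rank,
            obsolete=t.obsolete,
        )
    return OntologyGraph(terms=terms)


def resolve(g: OntologyGraph, query: str) -> TermId:
    """Resolve a CURIE or a human-readable label to a term id.

    CURIEs present in the graph pass straight through.  Labels are matched
    case-insensitively and exactly; an ambiguous label raises
    :class:`AmbiguousLabelError` listing the candidates.
    """
    if is_curie(query) and query in g:
        return query
    wanted = query.casefold()
    matches = [t.id for t in g.terms.values() if t.label.casefold() == wanted]
    if not matches:
        raise UnknownTermError(f"no term with id or label {query!r}")
    if len(matches) > 1:
        raise AmbiguousLabelError(query, matches)
    return matches[0]


def write_obo(g: OntologyGraph, path_or_stream) -> None:
    """Serialize the graph as OBO with stanzas sorted by term id.

    Sorting makes the output byte-stable, so a subset written twice (or
    round-tripped through :func:`parse_obo`) compares equal.
    """
    out = []
    out.append("format-version: 1.2\n")
    for tid in sorted(g.terms):
        t = g.terms[tid]
        out.append("\n[Term]\n")
        out.append(f"id: {t.id}\n")
        if t.label:
            out.append(f"name: {t.label}\n")
        for p in sorted(t.parent_ids):
            out.append(f"is_a: {p}\n")
        if t.rank != "no rank":
            out.append(f'property_value: has_rank NCBITaxon:{t.rank.replace(" ", "_")}\n')
        if t.obsolete:
            out.append("is_obsolete: true\n")
    text = "".join(out)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            fh.write(text)
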