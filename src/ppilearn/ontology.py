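"""Ontology graph parsing, depth assignment and annotation backtracking.

The ontology is read from an OBO 1.4 flat file and treated as a directed
acyclic graph with typed parent edges restricted to ``is_a``, ``part_of``
and ``regulates`` (the ``positively_regulates`` / ``negatively_regulates``
subtypes are folded into ``regulates``).

Depth ("level") is defined as the shortest-path distance from a single
*virtual root* placed above the namespace roots, so the namespace roots sit
at level 1 and a complete release of the Gene Ontology has exactly three
level-1 terms.  Annotation *backtracking* replaces every term annotated to a
protein by its ancestors-or-self at a fixed level ``L``; a term shallower
than ``L`` is kept as-is by default (``shallow="keep"``) or discarded
(``shallow="drop"``).
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "LevelAssignment",
    "BacktrackResult",
    "OboParseError",
    "OntologyCycleError",
    "UnknownTermWarning",
    "parse_obo",
    "parse_obo_text",
    "write_obo",
    "assign_levels",
    "ancestors_at_level",
    "backtrack_annotations",
    "level_term_counts",
    "backtrack_tally",
]

#: parent-edge relation types that participate in backtracking
RELATIONS = frozenset({"is_a", "part_of", "regulates"})

_REGULATES_SUBTYPES = frozenset({"positively_regulates", "negatively_regulates"})

VIRTUAL_ROOT = "VIRTUAL:ROOT"


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; the message names the line."""


class OntologyCycleError(ValueError):
    """Raised when the parent-edge graph contains a cycle."""


class UnknownTermWarning(UserWarning):
    """Emitted when an annotation references a term absent from the graph."""


@dataclass
class OntologyTerm:
    """A single ontology term.

    ``parents`` holds ``(parent_id, relation)`` pairs with relation in
    :data:`RELATIONS`.  ``alt_ids`` are secondary accessions that resolve to
    this term.
    """

    id: str
    name: str = ""
    namespace: str = ""
    parents: set[tuple[str, str]] = field(default_factory=set)
    obsolete: bool = False
    alt_ids: set[str] = field(default_factory=set)


class OntologyGraph:
    """Container of :class:`OntologyTerm` indexed by primary and alt id."""

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.alt_index: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self.alt_index[alt] = term.id

    @property
    def roots(self) -> list[str]:
        """Non-obsolete terms without parents, sorted for determinism."""
        return sorted(
            t.id for t in self.terms.values() if not t.obsolete and not t.parents
        )

    def resolve(self, term_id: str) -> str | None:
        """Map a primary or alternate accession to the primary id."""
        if term_id in self.terms:
            return term_id
        return self.alt_index.get(term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def n_edges(self) -> int:
        return sum(len(t.parents) for t in self.terms.values())


@dataclass(frozen=True)
class LevelAssignment:
    """Shortest-path depth of every reachable, non-obsolete term.

    Namespace roots are fixed at level 1; every other term satisfies
    ``level(t) == 1 + min(level(p) for p in parents(t))``.
    """

    level: dict[str, int]

    def __getitem__(self, term_id: str) -> int:
        return self.level[term_id]

    def get(self, term_id: str, default=None):
        return self.level.get(term_id, default)

    def max_level(self) -> int:
        return max(self.level.values()) if self.level else 0


@dataclass
class BacktrackResult:
    """Outcome of :func:`backtrack_annotations`."""

    mapping: dict[str, set[str]]
    distinct_terms: int
    skipped_terms: int


# ---------------------------------------------------------------------------
# OBO parsing / serialization
# ---------------------------------------------------------------------------


def _strip_comment(value: str) -> str:
    # trailing "! human readable" comments follow the accession
    return value.split(" ! ", 1)[0].strip()


def parse_obo_text(text: str, source: str = "<string>") -> OntologyGraph:
    """Parse OBO 1.4 stanza text into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are read; the keys used are ``id``, ``name``,
    ``namespace``, ``is_a``, ``relationship``, ``is_obsolete`` and
    ``alt_id``.  Parent edges whose relation is outside :data:`RELATIONS`
    (after folding the regulates subtypes) are ignored.  Dangling parent
    references are dropped with a warning.
    """
    terms: dict[str, OntologyTerm] = {}
    current: OntologyTerm | None = None
    in_term = False

    def flush():
        nonlocal current
        if current is not None:
            if current.id in terms:
                raise OboParseError(f"{source}: duplicate term id {current.id!r}")
            terms[current.id] = current
        current = None

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(
                    f"{source}, line {lineno}: malformed stanza header {line!r}"
                )
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term:
            # header block before the first stanza, or a non-Term stanza
            continue
        if ":" not in line:
            raise OboParseError(
                f"{source}, line {lineno}: expected 'key: value', got {line!r}"
            )
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "id":
            flush()
            current = OntologyTerm(id=_strip_comment(value))
            continue
        if current is None:
            raise OboParseError(
                f"{source}, line {lineno}: {key!r} before 'id' in [Term] stanza"
            )
        if key == "name":
            current.name = value
        elif key == "namespace":
            current.namespace = value
        elif key == "is_a":
            current.parents.add((_strip_comment(value), "is_a"))
        elif key == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(
                    f"{source}, line {lineno}: malformed relationship {value!r}"
                )
            rel, target = parts
            if rel in _REGULATES_SUBTYPES:
                rel = "regulates"
            if rel in RELATIONS:
                current.parents.add((target, rel))
        elif key == "is_obsolete":
            current.obsolete = value.lower().startswith("true")
        elif key == "alt_id":
            current.alt_ids.add(_strip_comment(value))
        # other keys (def, synonym, xref, ...) are ignored
    flush()

    graph = OntologyGraph(terms)
    dropped = 0
    for term in graph.terms.values():
        resolved = set()
        for pid, rel in term.parents:
            primary = graph.resolve(pid)
            if primary is None:
                dropped += 1
                continue
            resolved.add((primary, rel))
        term.parents = resolved
    if dropped:
        warnings.warn(
            f"{source}: dropped {dropped} parent edge(s) with dangling references",
            UnknownTermWarning,
            stacklevel=2,
        )
    return graph


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.4 file from disk. See :func:`parse_obo_text`."""
    path = Path(path)
    return parse_obo_text(path.read_text(), source=str(path))


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph to OBO 1.4 text (terms sorted by id, deterministic)."""
    lines = ["format-version: 1.4", ""]
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for alt in sorted(term.alt_ids):
            lines.append(f"alt_id: {alt}")
        for pid, rel in sorted(term.parents):
            if rel == "is_a":
                lines.append(f"is_a: {pid}")
            else:
                lines.append(f"relationship: {rel} {pid}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------


def _check_acyclic(graph: OntologyGraph) -> None:
    """DFS cycle check over parent edges; raises listing one cycle."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    for start in graph.terms:
        if color.get(start, WHITE) != WHITE:
            continue
        path: list[str] = []
        stack: list[tuple[str, Iterable[str]]] = [
            (start, iter(sorted(p for p, _ in graph.terms[start].parents)))
        ]
        color[start] = GRAY
        path.append(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                state = color.get(parent, WHITE)
                if state == GRAY:
                    cycle = path[path.index(parent):] + [parent]
                    raise OntologyCycleError(
                        "cycle in parent edges: " + " -> ".join(cycle)
                    )
                if state == WHITE:
                    color[parent] = GRAY
                    path.append(parent)
                    stack.append(
                        (
                            parent,
                            iter(sorted(p for p, _ in graph.terms[parent].parents)),
                        )
                    )
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                path.pop()
                color[node] = BLACK


def assign_levels(graph: OntologyGraph) -> LevelAssignment:
    """Breadth-first shortest-path depth from the virtual root.

    The namespace roots (parentless non-obsolete terms) get level 1.
    Obsolete terms are excluded.  Terms not reachable from any root get no
    level.  Raises :class:`OntologyCycleError` on a cyclic parent graph.
    """
    _check_acyclic(graph)
    children: dict[str, set[str]] = {}
    for term in graph.terms.values():
        if term.obsolete:
            continue
        for pid, _rel in term.parents:
            parent = graph.terms.get(pid)
            if parent is None or parent.obsolete:
                continue
            children.setdefault(pid, set()).add(term.id)

    level: dict[str, int] = {}
    queue: deque[str] = deque()
    for root in graph.roots:
        level[root] = 1
        queue.append(root)
    while queue:
        node = queue.popleft()
        for child in sorted(children.get(node, ())):
            if child not in level:
                level[child] = level[node] + 1
                queue.append(child)
    return LevelAssignment(level)


def level_term_counts(levels: LevelAssignment) -> dict[int, int]:
    """Number of distinct terms at each level (whole-graph tally)."""
    return dict(sorted(Counter(levels.level.values()).items()))


# ---------------------------------------------------------------------------
# Backtracking
# ---------------------------------------------------------------------------


def ancestors_at_level(
    graph: OntologyGraph,
    levels: LevelAssignment,
    term: str,
    L: int,
    shallow: str = "keep",
) -> set[str]:
    """All ancestors-or-self of ``term`` whose level equals ``L``.

    Traversal follows every parent edge (all three relation types).  A term
    shallower than ``L`` is returned as itself (``shallow="keep"``) or
    dropped (``shallow="drop"``).  Unknown, obsolete or unreachable terms
    yield an empty set with an :class:`UnknownTermWarning`.
    """
    if L < 1:
        raise ValueError(f"level must be >= 1, got {L}")
    if shallow not in ("keep", "drop"):
        raise ValueError(f"shallow must be 'keep' or 'drop', got {shallow!r}")
    tid = graph.resolve(term)
    if tid is None or graph.terms[tid].obsolete or tid not in levels.level:
        warnings.warn(
            f"term {term!r} not usable for backtracking (unknown, obsolete "
            "or unreachable)",
            UnknownTermWarning,
            stacklevel=2,
        )
        return set()
    if levels[tid] < L:
        return {tid} if shallow == "keep" else set()

    out: set[str] = set()
    seen = {tid}
    stack = [tid]
    while stack:
        cur = stack.pop()
        if levels.get(cur) == L:
            out.add(cur)
        for pid, _rel in graph.terms[cur].parents:
            if pid in seen:
                continue
            parent = graph.terms.get(pid)
            if parent is None or parent.obsolete:
                continue
            seen.add(pid)
            stack.append(pid)
    return out


def backtrack_annotations(
    annotations: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    levels: LevelAssignment,
    L: int,
    shallow: str = "keep",
) -> BacktrackResult:
    """Replace each protein's terms by their level-``L`` ancestors.

    Returns the per-protein union of :func:`ancestors_at_level` plus the
    number of distinct level-``L`` terms over the whole table and the count
    of annotation entries skipped as unresolvable.  Proteins with empty
    annotation sets are retained.
    """
    mapping: dict[str, set[str]] = {}
    skipped = 0
    all_terms: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnknownTermWarning)
        for protein, terms in annotations.items():
            out: set[str] = set()
            for term in terms:
                tid = graph.resolve(term)
                if tid is None or graph.terms[tid].obsolete or tid not in levels.level:
                    skipped += 1
                    continue
                out |= ancestors_at_level(graph, levels, tid, L, shallow=shallow)
            mapping[protein] = out
            all_terms |= out
    if skipped:
        warnings.warn(
            f"skipped {skipped} unresolvable annotation(s) during backtracking",
            UnknownTermWarning,
            stacklevel=2,
        )
    return BacktrackResult(mapping=mapping, distinct_terms=len(all_terms), skipped_terms=skipped)


def backtrack_tally(
    annotations: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    levels: LevelAssignment,
    level_range: Iterable[int] = range(1, 7),
    shallow: str = "keep",
) -> dict[int, int]:
    """Distinct-term tally of the backtracked table at each level."""
    tally: dict[int, int] = {}
    for L in level_range:
        result = backtrack_annotations(annotations, graph, levels, L, shallow=shallow)
        tally[L] = result.distinct_terms
    return tally
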