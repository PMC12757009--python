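"""Neighborhood expansion: grow a local graph from its backing engine.

``expand`` pulls, from the store behind the graph's engine handle, every edge
incident to a current node that passes the predicate and direction filters —
plus the nodes at their far ends, optionally restricted to a category set —
and returns the enlarged graph. With ``transitive=True`` the frontier step is
repeated to a fixed point, which is how ontology-style subclass hierarchies
are walked: ``descendants``/``ancestors`` are transitive inward/outward
``biolink:subclass_of`` expansions, and ``expand_n`` composes a bounded
number of single steps instead (two levels of subclasses rather than all of
them, say).

Every expansion obeys the supergraph contract: the output contains all nodes
and edges of its input.

Semantics pinned down here:

* ``direction="out"`` follows edges whose *subject* is a current node,
  ``"in"`` edges whose *object* is, ``"both"`` either.
* The category restriction applies only to newly added far-end nodes; it
  never removes existing nodes, and an edge between two nodes already in the
  graph is added whenever it passes the predicate/direction filters,
  whatever their categories.
* Transitive expansion requires a single direction and at least one
  predicate (transitive ``both`` would conflate ancestors and descendants
  into whole connected components) and tolerates cycles in the store.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .kg_model import SUBCLASS_OF, KnowledgeGraph

DIRECTIONS = ("out", "in", "both")


class MissingEngineError(RuntimeError):
    """The graph carries no engine handle, so there is no store to pull from."""


@dataclass(frozen=True)
class ExpandSpec:
    """Filters for one expansion.

    predicates / categories of ``None`` mean "all"; ``direction`` defaults to
    permissive ``"both"``.
    """

    predicates: Optional[tuple[str, ...]] = None
    categories: Optional[tuple[str, ...]] = None
    direction: str = "both"
    transitive: bool = False

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.predicates is not None:
            object.__setattr__(self, "predicates", tuple(self.predicates))
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(self.categories))
        if self.transitive:
            if self.direction == "both":
                raise ValueError("transitive expansion requires direction 'in' or 'out'")
            if not self.predicates:
                raise ValueError("transitive expansion requires at least one predicate")


def _as_tuple(value) -> Optional[tuple[str, ...]]:
    if value is None:
        return None
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def _step(engine, current: set, frontier: set, spec: ExpandSpec):
    """One frontier step: store edge rows to add and the new far-end ids."""
    out_idx, in_idx, categories = engine._ensure_indexes()
    edges = engine.store.edges
    subjects = edges["subject"].to_numpy() if len(edges) else []
    objects = edges["object"].to_numpy() if len(edges) else []
    predicates = edges["predicate"].to_numpy() if len(edges) else []
    predset = set(spec.predicates) if spec.predicates is not None else None
    catset = set(spec.categories) if spec.categories is not None else None

    candidate_rows: set[int] = set()
    if spec.direction in ("out", "both"):
        for nid in frontier:
            candidate_rows.update(out_idx.get(nid, ()))
    if spec.direction in ("in", "both"):
        for nid in frontier:
            candidate_rows.update(in_idx.get(nid, ()))

    selected: list[int] = []
    new_ids: set[str] = set()
    for i in sorted(candidate_rows):
        if predset is not None and predicates[i] not in predset:
            continue
        s, o = subjects[i], objects[i]
        # far endpoints relative to the current node set, per direction
        far: list[str] = []
        if spec.direction == "out":
            if s not in current:
                continue
            far = [o]
        elif spec.direction == "in":
            if o not in current:
                continue
            far = [s]
        else:
            far = [e for e in (s, o) if e not in current]
        newly = [e for e in far if e not in current]
        if newly and catset is not None:
            if any(not (set(categories.get(e, ())) & catset) for e in newly):
                continue
        selected.append(i)
        new_ids.update(newly)
    return selected, new_ids


def _apply(g: KnowledgeGraph, engine, edge_rows: list[int], node_ids_in_order: list[str]) -> KnowledgeGraph:
    store = engine.store
    nodes = g.nodes
    if node_ids_in_order:
        existing = set(nodes["id"])
        addset = set(node_ids_in_order) - existing
        add_nodes = store.nodes.loc[[nid in addset for nid in store.nodes["id"]]]
        nodes = pd.concat([nodes, add_nodes], ignore_index=True).astype(object)
        nodes = nodes.where(pd.notna(nodes), None)
    edges = g.edges
    if edge_rows:
        existing_triples = set(g.edge_triples())
        add = store.edges.iloc[sorted(set(edge_rows))]
        keep = [
            (s, p, o) not in existing_triples
            for s, p, o in zip(add["subject"], add["predicate"], add["object"])
        ]
        add = add.loc[keep]
        if len(add):
            edges = pd.concat([edges, add], ignore_index=True).astype(object)
            edges = edges.where(pd.notna(edges), None)
    return KnowledgeGraph(nodes, edges, g.engine)


def expand(
    g: KnowledgeGraph,
    spec: Optional[ExpandSpec] = None,
    *,
    predicates: Optional[Sequence[str]] = None,
    categories: Optional[Sequence[str]] = None,
    direction: str = "both",
    transitive: bool = False,
) -> KnowledgeGraph:
    """Expand a graph with matching edges and neighbor nodes from its store.

    Pass either a prebuilt :class:`ExpandSpec` or the individual filters as
    keyword arguments. Returns a supergraph of the input carrying the same
    engine handle.

    Raises
    ------
    MissingEngineError
        If ``g`` has no engine handle.
    ValueError
        For an unknown direction or an invalid transitive combination.
    """
    if spec is None:
        spec = ExpandSpec(
            predicates=_as_tuple(predicates),
            categories=_as_tuple(categories),
            direction=direction,
            transitive=transitive,
        )
    if g.engine is None:
        raise MissingEngineError(
            "graph has no engine handle; expansion needs a backing store"
        )
    engine = g.engine
    current = set(g.nodes["id"]) if len(g.nodes) else set()
    if not spec.transitive:
        rows, new_ids = _step(engine, current, current, spec)
        return _apply(g, engine, rows, sorted(new_ids))

    all_rows: list[int] = []
    order: list[str] = []
    frontier = set(current)
    while frontier:
        rows, new_ids = _step(engine, current, frontier, spec)
        all_rows.extend(rows)
        frontier = new_ids - current
        order.extend(sorted(frontier))
        current |= frontier
    return _apply(g, engine, all_rows, order)


def expand_n(
    g: KnowledgeGraph,
    predicates: Optional[Sequence[str]] = None,
    direction: str = "both",
    n: int = 1,
    categories: Optional[Sequence[str]] = None,
) -> KnowledgeGraph:
    """Compose ``n`` single (non-transitive) expansion steps.

    ``n=0`` returns the input unchanged; negative ``n`` is an error. Stops
    early once a step adds nothing (further steps would be identities).
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 0:
        raise ValueError(f"n must be a nonnegative integer, got {n!r}")
    out = g
    for _ in range(n):
        grown = expand(
            out, predicates=predicates, categories=categories, direction=direction
        )
        if len(grown.nodes) == len(out.nodes) and len(grown.edges) == len(out.edges):
            return grown
        out = grown
    return out


def descendants(g: KnowledgeGraph) -> KnowledgeGraph:
    """All transitive subtypes: inward ``biolink:subclass_of`` expansion."""
    return expand(g, predicates=(SUBCLASS_OF,), direction="in", transitive=True)


def ancestors(g: KnowledgeGraph) -> KnowledgeGraph:
    """All transitive supertypes: outward ``biolink:subclass_of`` expansion."""
    return expand(g, predicates=(SUBCLASS_OF,), direction="out", transitive=True)
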