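"""KG-aware graph algebra: join, rollups, attribute transfer, transitivity.

These operate on local graphs only (no engine needed) and respect the KG
identity rules: nodes are keyed by id, edges by (subject, predicate, object).

* :func:`kg_join` — set union of two graphs over those keys, with
  left-preferential attribute conflict resolution (missing values filled
  from the right operand). Joining graphs produced by engines over
  *different* stores is refused: node ids are only comparable within one KG.
* :func:`rollup` — aggregate an attribute over every node transitively
  reachable along one predicate (e.g. summing case counts up a disease
  hierarchy); :func:`transfer` is its one-step sibling (e.g. copying causal
  gene names onto disease nodes across the causal-gene edges).
* :func:`transitive_closure` / :func:`transitive_reduction` — add all
  path-implied edges for one predicate / remove all path-implied edges while
  preserving reachability. Reduction requires the predicate-labeled subgraph
  to be acyclic; closure tolerates cycles (and may then add self-loops).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import networkx as nx
import pandas as pd

from .kg_model import (
    EDGE_REQUIRED_COLUMNS,
    KnowledgeGraph,
    is_missing,
)


class EngineMismatchError(ValueError):
    """Joining graphs whose engines point at different stores is undefined."""


class CycleError(ValueError):
    """Transitive reduction requires an acyclic predicate subgraph."""


# --- join ---------------------------------------------------------------------


def _merge_tables(
    left: pd.DataFrame, right: pd.DataFrame, key: list[str]
) -> pd.DataFrame:
    columns = list(left.columns) + [c for c in right.columns if c not in left.columns]
    right_by_key = {}
    for row in right.to_dict("records"):
        right_by_key[tuple(row[k] for k in key)] = row
    records = []
    seen = set()
    for row in left.to_dict("records"):
        k = tuple(row[c] for c in key)
        seen.add(k)
        other = right_by_key.get(k)
        rec = {}
        for c in columns:
            v = row.get(c)
            if is_missing(v) and other is not None:
                v = other.get(c)
            rec[c] = None if is_missing(v) else v
        records.append(rec)
    for row in right.to_dict("records"):
        k = tuple(row[c] for c in key)
        if k in seen:
            continue
        records.append({c: None if is_missing(row.get(c)) else row.get(c) for c in columns})
    if not records:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    return pd.DataFrame(records, columns=columns, dtype=object)


def kg_join(a: KnowledgeGraph, b: KnowledgeGraph) -> KnowledgeGraph:
    """Union of two graphs from the same KG.

    Node rows are merged by id and edge rows by (subject, predicate, object);
    where both operands carry a value for the same attribute the left one
    wins, and values missing on the left are filled from the right. The
    result keeps ``a``'s engine handle (or ``b``'s if ``a`` has none).

    Raises :class:`EngineMismatchError` when both graphs carry engines over
    different sources.
    """
    if a.engine is not None and b.engine is not None:
        if not a.engine.same_source(b.engine):
            raise EngineMismatchError(
                f"cannot join graphs from different stores: "
                f"{a.engine.source!r} vs {b.engine.source!r}"
            )
    nodes = _merge_tables(a.nodes, b.nodes, ["id"])
    edges = _merge_tables(a.edges, b.edges, list(EDGE_REQUIRED_COLUMNS))
    return KnowledgeGraph(nodes, edges, a.engine or b.engine)


# --- rollup / transfer --------------------------------------------------------


def _collect(values: list) -> list:
    return list(values)


def _distinct_union(values: list) -> list:
    return sorted(set(values), key=str)


def _min_or_none(values: list):
    return min(values) if values else None


def _max_or_none(values: list):
    return max(values) if values else None


def _string_join(values: list) -> str:
    return "|".join(str(v) for v in values)


#: Named aggregators shipped with :func:`rollup`; all are total over the
#: empty collection. User callables are accepted anywhere a name is.
AGGREGATORS: dict[str, Callable[[list], object]] = {
    "collect": _collect,
    "distinct": _distinct_union,
    "count": len,
    "sum": sum,
    "min": _min_or_none,
    "max": _max_or_none,
    "string_join": _string_join,
}


@dataclass(frozen=True)
class RollupSpec:
    """How to roll an attribute up/down one predicate's reachability."""

    source: str
    predicate: str
    direction: str = "in"
    aggregator: Union[str, Callable[[list], object]] = "collect"
    include_self: bool = True
    target: Optional[str] = None

    def __post_init__(self):
        if self.direction not in ("in", "out"):
            raise ValueError(f"direction must be 'in' or 'out', got {self.direction!r}")
        if isinstance(self.aggregator, str) and self.aggregator not in AGGREGATORS:
            raise ValueError(
                f"unknown aggregator {self.aggregator!r}; "
                f"known: {sorted(AGGREGATORS)} (or pass a callable)"
            )

    @property
    def target_name(self) -> str:
        return self.target or f"{self.source}_rollup"

    @property
    def func(self) -> Callable[[list], object]:
        if callable(self.aggregator):
            return self.aggregator
        return AGGREGATORS[self.aggregator]


def _predicate_digraph(g: KnowledgeGraph, predicate: str) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(g.nodes["id"])
    if len(g.edges):
        for s, p, o in zip(g.edges["subject"], g.edges["predicate"], g.edges["object"]):
            if p == predicate:
                G.add_edge(s, o)
    return G


def _gather_values(values_by_id: dict, ids: list[str]) -> list:
    out = []
    for nid in ids:
        v = values_by_id.get(nid)
        if is_missing(v):
            continue
        if isinstance(v, (list, tuple)):
            out.extend(v)
        else:
            out.append(v)
    return out


def rollup(
    g: KnowledgeGraph,
    spec: Optional[RollupSpec] = None,
    *,
    source: Optional[str] = None,
    predicate: Optional[str] = None,
    direction: str = "in",
    aggregator: Union[str, Callable[[list], object]] = "collect",
    include_self: bool = True,
    target: Optional[str] = None,
) -> KnowledgeGraph:
    """Aggregate an attribute over each node's transitive neighborhood.

    For every node, the ``source`` attribute values of all nodes transitively
    reachable along ``predicate`` edges in ``direction`` (``"in"`` walks
    edges backwards, so on child→parent subclass edges it gathers
    descendants) — plus the node's own value when ``include_self`` — are fed
    to the aggregator and stored under the target attribute. Topology is
    unchanged. Nodes lacking the source attribute contribute nothing;
    multi-valued cells contribute each element.
    """
    if spec is None:
        if source is None or predicate is None:
            raise ValueError("rollup needs source and predicate (or a RollupSpec)")
        spec = RollupSpec(source, predicate, direction, aggregator, include_self, target)
    G = _predicate_digraph(g, spec.predicate)
    values_by_id = (
        dict(zip(g.nodes["id"], g.nodes[spec.source]))
        if spec.source in g.nodes.columns
        else {}
    )
    row_order = {nid: i for i, nid in enumerate(g.nodes["id"])}
    results = []
    for nid in g.nodes["id"]:
        related = nx.ancestors(G, nid) if spec.direction == "in" else nx.descendants(G, nid)
        ids = sorted(related, key=row_order.get)
        if spec.include_self:
            ids = [nid] + [x for x in ids if x != nid]
        results.append(spec.func(_gather_values(values_by_id, ids)))
    out = g.copy()
    out.nodes[spec.target_name] = pd.Series(results, dtype=object)
    return out


def transfer(
    g: KnowledgeGraph,
    attribute: str,
    predicate: str,
    direction: str = "in",
    target: Optional[str] = None,
) -> KnowledgeGraph:
    """Copy an attribute from immediate neighbors over one predicate.

    Each node's target attribute becomes the ordered list of the source
    attribute's values on nodes one matching edge away in ``direction``
    (``"in"``: the subjects of edges pointing at the node). Nodes with no
    such neighbors get an empty list; topology is unchanged.
    """
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    target = target or f"{attribute}_transferred"
    neighbors: dict[str, list[str]] = {nid: [] for nid in g.nodes["id"]}
    if len(g.edges):
        for s, p, o in zip(g.edges["subject"], g.edges["predicate"], g.edges["object"]):
            if p != predicate:
                continue
            if direction == "in":
                neighbors[o].append(s)
            else:
                neighbors[s].append(o)
    values_by_id = (
        dict(zip(g.nodes["id"], g.nodes[attribute]))
        if attribute in g.nodes.columns
        else {}
    )
    results = [
        _gather_values(values_by_id, neighbors[nid]) for nid in g.nodes["id"]
    ]
    out = g.copy()
    out.nodes[target] = pd.Series(results, dtype=object)
    return out


# --- transitive closure / reduction -------------------------------------------


def transitive_closure(g: KnowledgeGraph, predicate: str) -> KnowledgeGraph:
    """Add (a, predicate, c) for every predicate-path a→…→c.

    Edges of other predicates are untouched; added edges carry nothing beyond
    the triple, and where a closure edge already exists the original (with
    its attributes) is kept. Idempotent, and monotone: the input's edges are
    all retained. On a cyclic predicate subgraph the closure may include
    self-loops.
    """
    G = _predicate_digraph(g, predicate)
    closure = nx.transitive_closure(G, reflexive=False)
    existing = set(g.edge_triples())
    new_triples = sorted(
        (a, predicate, c)
        for a, c in closure.edges()
        if (a, predicate, c) not in existing
    )
    if not new_triples:
        return g.copy()
    add = pd.DataFrame(new_triples, columns=list(EDGE_REQUIRED_COLUMNS), dtype=object)
    for col in g.edges.columns:
        if col not in add.columns:
            add[col] = None
    edges = pd.concat([g.edges, add[list(g.edges.columns)]], ignore_index=True).astype(object)
    edges = edges.where(pd.notna(edges), None)
    return KnowledgeGraph(g.nodes.copy(), edges, g.engine)


def transitive_reduction(g: KnowledgeGraph, predicate: str) -> KnowledgeGraph:
    """Remove predicate edges implied by longer predicate-paths.

    Produces the unique minimal edge set with the same reachability (the
    predicate subgraph must be a DAG). Other predicates are untouched; kept
    edges keep their attributes.

    Raises :class:`CycleError` (naming a member node) when the
    predicate-labeled subgraph contains a cycle.
    """
    G = _predicate_digraph(g, predicate)
    if not nx.is_directed_acyclic_graph(G):
        cycle = nx.find_cycle(G)
        raise CycleError(
            f"predicate {predicate!r} subgraph is cyclic "
            f"(e.g. through node {cycle[0][0]!r}); reduction is undefined"
        )
    reduced = nx.transitive_reduction(G)
    keep_pairs = set(reduced.edges())
    if not len(g.edges):
        return g.copy()
    mask = [
        p != predicate or (s, o) in keep_pairs
        for s, p, o in zip(g.edges["subject"], g.edges["predicate"], g.edges["object"])
    ]
    return KnowledgeGraph(g.nodes.copy(), g.edges.loc[mask].reset_index(drop=True), g.engine)
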