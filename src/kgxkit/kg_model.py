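"""Core knowledge-graph data model.

A knowledge graph here is a labeled-property graph in the KGX sense: a node
table and an edge table, both carried as pandas DataFrames with plain Python
objects in the cells (strings, numbers, booleans, or ordered lists of strings
for multi-valued attributes; ``None`` marks an absent attribute).

Nodes require a ``id`` (CURIE string) and a nonempty, ordered, multi-valued
``category``; a single *primary category* (``pcategory``) is derived from the
category list via an ordered preference list. Edges require single-valued
``subject``, ``predicate`` and ``object`` CURIEs and are identified by that
triple. A graph may carry a handle to the engine that produced it, which
later expansions use to pull more of the backing store.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .file_engine import FileEngine
    from .query import QueryExpr

NODE_REQUIRED_COLUMNS = ("id", "category")
EDGE_REQUIRED_COLUMNS = ("subject", "predicate", "object")

SUBCLASS_OF = "biolink:subclass_of"

#: Default primary-category preference order, highest priority first.
#: Designed for Biolink-compatible graphs: the specific clinically-oriented
#: categories (disease, phenotype, gene, variant) outrank generic ones such
#: as biolink:BiologicalEntity or biolink:NamedThing, which typically appear
#: alongside them in multi-valued category lists. Fully overridable at engine
#: construction.
DEFAULT_PREFERENCES: tuple[str, ...] = (
    "biolink:Disease",
    "biolink:PhenotypicFeature",
    "biolink:Gene",
    "biolink:SequenceVariant",
    "biolink:Protein",
    "biolink:ChemicalEntity",
    "biolink:Drug",
    "biolink:MolecularActivity",
    "biolink:BiologicalProcess",
    "biolink:Pathway",
    "biolink:AnatomicalEntity",
    "biolink:Cell",
    "biolink:CellularComponent",
    "biolink:OrganismTaxon",
    "biolink:Publication",
)


class InvalidNodeError(ValueError):
    """A node record violates the model invariants (e.g. empty category)."""


def is_missing(value) -> bool:
    """True when a cell holds no value (None or scalar NaN; lists never)."""
    if isinstance(value, (list, tuple)):
        return False
    return value is None or (pd.api.types.is_scalar(value) and pd.isna(value))


def empty_nodes_frame(columns: Sequence[str] = ()) -> pd.DataFrame:
    cols = list(NODE_REQUIRED_COLUMNS) + ["pcategory"]
    for c in columns:
        if c not in cols:
            cols.append(c)
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def empty_edges_frame(columns: Sequence[str] = ()) -> pd.DataFrame:
    cols = list(EDGE_REQUIRED_COLUMNS)
    for c in columns:
        if c not in cols:
            cols.append(c)
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def resolve_pcategory(
    categories: Sequence[str],
    prefs: Sequence[str] = DEFAULT_PREFERENCES,
) -> str:
    """Pick the primary category for a node.

    Returns the highest-priority entry of ``prefs`` that occurs in
    ``categories``. When no preference matches, falls back to the first
    category in stored order, so the result is deterministic and always an
    element of ``categories``.

    Raises
    ------
    InvalidNodeError
        If ``categories`` is empty.
    """
    if categories is None or len(categories) == 0:
        raise InvalidNodeError("node has an empty category list")
    catset = set(categories)
    for pref in prefs:
        if pref in catset:
            return pref
    return categories[0]


@dataclass
class KnowledgeGraph:
    """A local, in-memory knowledge graph.

    Attributes
    ----------
    nodes : pandas.DataFrame
        One row per node; columns ``id``, ``category`` (list of CURIEs),
        ``pcategory`` plus any number of open attribute columns.
    edges : pandas.DataFrame
        One row per directed edge; columns ``subject``, ``predicate``,
        ``object`` plus open attribute columns.
    engine : FileEngine or None
        Handle to the engine that produced this graph, if any. Expansion
        operations require it; pure algebra does not.
    """

    nodes: pd.DataFrame = field(default_factory=empty_nodes_frame)
    edges: pd.DataFrame = field(default_factory=empty_edges_frame)
    engine: Optional["FileEngine"] = None

    @classmethod
    def empty(cls, engine: Optional["FileEngine"] = None) -> "KnowledgeGraph":
        return cls(empty_nodes_frame(), empty_edges_frame(), engine)

    def node_ids(self) -> list[str]:
        return list(self.nodes["id"]) if len(self.nodes) else []

    def edge_triples(self) -> list[tuple[str, str, str]]:
        if not len(self.edges):
            return []
        return list(
            zip(self.edges["subject"], self.edges["predicate"], self.edges["object"])
        )

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(self.nodes.copy(), self.edges.copy(), self.engine)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<KnowledgeGraph {len(self.nodes)} nodes, {len(self.edges)} edges"
            + (f", engine={self.engine.source!r}>" if self.engine else ">")
        )


def validate_graph(g: KnowledgeGraph) -> list[str]:
    """Check all KnowledgeGraph invariants; return violation descriptions.

    Reports rather than raises: an empty list means the graph is valid. Each
    violation names the offending node id or edge triple.
    """
    violations: list[str] = []
    nodes, edges = g.nodes, g.edges

    for col in NODE_REQUIRED_COLUMNS:
        if col not in nodes.columns:
            violations.append(f"node table missing required column {col!r}")
    for col in EDGE_REQUIRED_COLUMNS:
        if col not in edges.columns:
            violations.append(f"edge table missing required column {col!r}")
    if violations:
        return violations

    ids = list(nodes["id"])
    seen: set[str] = set()
    for nid in ids:
        if is_missing(nid) or nid == "":
            violations.append("node with empty or missing id")
        elif nid in seen:
            violations.append(f"duplicate node id {nid!r}")
        seen.add(nid)

    for nid, cats in zip(ids, nodes["category"]):
        if not isinstance(cats, (list, tuple)) or len(cats) == 0:
            violations.append(f"node {nid!r} has an empty or non-list category")
    if "pcategory" in nodes.columns:
        for nid, cats, pcat in zip(ids, nodes["category"], nodes["pcategory"]):
            if isinstance(cats, (list, tuple)) and len(cats) and pcat not in cats:
                violations.append(
                    f"node {nid!r} pcategory {pcat!r} not among its categories"
                )

    id_set = set(ids)
    seen_triples: set[tuple] = set()
    for s, p, o in zip(edges["subject"], edges["predicate"], edges["object"]):
        for part, label in ((s, "subject"), (p, "predicate"), (o, "object")):
            if is_missing(part) or part == "":
                violations.append(f"edge ({s!r},{p!r},{o!r}) has empty {label}")
        triple = (s, p, o)
        if triple in seen_triples:
            violations.append(f"duplicate edge triple {triple!r}")
        seen_triples.add(triple)
        if s not in id_set:
            violations.append(f"edge {triple!r} has dangling subject {s!r}")
        if o not in id_set:
            violations.append(f"edge {triple!r} has dangling object {o!r}")
    return violations


def filter_nodes(g: KnowledgeGraph, expr: "QueryExpr") -> KnowledgeGraph:
    """Restrict a graph to the nodes satisfying a query expression.

    Edges with either endpoint removed are dropped, so the result is always a
    valid graph. The engine handle is preserved. Attributes the expression
    references but the table lacks simply never match (no error), and the
    operation is idempotent.
    """
    if not len(g.nodes):
        return g.copy()
    mask = [expr.evaluate(row) for row in g.nodes.to_dict("records")]
    nodes = g.nodes.loc[mask].reset_index(drop=True)
    kept = set(nodes["id"])
    if len(g.edges):
        emask = [
            (s in kept) and (o in kept)
            for s, o in zip(g.edges["subject"], g.edges["object"])
        ]
        edges = g.edges.loc[emask].reset_index(drop=True)
    else:
        edges = g.edges.copy()
    return KnowledgeGraph(nodes, edges, g.engine)


def _normalize_cell(v):
    if is_missing(v):
        return None
    if isinstance(v, (list, tuple)):
        return tuple(str(x) for x in v)
    if isinstance(v, bool):
        return ("bool", v)
    if isinstance(v, float) and float(v).is_integer():
        return ("num", int(v))
    if isinstance(v, int):
        return ("num", int(v))
    if isinstance(v, float):
        return ("num", v)
    return v


def _normalized_records(df: pd.DataFrame, key: Sequence[str]) -> list[tuple]:
    # drop all-null columns: an attribute no row carries is indistinguishable
    # from one that was never present
    cols = [
        c
        for c in df.columns
        if c not in key and any(not is_missing(v) for v in df[c])
    ]
    cols = list(key) + sorted(cols)
    records = []
    for row in df.to_dict("records"):
        records.append(tuple((c, _normalize_cell(row.get(c))) for c in cols))
    records.sort(key=repr)
    return records


def graphs_equal(a: KnowledgeGraph, b: KnowledgeGraph) -> bool:
    """Order-insensitive equality of node and edge tables.

    Rows are compared as attribute sets keyed by node id / edge triple;
    row order, column order, derived ``pcategory`` values and columns that
    hold no values at all are ignored. Integer-valued floats compare equal to
    ints (a round trip through text may not preserve that distinction).
    """
    an = a.nodes.drop(columns=["pcategory"], errors="ignore")
    bn = b.nodes.drop(columns=["pcategory"], errors="ignore")
    if _normalized_records(an, ["id"]) != _normalized_records(bn, ["id"]):
        return False
    key = list(EDGE_REQUIRED_COLUMNS)
    return _normalized_records(a.edges, key) == _normalized_records(b.edges, key)
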