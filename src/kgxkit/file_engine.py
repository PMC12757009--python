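"""File-backed knowledge-graph engine.

An engine mediates all access to a backing KG store. The file engine loads a
whole KGX-TSV tar.gz archive into memory at construction and then serves

* :meth:`FileEngine.fetch_nodes` — an initial node set (no edges), selected
  by id list or by a :class:`~kgxkit.query.QueryExpr` over node attributes;
* :meth:`FileEngine.summarize` — counts per category / primary category /
  predicate plus the available node and edge attribute names;
* :meth:`FileEngine.example_graph` — a small deterministic subgraph
  guaranteed to exhibit every node category and edge predicate in the store.

Graphs returned by an engine carry a handle back to it, so neighborhood
expansion (:mod:`kgxkit.expansion`) can keep pulling from the same store.
The engine contract (these three methods plus the adjacency accessors used by
expansion) is deliberately small so that database-backed engines could
implement it later.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .kg_model import (
    DEFAULT_PREFERENCES,
    EDGE_REQUIRED_COLUMNS,
    NODE_REQUIRED_COLUMNS,
    KnowledgeGraph,
    empty_edges_frame,
    resolve_pcategory,
)
from .kgx_io import read_kgx
from .query import (  # noqa: F401  (re-exported engine query surface)
    And,
    Equals,
    InList,
    Matches,
    Not,
    Or,
    QueryError,
    QueryExpr,
    QuerySyntaxError,
    parse_expr,
)

logger = logging.getLogger(__name__)


@dataclass
class EngineSummary:
    """Census of a store: counts and available attribute names.

    ``category_counts`` tallies a node once per category entry (a node with
    three categories contributes three counts); ``pcategory_counts`` tallies
    each node exactly once, so those counts sum to ``n_nodes``.
    """

    n_nodes: int
    n_edges: int
    category_counts: dict[str, int]
    pcategory_counts: dict[str, int]
    predicate_counts: dict[str, int]
    node_attributes: list[str]
    edge_attributes: list[str]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "category_counts": dict(sorted(self.category_counts.items())),
            "pcategory_counts": dict(sorted(self.pcategory_counts.items())),
            "predicate_counts": dict(sorted(self.predicate_counts.items())),
            "node_attributes": list(self.node_attributes),
            "edge_attributes": list(self.edge_attributes),
        }

    def __str__(self) -> str:
        lines = [f"Nodes: {self.n_nodes}", f"Edges: {self.n_edges}", "", "Node categories (pcategory / total):"]
        for cat in sorted(set(self.category_counts) | set(self.pcategory_counts)):
            lines.append(
                f"  {cat}: {self.pcategory_counts.get(cat, 0)} / {self.category_counts.get(cat, 0)}"
            )
        lines.append("Edge predicates:")
        for pred, n in sorted(self.predicate_counts.items()):
            lines.append(f"  {pred}: {n}")
        lines.append("Node attributes: " + ", ".join(self.node_attributes))
        lines.append("Edge attributes: " + ", ".join(self.edge_attributes))
        return "\n".join(lines)


class FileEngine:
    """Queryable engine over a loaded KGX archive.

    Parameters
    ----------
    path : str or path-like
        KGX-TSV tar.gz archive to load.
    prefs : sequence of category CURIEs, optional
        Primary-category preference order, highest priority first; defaults
        to :data:`~kgxkit.kg_model.DEFAULT_PREFERENCES`.
    """

    def __init__(self, path, prefs: Optional[Sequence[str]] = None):
        self.prefs: tuple[str, ...] = tuple(prefs) if prefs else DEFAULT_PREFERENCES
        if len(set(self.prefs)) != len(self.prefs):
            raise ValueError("preference list contains duplicate entries")
        self.source = str(path)
        self.store = read_kgx(path, prefs=self.prefs)
        self._indexes = None

    @classmethod
    def from_graph(
        cls,
        graph: KnowledgeGraph,
        prefs: Optional[Sequence[str]] = None,
        source: str = "<memory>",
    ) -> "FileEngine":
        """Build an engine directly from an in-memory graph (no archive).

        The graph's ``pcategory`` column is (re)computed with the engine's
        preferences. Mainly useful for tests and programmatic pipelines.
        """
        eng = cls.__new__(cls)
        eng.prefs = tuple(prefs) if prefs else DEFAULT_PREFERENCES
        if len(set(eng.prefs)) != len(eng.prefs):
            raise ValueError("preference list contains duplicate entries")
        eng.source = source
        store = KnowledgeGraph(graph.nodes.copy(), graph.edges.copy(), None)
        pcats = [resolve_pcategory(c, eng.prefs) for c in store.nodes["category"]]
        store.nodes = store.nodes.drop(columns=["pcategory"], errors="ignore")
        store.nodes.insert(
            store.nodes.columns.get_loc("category") + 1,
            "pcategory",
            pd.Series(pcats, dtype=object),
        )
        eng.store = store
        eng._indexes = None
        return eng

    def same_source(self, other: "FileEngine") -> bool:
        return self is other or self.source == other.source

    # -- adjacency indexes used by expansion --------------------------------

    def _ensure_indexes(self):
        if self._indexes is not None:
            return self._indexes
        out_idx: dict[str, list[int]] = defaultdict(list)
        in_idx: dict[str, list[int]] = defaultdict(list)
        edges = self.store.edges
        for i, (s, o) in enumerate(zip(edges["subject"], edges["object"])):
            out_idx[s].append(i)
            in_idx[o].append(i)
        categories = dict(zip(self.store.nodes["id"], self.store.nodes["category"]))
        self._indexes = (dict(out_idx), dict(in_idx), categories)
        return self._indexes

    # -- queries --------------------------------------------------------------

    def fetch_nodes(
        self, query: Union[Iterable[str], QueryExpr, None] = None
    ) -> KnowledgeGraph:
        """Fetch an initial set of nodes (but no edges) as a local graph.

        ``query`` is either a collection of node ids or a
        :class:`QueryExpr`. Requested ids absent from the store are silently
        omitted (with a warning naming them); duplicates are collapsed and
        store order is preserved. The result carries this engine.
        """
        nodes = self.store.nodes
        if isinstance(query, QueryExpr):
            mask = [query.evaluate(row) for row in nodes.to_dict("records")]
            selected = nodes.loc[mask]
        elif query is None:
            selected = nodes.iloc[0:0]
        else:
            wanted = list(dict.fromkeys(query))
            present = set(nodes["id"])
            missing = [w for w in wanted if w not in present]
            if missing:
                logger.warning("requested ids not in store: %s", missing)
            wset = set(wanted)
            selected = nodes.loc[[nid in wset for nid in nodes["id"]]]
        return KnowledgeGraph(
            selected.reset_index(drop=True).copy(),
            empty_edges_frame(),
            engine=self,
        )

    def summarize(self) -> EngineSummary:
        """Census of the store (see :class:`EngineSummary`)."""
        nodes, edges = self.store.nodes, self.store.edges
        category_counts: dict[str, int] = {}
        pcategory_counts: dict[str, int] = {}
        for cats in nodes["category"]:
            for c in cats:
                category_counts[c] = category_counts.get(c, 0) + 1
        for p in nodes["pcategory"]:
            pcategory_counts[p] = pcategory_counts.get(p, 0) + 1
        predicate_counts: dict[str, int] = {}
        for p in edges["predicate"]:
            predicate_counts[p] = predicate_counts.get(p, 0) + 1
        node_attrs = sorted(
            c for c in nodes.columns if c not in NODE_REQUIRED_COLUMNS and c != "pcategory"
        )
        edge_attrs = sorted(c for c in edges.columns if c not in EDGE_REQUIRED_COLUMNS)
        return EngineSummary(
            n_nodes=len(nodes),
            n_edges=len(edges),
            category_counts=category_counts,
            pcategory_counts=pcategory_counts,
            predicate_counts=predicate_counts,
            node_attributes=node_attrs,
            edge_attributes=edge_attrs,
        )

    def example_graph(self) -> KnowledgeGraph:
        """Deterministic sample covering every category and predicate.

        A uniform random sample of a heterogeneous store is unlikely to show
        its diversity, so instead: for each predicate the lexicographically
        smallest (subject, predicate, object) edge is taken together with its
        endpoints; then for each category not yet represented, the smallest
        node id carrying it. Running twice yields identical output.
        """
        nodes, edges = self.store.nodes, self.store.edges
        chosen_edges: list[tuple[str, str, str]] = []
        if len(edges):
            best: dict[str, tuple[str, str, str]] = {}
            for s, p, o in zip(edges["subject"], edges["predicate"], edges["object"]):
                t = (s, p, o)
                if p not in best or t < best[p]:
                    best[p] = t
            chosen_edges = [best[p] for p in sorted(best)]
        node_ids = []
        for s, _, o in chosen_edges:
            for nid in (s, o):
                if nid not in node_ids:
                    node_ids.append(nid)
        covered: set[str] = set()
        cat_lookup = dict(zip(nodes["id"], nodes["category"]))
        for nid in node_ids:
            covered.update(cat_lookup[nid])
        uncovered = set()
        for cats in nodes["category"]:
            uncovered.update(set(cats) - covered)
        for cat in sorted(uncovered):
            if cat in covered:
                continue
            candidates = sorted(
                nid for nid, cats in cat_lookup.items() if cat in cats
            )
            pick = candidates[0]
            if pick not in node_ids:
                node_ids.append(pick)
            covered.update(cat_lookup[pick])

        idset = set(node_ids)
        out_nodes = nodes.loc[[nid in idset for nid in nodes["id"]]].reset_index(drop=True)
        tset = set(chosen_edges)
        if len(edges):
            emask = [
                (s, p, o) in tset
                for s, p, o in zip(edges["subject"], edges["predicate"], edges["object"])
            ]
            out_edges = edges.loc[emask].reset_index(drop=True)
        else:
            out_edges = edges.copy().reset_index(drop=True)
        return KnowledgeGraph(out_nodes.copy(), out_edges.copy(), engine=self)


def create_file_engine(path, prefs: Optional[Sequence[str]] = None) -> FileEngine:
    """Open a KGX-TSV tar.gz archive as a queryable :class:`FileEngine`."""
    return FileEngine(path, prefs=prefs)


def fetch_nodes(engine: FileEngine, query) -> KnowledgeGraph:
    return engine.fetch_nodes(query)


def summarize(engine: FileEngine) -> EngineSummary:
    return engine.summarize()


def example_graph(engine: FileEngine) -> KnowledgeGraph:
    return engine.example_graph()
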