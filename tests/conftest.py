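"""Shared fixtures and independent oracles.

The oracle helpers here deliberately avoid the package's own code paths (and
networkx, which the implementation uses for closure/reduction): reachability
is a plain dict-based DFS, transitive closure a numpy boolean-matrix power
loop, and query evaluation a stand-alone recursive interpreter of the
documented semantics.
"""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pytest

from kgxkit import (
    FileEngine,
    GeneratorSpec,
    KnowledgeGraph,
    generate_kg,
    resolve_pcategory,
    write_fixture,
)
from kgxkit.kg_model import empty_edges_frame


def make_graph(node_defs, edge_defs=(), engine=None, prefs=None) -> KnowledgeGraph:
    """Build a KnowledgeGraph from terse node/edge dicts.

    ``node_defs``: dicts with at least ``id``; ``category`` defaults to
    ``["x:Thing"]``. ``edge_defs``: dicts with subject/predicate/object.
    """
    nrows = []
    for nd in node_defs:
        row = dict(nd)
        row.setdefault("category", ["x:Thing"])
        row["pcategory"] = resolve_pcategory(row["category"], prefs or ())
        nrows.append(row)
    nodes = pd.DataFrame(nrows, dtype=object)
    nodes = nodes.where(pd.notna(nodes), None)
    if edge_defs:
        edges = pd.DataFrame([dict(e) for e in edge_defs], dtype=object)
        edges = edges.where(pd.notna(edges), None)
    else:
        edges = empty_edges_frame()
    return KnowledgeGraph(nodes, edges, engine)


def engine_for(g: KnowledgeGraph, source="<memory>", prefs=None) -> FileEngine:
    return FileEngine.from_graph(g, source=source, prefs=prefs)


def random_dag(rng: random.Random, n_nodes: int, predicate="biolink:subclass_of",
               p_extra=0.2):
    """Random DAG as (graph, child->parents adjacency); edges child→parent."""
    ids = [f"D:{i:04d}" for i in range(n_nodes)]
    parents: dict[str, list[str]] = {nid: [] for nid in ids}
    edges = []
    for i in range(1, n_nodes):
        parent = ids[rng.randrange(i)]
        parents[ids[i]].append(parent)
        edges.append({"subject": ids[i], "predicate": predicate, "object": parent})
        if i > 1 and rng.random() < p_extra:
            extra = ids[rng.randrange(i)]
            if extra not in parents[ids[i]]:
                parents[ids[i]].append(extra)
                edges.append({"subject": ids[i], "predicate": predicate, "object": extra})
    g = make_graph([{"id": nid} for nid in ids], edges)
    return g, parents


def random_digraph(rng: random.Random, n_nodes: int, p_edge=0.12,
                   predicate="x:links"):
    """Random digraph (cycles allowed), no self loops."""
    ids = [f"N:{i:03d}" for i in range(n_nodes)]
    edges = []
    for a in ids:
        for b in ids:
            if a != b and rng.random() < p_edge:
                edges.append({"subject": a, "predicate": predicate, "object": b})
    return make_graph([{"id": nid} for nid in ids], edges)


# --- independent oracles -----------------------------------------------------


def dfs_reachable(adjacency: dict, start: str, include_start=True) -> set:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in adjacency.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if not include_start:
        seen.discard(start)
    return seen


def edge_adjacency(g: KnowledgeGraph, predicate=None, reverse=False) -> dict:
    adj: dict[str, list[str]] = {}
    for s, p, o in g.edge_triples():
        if predicate is not None and p != predicate:
            continue
        if reverse:
            s, o = o, s
        adj.setdefault(s, []).append(o)
    return adj


def matrix_closure_pairs(g: KnowledgeGraph, predicate: str) -> set:
    """Transitive-closure pairs by boolean matrix powering (numpy)."""
    ids = g.node_ids()
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=bool)
    for s, p, o in g.edge_triples():
        if p == predicate:
            A[index[s], index[o]] = True
    reach = A.copy()
    for _ in range(n):
        new = reach | (reach @ A)
        if (new == reach).all():
            break
        reach = new
    return {(ids[i], ids[j]) for i, j in zip(*np.nonzero(reach))}


def naive_eval(expr, row: dict) -> bool:
    """Stand-alone interpreter of the query semantics (test oracle)."""
    from kgxkit import And, Equals, InList, Matches, Not, Or
    import re as _re

    def missing(v):
        return v is None or (not isinstance(v, (list, tuple)) and pd.isna(v))

    if isinstance(expr, And):
        return all(naive_eval(c, row) for c in expr.clauses)
    if isinstance(expr, Or):
        return any(naive_eval(c, row) for c in expr.clauses)
    if isinstance(expr, Not):
        return not naive_eval(expr.clause, row)
    if isinstance(expr, Equals):
        v = row.get(expr.attribute)
        if missing(v) or isinstance(v, (list, tuple)):
            return False
        if isinstance(v, bool) or isinstance(expr.value, bool):
            return v is expr.value
        return v == expr.value
    if isinstance(expr, Matches):
        v = row.get(expr.attribute)
        if missing(v):
            return False
        items = v if isinstance(v, (list, tuple)) else [v]
        return any(_re.search(expr.pattern, str(x)) for x in items)
    if isinstance(expr, InList):
        v = row.get(expr.attribute)
        if missing(v):
            return False
        items = v if isinstance(v, (list, tuple)) else [v]
        return expr.value in items
    raise TypeError(expr)


# --- session fixtures --------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_archive(tmp_path_factory):
    path = tmp_path_factory.mktemp("kgx") / "fixture.tar.gz"
    write_fixture(GeneratorSpec(seed=11), path)
    return path


@pytest.fixture(scope="session")
def fixture_engine(fixture_archive):
    return FileEngine(fixture_archive)


@pytest.fixture(scope="session")
def generated():
    return generate_kg(GeneratorSpec(seed=11))
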