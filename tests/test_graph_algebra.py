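"""Graph algebra: join laws, rollups, transfer, closure and reduction."""

import random

import pytest

from kgxkit import (
    CycleError,
    EngineMismatchError,
    RollupSpec,
    graphs_equal,
    kg_join,
    rollup,
    transfer,
    transitive_closure,
    transitive_reduction,
    validate_graph,
)
from kgxkit.kg_model import SUBCLASS_OF, KnowledgeGraph

from conftest import (
    dfs_reachable,
    edge_adjacency,
    engine_for,
    make_graph,
    matrix_closure_pairs,
    random_dag,
    random_digraph,
)


class TestKgJoin:
    def test_idempotent(self, generated):
        g = generated.graph
        assert graphs_equal(kg_join(g, g), g)

    def test_empty_identity(self, generated):
        g = generated.graph
        assert graphs_equal(kg_join(g, KnowledgeGraph.empty()), g)
        assert graphs_equal(kg_join(KnowledgeGraph.empty(), g), g)

    def test_union_matches_set_oracle_and_is_commutative(self):
        rng = random.Random(3)
        for _ in range(20):
            a = random_digraph(rng, rng.randint(2, 25), p_edge=0.15)
            b = random_digraph(rng, rng.randint(2, 25), p_edge=0.15)
            ab = kg_join(a, b)
            ba = kg_join(b, a)
            expected_nodes = set(a.node_ids()) | set(b.node_ids())
            expected_edges = set(a.edge_triples()) | set(b.edge_triples())
            for j in (ab, ba):
                assert set(j.node_ids()) == expected_nodes
                assert set(j.edge_triples()) == expected_edges
                assert validate_graph(j) == []

    def test_overlapping_expansions_union_once(self, fixture_engine, generated):
        """Two expansion routes meeting at shared variant nodes join cleanly."""
        from kgxkit import descendants, expand

        noonans = descendants(
            fixture_engine.fetch_nodes(generated.census.replay["root"])
        )
        direct = expand(noonans, categories=("biolink:SequenceVariant",))
        via_genes = expand(
            expand(noonans, categories=("biolink:Gene",)),
            predicates=("biolink:is_sequence_variant_of",),
        )
        joined = kg_join(direct, via_genes)
        assert set(joined.node_ids()) == set(direct.node_ids()) | set(via_genes.node_ids())
        assert len(joined.nodes) == len(set(joined.node_ids()))  # no duplicates
        assert joined.engine is fixture_engine

    def test_left_preferential_attribute_merge(self):
        a = make_graph([{"id": "x:1", "name": "left", "only_a": 1}])
        b = make_graph([{"id": "x:1", "name": "right", "only_b": 2}])
        j = kg_join(a, b)
        row = j.nodes.iloc[0]
        assert row["name"] == "left" and row["only_a"] == 1 and row["only_b"] == 2

    def test_engine_source_mismatch_raises(self, tmp_path):
        g1 = make_graph([{"id": "x:1"}])
        a = engine_for(g1, source="store-A").fetch_nodes(["x:1"])
        b = engine_for(g1, source="store-B").fetch_nodes(["x:1"])
        with pytest.raises(EngineMismatchError):
            kg_join(a, b)

    def test_associative_on_sets(self):
        rng = random.Random(9)
        a = random_digraph(rng, 10)
        b = random_digraph(rng, 10)
        c = random_digraph(rng, 10)
        left = kg_join(kg_join(a, b), c)
        right = kg_join(a, kg_join(b, c))
        assert set(left.node_ids()) == set(right.node_ids())
        assert set(left.edge_triples()) == set(right.edge_triples())


class TestRollup:
    def test_leaf_collect_includes_self_only(self):
        g = make_graph([{"id": "a", "v": 7}])
        out = rollup(g, source="v", predicate=SUBCLASS_OF, direction="in",
                     aggregator="collect", target="vals")
        assert out.nodes.loc[0, "vals"] == [7]

    def test_chain_sum(self):
        g = make_graph(
            [{"id": "c1", "v": 1}, {"id": "c2", "v": 1}, {"id": "c3", "v": 1}],
            [
                {"subject": "c2", "predicate": SUBCLASS_OF, "object": "c1"},
                {"subject": "c3", "predicate": SUBCLASS_OF, "object": "c2"},
            ],
        )
        out = rollup(g, source="v", predicate=SUBCLASS_OF, direction="in",
                     aggregator="sum", target="total")
        totals = dict(zip(out.nodes["id"], out.nodes["total"]))
        assert totals == {"c1": 3, "c2": 2, "c3": 1}

    def test_random_dag_sum_matches_reachability_oracle(self):
        rng = random.Random(4)
        for _ in range(15):
            g, _ = random_dag(rng, rng.randint(2, 60))
            g.nodes["v"] = [rng.randint(0, 9) for _ in range(len(g.nodes))]
            out = rollup(g, source="v", predicate=SUBCLASS_OF, direction="in",
                         aggregator="sum", target="total")
            values = dict(zip(g.nodes["id"], g.nodes["v"]))
            children = edge_adjacency(g, SUBCLASS_OF, reverse=True)
            for nid, total in zip(out.nodes["id"], out.nodes["total"]):
                expected = sum(values[x] for x in dfs_reachable(children, nid))
                assert total == expected

    def test_spec_object_and_direction_out(self):
        g = make_graph(
            [{"id": "c1", "v": 5}, {"id": "c2", "v": 2}],
            [{"subject": "c2", "predicate": SUBCLASS_OF, "object": "c1"}],
        )
        spec = RollupSpec("v", SUBCLASS_OF, direction="out", aggregator="collect",
                         include_self=False, target="up")
        out = rollup(g, spec)
        vals = dict(zip(out.nodes["id"], out.nodes["up"]))
        assert vals == {"c1": [], "c2": [5]}

    def test_unknown_aggregator_rejected(self):
        with pytest.raises(ValueError):
            RollupSpec("v", SUBCLASS_OF, aggregator="frobnicate")

    def test_custom_callable_aggregator_and_unchanged_topology(self, generated):
        g = generated.graph
        out = rollup(g, source="name", predicate=SUBCLASS_OF, direction="in",
                     aggregator=lambda vals: len(set(vals)), target="n_names")
        assert len(out.nodes) == len(g.nodes) and len(out.edges) == len(g.edges)
        assert all(isinstance(v, int) for v in out.nodes["n_names"])

    def test_aggregators_total_over_empty(self):
        from kgxkit import AGGREGATORS

        expected = {"collect": [], "distinct": [], "count": 0, "sum": 0,
                    "min": None, "max": None, "string_join": ""}
        for name, func in AGGREGATORS.items():
            assert func([]) == expected[name]


class TestTransfer:
    def test_isolated_node_gets_empty_collection(self):
        g = make_graph([{"id": "a", "name": "A"}])
        out = transfer(g, "name", "x:causes", direction="in", target="genes")
        assert out.nodes.loc[0, "genes"] == []

    def test_disease_collects_causal_gene_names(self):
        g = make_graph(
            [
                {"id": "d", "name": "disease"},
                {"id": "g1", "name": "G1"},
                {"id": "g2", "name": "G2"},
            ],
            [
                {"subject": "g1", "predicate": "x:causes", "object": "d"},
                {"subject": "g2", "predicate": "x:causes", "object": "d"},
            ],
        )
        out = transfer(g, "name", "x:causes", direction="in", target="causal_genes")
        vals = dict(zip(out.nodes["id"], out.nodes["causal_genes"]))
        assert vals["d"] == ["G1", "G2"] and vals["g1"] == []

    def test_bipartite_random_matches_adjacency_scan(self):
        rng = random.Random(6)
        left = [f"L:{i}" for i in range(10)]
        right = [f"R:{i}" for i in range(10)]
        edges = [
            {"subject": l, "predicate": "x:p", "object": r}
            for l in left for r in right if rng.random() < 0.2
        ]
        g = make_graph(
            [{"id": n, "name": n.lower()} for n in left + right], edges
        )
        out = transfer(g, "name", "x:p", direction="out", target="t")
        vals = dict(zip(out.nodes["id"], out.nodes["t"]))
        for n in left + right:
            expected = [o.lower() for e in edges for o in [e["object"]] if e["subject"] == n]
            assert vals[n] == expected


class TestClosure:
    def test_chain_gains_shortcut(self):
        g = make_graph(
            [{"id": "a"}, {"id": "b"}, {"id": "c"}],
            [
                {"subject": "a", "predicate": "x:p", "object": "b"},
                {"subject": "b", "predicate": "x:p", "object": "c"},
            ],
        )
        out = transitive_closure(g, "x:p")
        assert ("a", "x:p", "c") in out.edge_triples()
        assert len(out.edges) == 3

    def test_idempotent_and_monotone(self):
        rng = random.Random(8)
        for _ in range(10):
            g = random_digraph(rng, rng.randint(2, 20))
            once = transitive_closure(g, "x:links")
            twice = transitive_closure(once, "x:links")
            assert set(g.edge_triples()) <= set(once.edge_triples())
            assert set(twice.edge_triples()) == set(once.edge_triples())

    def test_matches_boolean_matrix_oracle(self):
        rng = random.Random(12)
        for _ in range(20):
            g = random_digraph(rng, rng.randint(2, 40))
            out = transitive_closure(g, "x:links")
            got = {(s, o) for s, p, o in out.edge_triples() if p == "x:links"}
            assert got == matrix_closure_pairs(g, "x:links")

    def test_other_predicates_untouched_and_new_edges_bare(self, generated):
        g = generated.graph
        out = transitive_closure(g, SUBCLASS_OF)
        other = lambda kg: {t for t in kg.edge_triples() if t[1] != SUBCLASS_OF}
        assert other(out) == other(g)
        existing = set(g.edge_triples())
        new = out.edges[[t not in existing for t in out.edge_triples()]]
        for col in new.columns:
            if col not in ("subject", "predicate", "object"):
                assert all(v is None for v in new[col])
        assert validate_graph(out) == []


class TestReduction:
    def test_triangle_shortcut_removed(self):
        g = make_graph(
            [{"id": "a"}, {"id": "b"}, {"id": "c"}],
            [
                {"subject": "a", "predicate": "x:p", "object": "b"},
                {"subject": "b", "predicate": "x:p", "object": "c"},
                {"subject": "a", "predicate": "x:p", "object": "c"},
            ],
        )
        out = transitive_reduction(g, "x:p")
        assert set(out.edge_triples()) == {
            ("a", "x:p", "b"), ("b", "x:p", "c")
        }

    def test_chain_already_reduced_is_identity(self):
        g = make_graph(
            [{"id": "a"}, {"id": "b"}],
            [{"subject": "a", "predicate": "x:p", "object": "b"}],
        )
        assert graphs_equal(transitive_reduction(g, "x:p"), g)

    def test_cycle_raises_naming_a_member(self):
        g = make_graph(
            [{"id": "a"}, {"id": "b"}],
            [
                {"subject": "a", "predicate": "x:p", "object": "b"},
                {"subject": "b", "predicate": "x:p", "object": "a"},
            ],
        )
        with pytest.raises(CycleError, match="a|b"):
            transitive_reduction(g, "x:p")

    def test_reduction_subgraph_with_equal_closure(self):
        rng = random.Random(13)
        for _ in range(15):
            g, _ = random_dag(rng, rng.randint(2, 40))
            # add shortcuts so there is something to reduce
            closed = transitive_closure(g, SUBCLASS_OF)
            reduced = transitive_reduction(closed, SUBCLASS_OF)
            assert set(reduced.edge_triples()) <= set(closed.edge_triples())
            assert matrix_closure_pairs(reduced, SUBCLASS_OF) == matrix_closure_pairs(
                closed, SUBCLASS_OF
            )
            again = transitive_reduction(
                transitive_closure(reduced, SUBCLASS_OF), SUBCLASS_OF
            )
            assert set(again.edge_triples()) == set(reduced.edge_triples())
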