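# kgxkit

Query and manipulate biomedical knowledge graphs in the KGX exchange format.

Biomedical knowledge graphs (KGs) link genes, genetic variants, diseases and
phenotypes as a labeled-property graph: nodes carry a CURIE `id` (e.g.
`MONDO:0019391`) and an ordered, multi-valued `category` list from the
Biolink model (e.g. `biolink:BiologicalEntity|biolink:Disease|biolink:NamedThing`),
edges carry single-valued `subject`, `predicate`, `object` CURIEs, and both
carry open attribute sets. The KGX-TSV serialization packs these node/edge
tables into a tar.gz archive. Working with such graphs — "give me every
subtype of this syndrome, the variants and causal genes attached to any of
them, and the phenotypes two levels of generalization above the directly
annotated ones" — takes awkward ad-hoc code with generic graph libraries.
kgxkit provides the KG-specific operations directly, for anyone assembling
entity panels (e.g. PheWAS variant/phenotype sets) from a KGX graph:

* **File engine** — load a KGX-TSV tar.gz and query it: `fetch_nodes` by id
  list or by an attribute expression (equality, regex, list membership,
  boolean connectives), `summarize` (counts per category / primary category /
  predicate, attribute inventories), and `example_graph`, a small
  deterministic sample guaranteed to exhibit *every* category and predicate
  in the store.
* **Primary categories** — KGX allows many categories per node but names no
  primary one; kgxkit derives a `pcategory` per node from an ordered,
  overridable preference list (so the disease node above counts as a
  `biolink:Disease`, not a `biolink:BiologicalEntity`).
* **Expansion** — grow a fetched graph from its backing store along
  predicate/category/direction filters: one step (`expand`), a bounded number
  of steps (`expand_n`), or transitively to a fixed point
  (`expand(..., transitive=True)`, with `descendants()`/`ancestors()`
  shorthands for inward/outward `biolink:subclass_of` walks). Every
  expansion returns a supergraph of its input.
* **Graph algebra** — `kg_join` (union by node id / edge triple, with
  left-preferential attribute merging), `rollup` (aggregate an attribute
  over each node's transitive neighborhood with pluggable aggregators),
  `transfer` (copy attribute values from one-step neighbors, e.g. causal
  gene names onto diseases), `transitive_closure` and `transitive_reduction`
  per predicate.
* **Synthetic fixtures** — a seeded generator of ontology-like KGs (disease
  and phenotype subclass DAGs, genes, variants, cross-category associations)
  with an embedded ground-truth census, so everything is testable offline.
* **CLI** — `kgxkit generate | summary | fetch | expand | join | closure |
  reduce | rollup | transfer | export`, passing graphs between invocations
  as KGX archives (GraphML export for network visualization tools).

## Worked example

Build a seeded synthetic KG, then run the variant/phenotype prioritization
walk for the first disease family: all subtypes of the root syndrome, the
sequence variants attached to any of them either directly or through
associated genes, and the phenotype panel two generalization levels deep.

```python
import kgxkit as kgx

spec = kgx.GeneratorSpec(seed=1)
kgx.write_fixture(spec, "example.tar.gz")
engine = kgx.create_file_engine("example.tar.gz")
print(engine.summarize())

syndrome = kgx.descendants(engine.fetch_nodes(["FAKEMONDO:0000001"]))

direct = kgx.expand(syndrome, categories=["biolink:SequenceVariant"])
via_genes = kgx.expand(
    kgx.expand(syndrome, categories=["biolink:Gene"]),
    predicates=["biolink:is_sequence_variant_of"],
)
all_vars = kgx.kg_join(direct, via_genes)

phenos = kgx.filter_nodes(
    kgx.expand(all_vars, categories=["biolink:PhenotypicFeature"]),
    kgx.parse_expr('id =~ "^FAKEHP:"'),
)
panel = kgx.expand_n(phenos, predicates=["biolink:subclass_of"],
                     direction="out", n=2)
```

Output (abridged):

```
Nodes: 118
Edges: 362
Node categories (pcategory / total):
  biolink:Disease: 30 / 30
  biolink:Gene: 12 / 12
  biolink:NamedThing: 0 / 50
  biolink:PhenotypicFeature: 40 / 40
  biolink:SequenceVariant: 36 / 36
  ...
Edge predicates:
  biolink:causes: 54
  biolink:has_phenotype: 137
  biolink:subclass_of: 72
  ...
```

The store holds 118 nodes and 362 edges; the `pcategory / total` pair shows,
for instance, that 50 nodes list `biolink:NamedThing` among their categories
but none has it as primary category — the preference list always finds a
more specific one. The walk itself gives:

* `syndrome`: 15 nodes — the root plus its 14 transitive subtypes;
* `direct`: 35 nodes — those diseases plus 20 directly attached variants;
* `via_genes`: 59 nodes — the diseases, 11 associated genes and their
  33 variants;
* `all_vars`: 60 nodes — the union; variants found by both routes appear
  once;
* `phenos`: 35 directly annotated phenotypes, growing to a 36-node panel
  after two levels of subclass generalization.

The same walk works unchanged against any real KGX archive (e.g. from the
KGHub registry): only the engine's archive path and the CURIEs change.

Query expression syntax (for `fetch_nodes` via `parse_expr` and
`kgxkit fetch --expr`): `attr == <literal>`, `attr =~ "<regex>"`,
`<literal> in attr` (multi-valued cell membership; scalar cells act as
singletons), combined with `and`, `or`, `not` and parentheses. Literals are
double-quoted strings, numbers, `true`/`false`. Attributes missing from a
row never match.

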