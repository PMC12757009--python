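# Methods

## Data model

A knowledge graph is held as two pandas DataFrames of plain Python objects:
a node table (`id`, ordered multi-valued `category`, derived `pcategory`,
open attribute columns) and an edge table (`subject`, `predicate`, `object`,
open attribute columns). Node identity is the id string verbatim — no CURIE
normalization (case folding, prefix expansion) is attempted, because silent
identifier rewriting is a classic source of spurious merges. Edge identity
is the (subject, predicate, object) triple; a graph therefore cannot carry
two parallel edges with the same predicate, which matches the KGX export
convention of one row per assertion. Validity means: unique node ids, unique
triples, no dangling endpoints, nonempty category lists, and `pcategory`
drawn from `category`. `validate_graph` reports violations rather than
raising, so it can be used as a diagnostic on suspect inputs.

Multi-valued attribute cells preserve input order and are not de-duplicated:
order may be meaningful (category lists often go from general to specific)
and duplicate entries are evidence about the source, not noise to erase.

## Primary categories

KGX permits many categories per node and names no primary one. `pcategory`
is resolved per node as the highest-priority entry of an ordered preference
list that occurs in the node's category list. The shipped default ordering
puts the specific clinically-oriented categories first (disease, phenotype,
gene, sequence variant, then protein/chemical/process/anatomy, …) because in
Biolink-style graphs those co-occur with generic superclasses
(`biolink:BiologicalEntity`, `biolink:NamedThing`) that would otherwise win.
The list is fully overridable at engine construction. When no preference
matches, the fallback is the *first stored category* — deterministic,
stable across runs, and independent of the preference list; alternatives
(alphabetical order, error) would respectively privilege an arbitrary
lexical accident or make loading of unanticipated category vocabularies
fail.

## KGX-TSV serialization

Archives are tar.gz files; members ending in `nodes.tsv` / `edges.tsv`
(case-insensitive) are node/edge tables and all matches are concatenated,
tolerating the member-naming dialects seen in the wild. Multi-valued cells
use the pipe `|` delimiter of the KGX TSV convention (configurable). Values
containing a tab, newline, carriage return, backslash or the delimiter are
backslash-escaped on write and unescaped on read, so arbitrary strings
round-trip; unknown escape sequences pass through literally rather than
erroring. An empty cell means the attribute is absent for that row, not an
empty string — consequently an attribute column no row populates does not
survive a round trip, and round-trip identity is stated up to that (the
synthetic generator never emits such columns).

Scalar columns whose present values all parse as integers, floats, or
`True`/`False` are converted to those types on read; everything else stays
a string. This makes numeric attributes usable in rollups directly, at the
documented cost that a purely digit-string attribute would come back
numeric. The `category` column is always split to a list, even for
singletons.

Policy on malformed input: duplicate node ids and duplicate triples collapse
to the first occurrence with a logged warning (first-wins keeps the result
independent of later files in the archive); edges whose endpoints are
missing from the node files are dropped with a warning, restoring the
no-dangling-endpoints invariant; a missing required *column* is a hard
format error naming the file and column, since it indicates the archive is
not KGX at all.

Written archives are byte-deterministic (fixed member order, zeroed
timestamps and ownership, gzip mtime 0), which is what makes seeded
fixtures reproducible to the byte and lets tests compare serialized output
directly.

## Engine and queries

The file engine loads the whole archive into memory at construction — the
intended scale is desk-sized extracts and fixtures, not the multi-million
node stores behind database engines, and the engine surface (fetch /
summarize / example sampling / adjacency access) is deliberately small so a
database-backed engine could implement the same contract with pagination
and caching behind it.

Query expressions are explicit trees (`Equals`, `Matches`, `InList`, `And`,
`Or`, `Not`) rather than captured host-language expressions, so the same
semantics are scriptable from the CLI's textual syntax. Semantics chosen
where the reference behavior is underdetermined: `Equals` never matches a
multi-valued cell (use `InList`, which treats a scalar cell as a singleton
collection); `Matches` uses `re.search` and matches any element of a
multi-valued cell; an attribute missing from the table or empty for the row
makes any leaf false, never an error — filters over heterogeneous node
tables would otherwise be unwritable. Fetching by ids preserves store order
and de-duplicates the request; unknown ids are omitted with a warning
naming them, because a hard error would make set-valued lookups against
evolving stores brittle.

`summarize` reports both per-category counts (a node counts once per
category entry) and per-pcategory counts (each node exactly once, so these
sum to the node total): the two views answer different questions ("how many
nodes mention Gene?" vs "how many nodes *are* genes?").

`example_graph` must represent every category and predicate; a uniform
random sample does not. The deterministic rule — per predicate, the
lexicographically smallest (subject, predicate, object) edge plus its
endpoints; then per still-uncovered category the smallest node id carrying
it — achieves full coverage with at most (#predicates) edges plus
(#uncovered categories) extra nodes, and identical output on every run,
which makes it usable in regression tests.

## Expansion

`expand` pulls from the store every edge incident to a current node that
passes the predicate and direction filters (`out` = current node is
subject), plus the far-end nodes, optionally restricted by category;
`transitive=True` iterates the frontier step to a fixed point with a
visited set, so cyclic stores terminate. Design choices:

* The category restriction applies to *newly added* nodes only and never
  filters edges between two nodes already present — this keeps the
  supergraph contract unconditional and makes staged expansions compose
  (expanding to genes and then to variants equals the one-shot two-step
  growth).
* Absent predicate filter means all predicates; absent category filter all
  categories; default direction `both` — permissive defaults so the
  common "attach everything adjacent in any way" expansion needs no
  arguments.
* Transitive expansion with `direction="both"` is rejected: it would
  compute connected components, conflating ancestors with descendants; the
  meaningful transitive walks are directional.
* `expand_n` composes the single step n times (`n=0` is the identity) and
  stops early at a fixed point, so a generous n is cheap.

`descendants()`/`ancestors()` are exactly transitive inward/outward
`biolink:subclass_of` expansion.

## Graph algebra

`kg_join` unions node tables by id and edge tables by triple. Attribute
conflicts resolve left-preferentially with missing values filled from the
right — deterministic and documented, and idempotent/commutative/associative
on the id and triple *sets* (cell-level content depends on operand order
only where the operands genuinely disagree). Graphs whose engines point at
different sources refuse to join: node ids are only comparable within one
KG.

`rollup` aggregates a source attribute over every node transitively
reachable along one predicate (direction `in` walks edges backwards: on
child→parent subclass edges it gathers descendants), including the node
itself by default — a node's rolled-up value naturally includes its own
contribution, and `include_self=False` is available where it should not.
Shipped aggregators (`collect`, `distinct`, `count`, `sum`, `min`, `max`,
`string_join`) are all total over the empty collection (`sum` → 0, `min` →
None, …); arbitrary callables are accepted. Contributing values are
gathered in node-table row order so results are deterministic. `transfer`
is the one-step analogue and always yields a list (possibly empty).

`transitive_closure` adds `(a, predicate, c)` for every predicate-path
a→…→c, leaving other predicates untouched; added edges carry nothing
beyond the triple, and an existing edge (with its attributes) wins a triple
collision. On cyclic predicate subgraphs the closure may include self-loops
(a node on a cycle reaches itself); on DAGs it never does.
`transitive_reduction` requires the predicate subgraph to be a DAG and
raises a cycle error naming a member node otherwise — silently condensing
cycles would destroy assertions without a trace. Both are implemented on
networkx digraphs built from the predicate-labeled edge subset; the test
suite checks them against an independent boolean-matrix closure oracle.

## Synthetic generator

The generator emulates the structure the operations care about: disease
subclass DAGs (per-root trees of configurable depth and branching, with a
15% chance of an extra, shallower parent so hierarchies are DAGs rather
than trees), a phenotype subclass DAG grown by random parent attachment,
genes with species labels, variants attached to genes, and sparse
cross-category association edges (disease→phenotype 0.12, gene→disease
0.18, variant→disease 0.06 per pair; at least one edge per configured
predicate is guaranteed). Half the nodes carry a multi-valued category list
in which the specific category is deliberately not first, exercising
preference resolution. Identifiers use fabricated CURIE prefixes
(`FAKEMONDO:`, `FAKEHP:`, `FAKEGENE:`, `FAKEVAR:`) so prefix-regex queries
work without colliding with real vocabularies. Defaults give a ~120-node
graph — large enough for every code path, small enough that property
suites run hundreds of cases in seconds; the round-trip suite additionally
generates a couple of ~2000-node stores.

Alongside the graph the generator records a census from its own
construction bookkeeping — counts per category and predicate, each disease
root's subclass-reachable set, and the node sets of the staged
variant/phenotype prioritization walk — embedded in fixtures as a
`census.json` sidecar member that the KGX reader ignores. Tests and the
acceptance script compare operation output against this record, so the
ground truth never comes from the code paths under test.

What the generator does *not* emulate: realistic degree distributions, the
scale of public KGs, cross-references between vocabularies, literature
provenance attributes, or inter-species phenotype mappings. Passing tests
demonstrate the operations' correctness on structurally representative
graphs, not performance or semantics on any particular public KG.

## CLI

Each subcommand wraps one library operation; graphs pass between
invocations as KGX archives, with `--source` re-attaching the backing store
where expansion needs it — the CLI holds no state, so pipelines are
shell-scriptable and resumable. Warnings and logs go to stderr, data to
files; exit status is zero iff no error. GraphML export (lists pipe-joined,
`pcategory` on every node for coloring) provides the bridge to network
visualization tools.

## Known limitations

* The whole store lives in memory; archives beyond a few hundred thousand
  rows belong in a database-backed engine implementing the same contract.
* Edge-attribute predicates in `expand` (e.g. "follow only edges with
  frequency above x") are not supported; filter after expansion instead.
* Attribute typing is per-column inference on read; mixed-type columns stay
  strings.
* `graphs_equal` compares integer-valued floats equal to ints, reflecting
  what a text serialization can preserve.
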