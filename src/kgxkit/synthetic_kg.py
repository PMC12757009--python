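"""Seeded generator of ontology-like synthetic knowledge graphs.

Real biomedical KGs mix ontology hierarchies with cross-category
associations. The generator emulates that shape on a small scale so every
operation in this package is testable without downloading anything:

* a disease subclass DAG (a configurable number of root "syndromes", each
  with a tree of subtypes plus occasional extra parents, so the hierarchy is
  a DAG rather than a tree);
* a phenotype subclass DAG;
* genes with species labels (``in_taxon_label``) and sequence variants
  attached to genes via ``biolink:is_sequence_variant_of``;
* cross edges: disease→phenotype (``biolink:has_phenotype``, sometimes with
  a ``frequency_qualifier``), gene→disease
  (``biolink:gene_associated_with_condition``) and variant→disease
  (``biolink:causes``), each attached with a configurable probability.

Identifiers mimic CURIEs with fabricated prefixes (``FAKEMONDO:0000001``,
``FAKEHP:…``, ``FAKEGENE:…``, ``FAKEVAR:…``) so prefix-regex queries are
exercised without colliding with real identifiers. A configurable fraction
of nodes carries a multi-valued category list in which the specific category
is *not* first, exercising preference-driven pcategory resolution.

Alongside the graph, the generator declares its own ground-truth
:class:`Census` — counts per category and predicate, the subclass
reachability set of every disease root, and the node sets of the worked
variant/phenotype prioritization walk — recorded from its construction
bookkeeping so tests can assert against it without re-deriving anything from
the graph under test. The same seed always produces byte-identical archives.
"""

from __future__ import annotations

import json
import random
import tarfile
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import pandas as pd

from .kg_model import (
    DEFAULT_PREFERENCES,
    SUBCLASS_OF,
    KnowledgeGraph,
    resolve_pcategory,
)
from .kgx_io import write_kgx

HAS_PHENOTYPE = "biolink:has_phenotype"
GENE_TO_DISEASE = "biolink:gene_associated_with_condition"
VARIANT_TO_DISEASE = "biolink:causes"
VARIANT_OF = "biolink:is_sequence_variant_of"

CENSUS_MEMBER = "census.json"


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic KG.

    Defaults give a compact graph (~120 nodes) with every structural feature
    present: two disease hierarchies three levels deep with branching two,
    a 40-node phenotype DAG, 12 genes (three species) with three variants
    each, and sparse cross-category associations.
    """

    seed: int = 0
    n_disease_roots: int = 2
    subclass_depth: int = 3
    branching: int = 2
    n_genes: int = 12
    n_variants_per_gene: int = 3
    n_phenotypes: int = 40
    p_has_phenotype: float = 0.12
    p_gene_disease: float = 0.18
    p_variant_disease: float = 0.06
    p_extra_parent: float = 0.15
    taxon_labels: tuple[str, ...] = ("Homo sapiens", "Mus musculus", "Danio rerio")
    multi_category_fraction: float = 0.5


@dataclass
class Census:
    """Ground truth recorded while the generator builds the graph."""

    n_nodes: int
    n_edges: int
    category_counts: dict[str, int]
    pcategory_counts: dict[str, int]
    predicate_counts: dict[str, int]
    n_multi_category: int
    #: disease root id -> sorted subclass-reachable ids (root included)
    disease_descendants: dict[str, list[str]]
    #: the worked prioritization walk, from the first disease root
    replay: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Census":
        return cls(**json.loads(text))


@dataclass
class GeneratedKG:
    graph: KnowledgeGraph
    census: Census


def _reachable(adjacency: dict[str, list[str]], start: str) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adjacency.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def generate_kg(spec: GeneratorSpec) -> GeneratedKG:
    """Build a synthetic KG plus its ground-truth census.

    Deterministic: the same spec yields identical tables (and, via
    :func:`write_fixture`, byte-identical archives). Raises ``ValueError``
    for a degenerate spec that would produce zero nodes.
    """
    total = spec.n_disease_roots + spec.n_genes + spec.n_phenotypes
    if total <= 0:
        raise ValueError("degenerate GeneratorSpec: would generate zero nodes")
    rng = random.Random(spec.seed)

    node_rows: list[dict] = []
    edge_rows: list[dict] = []

    def multi(base_cats: list[str], generic: list[str]) -> tuple[list[str], bool]:
        if rng.random() < spec.multi_category_fraction:
            # specific category deliberately not first
            return [generic[0], *base_cats, *generic[1:]], True
        return list(base_cats), False

    n_multi = 0

    def add_node(nid: str, base: list[str], generic: list[str], **attrs):
        nonlocal n_multi
        cats, is_multi = multi(base, generic)
        n_multi += is_multi
        node_rows.append({"id": nid, "category": cats, **attrs})

    # --- disease hierarchy ---------------------------------------------------
    disease_counter = 0

    def new_disease() -> str:
        nonlocal disease_counter
        disease_counter += 1
        return f"FAKEMONDO:{disease_counter:07d}"

    disease_children: dict[str, list[str]] = {}
    roots: list[str] = []
    diseases: list[str] = []
    for r in range(spec.n_disease_roots):
        root = new_disease()
        roots.append(root)
        name = "Noonan-like syndrome (synthetic)" if r == 0 else f"Synthetic disease family {r + 1}"
        add_node(root, ["biolink:Disease"], ["biolink:BiologicalEntity", "biolink:NamedThing"], name=name)
        diseases.append(root)
        levels = [[root]]
        for depth in range(spec.subclass_depth):
            level = []
            for parent in levels[-1]:
                for _ in range(spec.branching):
                    child = new_disease()
                    add_node(
                        child,
                        ["biolink:Disease"],
                        ["biolink:BiologicalEntity", "biolink:NamedThing"],
                        name=f"Synthetic disease {child.split(':')[1].lstrip('0')}",
                    )
                    diseases.append(child)
                    level.append(child)
                    edge_rows.append(
                        {"subject": child, "predicate": SUBCLASS_OF, "object": parent}
                    )
                    disease_children.setdefault(parent, []).append(child)
                    # occasional second parent keeps the hierarchy a DAG, not a tree
                    shallower = [n for lv in levels for n in lv if n != parent]
                    if shallower and rng.random() < spec.p_extra_parent:
                        extra = rng.choice(shallower)
                        if child not in disease_children.get(extra, []):
                            edge_rows.append(
                                {"subject": child, "predicate": SUBCLASS_OF, "object": extra}
                            )
                            disease_children.setdefault(extra, []).append(child)
            levels.append(level)

    # --- phenotype DAG -------------------------------------------------------
    phenotypes: list[str] = []
    pheno_parents: dict[str, list[str]] = {}
    for i in range(spec.n_phenotypes):
        pid = f"FAKEHP:{i + 1:07d}"
        add_node(
            pid,
            ["biolink:PhenotypicFeature"],
            ["biolink:BiologicalEntity", "biolink:NamedThing"],
            name=f"Synthetic phenotype {i + 1}",
        )
        if phenotypes:
            parent = rng.choice(phenotypes)
            edge_rows.append({"subject": pid, "predicate": SUBCLASS_OF, "object": parent})
            pheno_parents[pid] = [parent]
            if len(phenotypes) > 1 and rng.random() < spec.p_extra_parent:
                extra = rng.choice([p for p in phenotypes if p != parent])
                edge_rows.append({"subject": pid, "predicate": SUBCLASS_OF, "object": extra})
                pheno_parents[pid].append(extra)
        phenotypes.append(pid)

    # --- genes and variants --------------------------------------------------
    genes: list[str] = []
    variants: list[str] = []
    variant_gene: dict[str, str] = {}
    vcount = 0
    for i in range(spec.n_genes):
        gid = f"FAKEGENE:{i + 1:05d}"
        taxon = rng.choice(spec.taxon_labels)
        add_node(
            gid,
            ["biolink:Gene"],
            ["biolink:Entity", "biolink:NamedThing"],
            name=f"GENE{i + 1}",
            in_taxon_label=taxon,
        )
        genes.append(gid)
        for _ in range(spec.n_variants_per_gene):
            vcount += 1
            vid = f"FAKEVAR:{vcount:06d}"
            add_node(
                vid,
                ["biolink:SequenceVariant"],
                ["biolink:BiologicalEntity", "biolink:NamedThing"],
                name=f"var-{vcount}",
                in_taxon_label=taxon,
            )
            variants.append(vid)
            variant_gene[vid] = gid
            edge_rows.append({"subject": vid, "predicate": VARIANT_OF, "object": gid})

    # --- cross-category associations ------------------------------------------
    freq_pool = ("HP:0040281", "HP:0040282", "HP:0040283")
    dis_phen: list[tuple[str, str]] = []
    for d in diseases:
        for p in phenotypes:
            if rng.random() < spec.p_has_phenotype:
                row = {"subject": d, "predicate": HAS_PHENOTYPE, "object": p}
                if rng.random() < 0.4:
                    row["frequency_qualifier"] = rng.choice(freq_pool)
                edge_rows.append(row)
                dis_phen.append((d, p))
    gene_dis: list[tuple[str, str]] = []
    for gid in genes:
        for d in diseases:
            if rng.random() < spec.p_gene_disease:
                edge_rows.append({"subject": gid, "predicate": GENE_TO_DISEASE, "object": d})
                gene_dis.append((gid, d))
    var_dis: list[tuple[str, str]] = []
    for vid in variants:
        for d in diseases:
            if rng.random() < spec.p_variant_disease:
                edge_rows.append({"subject": vid, "predicate": VARIANT_TO_DISEASE, "object": d})
                var_dis.append((vid, d))

    # guarantee >=1 edge per configured cross predicate
    if diseases and phenotypes and not dis_phen:
        edge_rows.append({"subject": diseases[0], "predicate": HAS_PHENOTYPE, "object": phenotypes[0]})
        dis_phen.append((diseases[0], phenotypes[0]))
    if genes and diseases and not gene_dis:
        edge_rows.append({"subject": genes[0], "predicate": GENE_TO_DISEASE, "object": diseases[0]})
        gene_dis.append((genes[0], diseases[0]))
    if variants and diseases and not var_dis:
        edge_rows.append({"subject": variants[0], "predicate": VARIANT_TO_DISEASE, "object": diseases[0]})
        var_dis.append((variants[0], diseases[0]))

    # --- assemble tables -------------------------------------------------------
    nodes = pd.DataFrame(node_rows, dtype=object)
    nodes = nodes.where(pd.notna(nodes), None)
    pcats = [resolve_pcategory(c, DEFAULT_PREFERENCES) for c in nodes["category"]]
    nodes.insert(nodes.columns.get_loc("category") + 1, "pcategory", pd.Series(pcats, dtype=object))
    edges = pd.DataFrame(edge_rows, dtype=object)
    edges = edges.where(pd.notna(edges), None)
    graph = KnowledgeGraph(nodes, edges, None)

    # --- census from construction bookkeeping ----------------------------------
    category_counts: Counter = Counter()
    for row in node_rows:
        category_counts.update(row["category"])
    predicate_counts = Counter(r["predicate"] for r in edge_rows)

    disease_descendants = {
        root: sorted(_reachable(disease_children, root)) for root in roots
    }

    replay: dict[str, list[str]] = {}
    if roots:
        root0 = roots[0]
        D = _reachable(disease_children, root0)
        direct_vars = {v for v, d in var_dis if d in D}
        assoc_genes = {g for g, d in gene_dis if d in D}
        gene_vars = {v for v, g in variant_gene.items() if g in assoc_genes}
        union = D | direct_vars | assoc_genes | gene_vars
        direct_phenos = {p for d, p in dis_phen if d in D}
        # two levels of phenotype generalization (child -> parent walks)
        frontier = set(direct_phenos)
        expanded = set(direct_phenos)
        for _ in range(2):
            frontier = {
                parent for child in frontier for parent in pheno_parents.get(child, ())
            } - expanded
            expanded |= frontier
        replay = {
            "root": [root0],
            "descendants": sorted(D),
            "direct_variants": sorted(direct_vars),
            "associated_genes": sorted(assoc_genes),
            "gene_variants": sorted(gene_vars),
            "variant_union": sorted(union),
            "direct_phenotypes": sorted(direct_phenos),
            "phenotypes_two_levels": sorted(expanded),
        }

    census = Census(
        n_nodes=len(node_rows),
        n_edges=len(edge_rows),
        category_counts=dict(sorted(category_counts.items())),
        pcategory_counts=dict(sorted(Counter(pcats).items())),
        predicate_counts=dict(sorted(predicate_counts.items())),
        n_multi_category=n_multi,
        disease_descendants=disease_descendants,
        replay=replay,
    )
    return GeneratedKG(graph=graph, census=census)


def write_fixture(spec: GeneratorSpec, path) -> str:
    """Generate a KG and write it as a KGX archive with an embedded census.

    The census rides along as a ``census.json`` member that
    :func:`~kgxkit.kgx_io.read_kgx` ignores; recover it with
    :func:`read_census`. Byte-deterministic per spec.
    """
    generated = generate_kg(spec)
    extra = {CENSUS_MEMBER: generated.census.to_json().encode("utf-8")}
    return write_kgx(generated.graph, path, extra_members=extra)


def read_census(path) -> Census:
    """Read the ground-truth census embedded in a generated fixture."""
    with tarfile.open(str(path), "r:*") as tar:
        member = tar.extractfile(CENSUS_MEMBER)
        if member is None:  # pragma: no cover - defensive
            raise FileNotFoundError(f"{path}: no {CENSUS_MEMBER} member")
        return Census.from_json(member.read().decode("utf-8"))
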