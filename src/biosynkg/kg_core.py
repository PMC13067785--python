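"""Heterogeneous knowledge graph of microbes, nanomaterials and elements.

The graph has two levels: a small class ontology (Element, Material,
Microorganism, ... linked by subclass edges) and an instance level of
concrete entities typed into those classes.  A taxonomy backbone (phylum →
genus → species → strain) connects microbial entities through
``taxon_parent`` edges and/or per-entity lineage annotations, and reported
biosynthesis facts are ``synthesizes`` edges carrying the publication year
of the report.  This module owns loading, validation, temporal splitting,
taxonomy queries and serialization (TSV, N-Triples, Newick).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
import rdflib
from rdflib.namespace import RDF, RDFS

logger = logging.getLogger(__name__)

#: Namespace used for N-Triples serialization.
NS = "http://biosynkg.org/kg/"

#: Relations every graph understands.  The vocabulary is open: unknown
#: relations are kept (with a warning) and treated as distinct edge types.
CORE_RELATIONS = frozenset(
    {
        "synthesizes",
        "composed_of",
        "instance_of",
        "subclass_of",
        "taxon_parent",
        "uses_method",
    }
)

#: Canonical taxonomic ranks, highest first.
RANK_ORDER = ("domain", "phylum", "class", "order", "family", "genus", "species", "strain")
_RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}

#: Classes treated as taxon-level (eligible for genus lookup).
TAXON_CLASSES = frozenset({"Microorganism", "Species", "Genus", "Phylum"})


class ValidationError(ValueError):
    """A structural invariant of the knowledge graph is violated."""


@dataclass(frozen=True)
class OntologyClass:
    """One node of the class hierarchy; ``parent`` is None only for the root."""

    name: str
    parent: str | None = None


def default_ontology() -> dict[str, OntologyClass]:
    """The built-in class hierarchy.

    ``Element`` branches into ``Metals`` and ``Nonmetals``; the microbial
    side descends ``Genus`` → ``Species`` → ``Microorganism`` (strains);
    ``Material`` and ``SynthesisMethod`` are independent classes.
    """
    classes = [
        OntologyClass("Thing", None),
        OntologyClass("Element", "Thing"),
        OntologyClass("Metals", "Element"),
        OntologyClass("Nonmetals", "Element"),
        OntologyClass("Phylum", "Thing"),
        OntologyClass("Genus", "Phylum"),
        OntologyClass("Species", "Genus"),
        OntologyClass("Microorganism", "Species"),
        OntologyClass("Material", "Thing"),
        OntologyClass("SynthesisMethod", "Thing"),
    ]
    return {c.name: c for c in classes}


@dataclass(frozen=True)
class EntityRecord:
    """One node: a microbe, material, element, taxon or method.

    ``lineage`` is an ordered tuple of ``(rank, taxon name)`` pairs from
    highest rank (e.g. phylum) down to the entity's own rank.
    """

    id: str
    cls: str
    label: str = ""
    description: str = ""
    year: int | None = None
    lineage: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be nonempty")
        if self.lineage is not None:
            ranks = [r for r, _ in self.lineage]
            known = [(_RANK_INDEX[r], r) for r in ranks if r in _RANK_INDEX]
            if any(known[i][0] >= known[i + 1][0] for i in range(len(known) - 1)):
                raise ValidationError(
                    f"entity {self.id}: lineage ranks not strictly descending: {ranks}"
                )

    def lineage_rank(self, rank: str) -> str | None:
        if self.lineage is None:
            return None
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


@dataclass(frozen=True)
class TripleRecord:
    """One directed labeled edge ``head --relation--> tail``."""

    head: str
    relation: str
    tail: str
    year: int | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


@dataclass
class KnowledgeGraph:
    """Typed entities plus relation triples; single source of truth downstream."""

    classes: dict[str, OntologyClass] = field(default_factory=default_ontology)
    entities: dict[str, EntityRecord] = field(default_factory=dict)
    triples: list[TripleRecord] = field(default_factory=list)
    dedup_count: int = 0

    # -- construction ----------------------------------------------------
    def add_entity(self, e: EntityRecord) -> None:
        if e.id in self.entities:
            raise ValidationError(f"duplicate entity id {e.id!r}")
        if e.cls not in self.classes:
            raise ValidationError(f"entity {e.id!r}: unknown class {e.cls!r}")
        self.entities[e.id] = e

    def add_class(self, c: OntologyClass) -> None:
        self.classes[c.name] = c

    def add_triples(self, triples: Iterable[TripleRecord], dedup: bool = True) -> int:
        """Append triples; duplicates (same head, relation, tail) dropped.

        Returns the number of duplicates dropped and accumulates it on
        :attr:`dedup_count`.
        """
        seen = {t.key() for t in self.triples}
        dropped = 0
        for t in triples:
            if dedup and t.key() in seen:
                dropped += 1
                continue
            seen.add(t.key())
            self.triples.append(t)
        if dropped:
            logger.warning("dropped %d duplicate triples", dropped)
        self.dedup_count += dropped
        return dropped

    # -- queries ---------------------------------------------------------
    def triples_with(self, relation: str) -> list[TripleRecord]:
        return [t for t in self.triples if t.relation == relation]

    def entities_of_class(self, cls: str) -> list[EntityRecord]:
        return [e for e in self.entities.values() if e.cls == cls]

    def microbes(self) -> list[EntityRecord]:
        return self.entities_of_class("Microorganism")

    def materials(self) -> list[EntityRecord]:
        return self.entities_of_class("Material")

    def relations(self) -> list[str]:
        return sorted({t.relation for t in self.triples})

    def taxon_parent_map(self) -> dict[str, str]:
        """child id → parent id under ``taxon_parent`` (first parent wins)."""
        parent: dict[str, str] = {}
        for t in self.triples_with("taxon_parent"):
            if t.head in parent and parent[t.head] != t.tail:
                logger.warning(
                    "entity %s has multiple taxon parents; keeping %s", t.head, parent[t.head]
                )
                continue
            parent[t.head] = t.tail
        return parent

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        for name, c in self.classes.items():
            seen: set[str] = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"class hierarchy cycle at {cur!r}")
                seen.add(cur)
                parent = self.classes.get(cur)
                if parent is None:
                    raise ValidationError(f"class {cur!r} undeclared")
                cur = parent.parent
        dangling = [
            (i, t)
            for i, t in enumerate(self.triples)
            if t.head not in self.entities or t.tail not in self.entities
        ]
        if dangling:
            rows = "; ".join(
                f"row {i}: ({t.head}, {t.relation}, {t.tail})" for i, t in dangling[:10]
            )
            raise ValidationError(f"{len(dangling)} triples with dangling endpoints: {rows}")
        keys = [t.key() for t in self.triples]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate triples present; load via add_triples")
        unknown = {t.relation for t in self.triples} - CORE_RELATIONS
        if unknown:
            logger.warning("unknown relations kept as distinct types: %s", sorted(unknown))
        # taxon_parent must be a forest
        parent = self.taxon_parent_map()
        for start in parent:
            cur, seen = start, set()
            while cur in parent:
                if cur in seen:
                    raise ValidationError(f"taxonomy cycle through {cur!r}")
                seen.add(cur)
                cur = parent[cur]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

ENTITY_COLUMNS = ["id", "class", "label", "description", "year", "lineage"]
TRIPLE_COLUMNS = ["head", "relation", "tail", "year"]


def _parse_year(raw: str) -> int | None:
    raw = str(raw).strip()
    if raw in ("", "nan", "None", "NA"):
        return None
    return int(float(raw))


def parse_lineage(raw: str) -> tuple[tuple[str, str], ...] | None:
    """Parse a semicolon-joined ``rank:name`` lineage string."""
    raw = raw.strip()
    if not raw:
        return None
    pairs = []
    for part in raw.split(";"):
        rank, _, name = part.partition(":")
        if not name:
            raise ValidationError(f"malformed lineage element {part!r}")
        pairs.append((rank.strip(), name.strip()))
    return tuple(pairs)


def format_lineage(lineage: tuple[tuple[str, str], ...] | None) -> str:
    if lineage is None:
        return ""
    return ";".join(f"{r}:{n}" for r, n in lineage)


def load_graph(
    entity_file: str | Path,
    triple_file: str | Path,
    taxonomy_file: str | Path | None = None,
) -> KnowledgeGraph:
    """Load a knowledge graph from tab-separated entity and triple tables.

    The entity table needs columns ``id, class, label, description, year``
    (optionally ``lineage`` as semicolon-joined ``rank:name``); the triple
    table needs ``head, relation, tail, year``.  Years may be empty.  An
    optional taxonomy file adds ``taxon_parent`` edges, either as a
    two-column ``child<TAB>parent`` TSV or as a Newick file whose node
    labels are entity ids.  Malformed rows raise with row numbers;
    duplicated triples are dropped and counted on ``dedup_count``.
    """
    entity_file, triple_file = Path(entity_file), Path(triple_file)
    for p in (entity_file, triple_file):
        if not p.exists():
            raise FileNotFoundError(p)

    g = KnowledgeGraph()
    ent = pd.read_csv(entity_file, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ENTITY_COLUMNS[:5] if c not in ent.columns]
    if missing:
        raise ValidationError(f"entity file missing columns {missing}")
    errors: list[str] = []
    for i, row in enumerate(ent.to_dict("records"), start=2):
        try:
            cls = row["class"]
            lineage = parse_lineage(row.get("lineage", ""))
            if cls not in g.classes:
                g.add_class(OntologyClass(cls, "Thing"))
                logger.warning("row %d: undeclared class %r added under Thing", i, cls)
            g.add_entity(
                EntityRecord(
                    id=row["id"],
                    cls=cls,
                    label=row["label"],
                    description=row["description"],
                    year=_parse_year(row["year"]),
                    lineage=lineage,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"{entity_file.name} row {i}: {exc}")
    if errors:
        raise ValidationError("malformed entity rows:\n" + "\n".join(errors))

    tri = pd.read_csv(triple_file, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TRIPLE_COLUMNS[:3] if c not in tri.columns]
    if missing:
        raise ValidationError(f"triple file missing columns {missing}")
    records = []
    for i, row in enumerate(tri.itertuples(index=False), start=2):
        try:
            year = _parse_year(row.year) if "year" in tri.columns else None
            records.append(TripleRecord(row.head, row.relation, row.tail, year))
        except ValueError as exc:
            errors.append(f"{triple_file.name} row {i}: {exc}")
    if errors:
        raise ValidationError("malformed triple rows:\n" + "\n".join(errors))
    g.add_triples(records)

    if taxonomy_file is not None:
        g.add_triples(_load_taxonomy(Path(taxonomy_file), g))
    _reconcile_lineage(g)
    g.validate()
    return g


def _load_taxonomy(path: Path, g: KnowledgeGraph) -> list[TripleRecord]:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".nwk", ".newick", ".tre", ".tree"):
        tree_list = dendropy.TreeList.get(path=str(path), schema="newick")
        out = []
        for tree in tree_list:
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                child = node.taxon.label if node.taxon else node.label
                parent = (
                    node.parent_node.taxon.label
                    if node.parent_node.taxon
                    else node.parent_node.label
                )
                if child and parent:
                    out.append(TripleRecord(child, "taxon_parent", parent))
        return out
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"child", "parent"} <= set(df.columns):
        raise ValidationError("taxonomy TSV needs columns child, parent")
    return [TripleRecord(r.child, "taxon_parent", r.parent) for r in df.itertuples(index=False)]


def _reconcile_lineage(g: KnowledgeGraph) -> None:
    """Lineage columns win over conflicting taxon_parent edges (logged)."""
    parent = g.taxon_parent_map()
    by_label = {(e.cls, e.label or e.id): e.id for e in g.entities.values()}
    for e in g.entities.values():
        if e.lineage is None or e.cls != "Microorganism":
            continue
        genus_name = e.lineage_rank("genus")
        if genus_name is None:
            continue
        edge_genus = _walk_to_class(g, parent, e.id, "Genus")
        if edge_genus is not None:
            edge_name = g.entities[edge_genus].label or edge_genus
            if edge_name != genus_name:
                logger.warning(
                    "entity %s: lineage genus %r overrides taxon_parent genus %r",
                    e.id,
                    genus_name,
                    edge_name,
                )


def _walk_to_class(
    g: KnowledgeGraph, parent: Mapping[str, str], start: str, cls: str
) -> str | None:
    cur = start
    seen = set()
    while cur in parent and cur not in seen:
        seen.add(cur)
        cur = parent[cur]
        if g.entities.get(cur) is not None and g.entities[cur].cls == cls:
            return cur
    return None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def temporal_subgraph(g: KnowledgeGraph, cutoff_year: int, side: str) -> KnowledgeGraph:
    """Split the reported-synthesis facts by publication year.

    ``side='before'`` keeps ``synthesizes`` triples with year < cutoff;
    ``side='from'`` keeps year >= cutoff.  Structural triples (composition,
    taxonomy, ontology, methods) and the entity set are retained on both
    sides: background knowledge is not year-filtered.  Undated synthesizes
    triples are dropped from both sides with a warning.
    """
    if side not in ("before", "from"):
        raise ValueError(f"side must be 'before' or 'from', got {side!r}")
    synth = g.triples_with("synthesizes")
    if synth and all(t.year is None for t in synth):
        raise ValidationError(
            "all synthesizes triples lack years; supply publication years to split temporally"
        )
    undated = sum(1 for t in synth if t.year is None)
    if undated:
        logger.warning("%d undated synthesizes triples excluded from both sides", undated)
    kept: list[TripleRecord] = []
    for t in g.triples:
        if t.relation != "synthesizes":
            kept.append(t)
        elif t.year is not None and (t.year < cutoff_year if side == "before" else t.year >= cutoff_year):
            kept.append(t)
    if not any(t.relation == "synthesizes" for t in kept):
        logger.warning("temporal_subgraph(%s, %d): empty synthesizes set", side, cutoff_year)
    out = KnowledgeGraph(classes=dict(g.classes), entities=dict(g.entities))
    out.add_triples(kept, dedup=False)
    out.validate()
    return out


def genus_of(g: KnowledgeGraph, microbe_id: str) -> str | None:
    """Genus of a microbial entity, from its lineage or taxon_parent walk.

    Lineage takes precedence; returns the genus taxon name (lineage) or the
    genus entity id (graph walk), or None when no genus is recorded.
    """
    e = g.entities.get(microbe_id)
    if e is None:
        raise KeyError(microbe_id)
    if e.cls not in TAXON_CLASSES:
        raise TypeError(f"{microbe_id!r} is class {e.cls!r}, not a microbial taxon")
    if e.cls == "Genus":
        return e.id
    name = e.lineage_rank("genus")
    if name is not None:
        return name
    return _walk_to_class(g, g.taxon_parent_map(), microbe_id, "Genus")


def export_ntriples(g: KnowledgeGraph, out: str | Path) -> int:
    """Serialize class hierarchy, typing and domain relations as N-Triples.

    Subclass edges become ``rdfs:subClassOf``, entity typing ``rdf:type``,
    and domain relations namespaced predicates; nonempty labels and
    descriptions are emitted as ``rdfs:label`` / ``rdfs:comment`` literals.
    Returns the number of statements written.
    """
    rg = rdflib.Graph()
    ent_ns = rdflib.Namespace(NS + "entity/")
    cls_ns = rdflib.Namespace(NS + "class/")
    rel_ns = rdflib.Namespace(NS + "relation/")
    for c in g.classes.values():
        if c.parent is not None:
            rg.add((cls_ns[c.name], RDFS.subClassOf, cls_ns[c.parent]))
    for e in g.entities.values():
        rg.add((ent_ns[e.id], RDF.type, cls_ns[e.cls]))
        if e.label:
            rg.add((ent_ns[e.id], RDFS.label, rdflib.Literal(e.label)))
        if e.description:
            rg.add((ent_ns[e.id], RDFS.comment, rdflib.Literal(e.description)))
    for t in g.triples:
        if t.relation in ("instance_of", "subclass_of"):
            continue  # already expressed through rdf:type / rdfs:subClassOf
        rg.add((ent_ns[t.head], rel_ns[t.relation], ent_ns[t.tail]))
    rg.serialize(destination=str(out), format="nt", encoding="utf-8")
    return len(rg)


def import_ntriples(path: str | Path) -> KnowledgeGraph:
    """Rebuild a structure-lossless graph from an :func:`export_ntriples` file.

    Edge years and lineage are not representable in plain N-Triples, so the
    round trip preserves entity and triple identity, not year stamps.
    """
    rg = rdflib.Graph()
    rg.parse(str(path), format="nt")
    ent_pre, cls_pre, rel_pre = NS + "entity/", NS + "class/", NS + "relation/"
    g = KnowledgeGraph()
    labels: dict[str, str] = {}
    comments: dict[str, str] = {}
    typed: dict[str, str] = {}
    domain: list[tuple[str, str, str]] = []
    for s, p, o in rg:
        s_id = str(s)[len(ent_pre):] if str(s).startswith(ent_pre) else str(s)
        if p == RDFS.subClassOf:
            child = str(s)[len(cls_pre):]
            parent = str(o)[len(cls_pre):]
            g.add_class(OntologyClass(child, parent))
            if parent not in g.classes:
                g.add_class(OntologyClass(parent, "Thing" if parent != "Thing" else None))
        elif p == RDF.type:
            typed[s_id] = str(o)[len(cls_pre):]
        elif p == RDFS.label:
            labels[s_id] = str(o)
        elif p == RDFS.comment:
            comments[s_id] = str(o)
        elif str(p).startswith(rel_pre):
            domain.append((s_id, str(p)[len(rel_pre):], str(o)[len(ent_pre):]))
    for eid, cls in typed.items():
        if cls not in g.classes:
            g.add_class(OntologyClass(cls, "Thing"))
        g.add_entity(
            EntityRecord(eid, cls, label=labels.get(eid, ""), description=comments.get(eid, ""))
        )
    g.add_triples(TripleRecord(h, r, t) for h, r, t in domain)
    g.validate()
    return g


def export_taxonomy_newick(g: KnowledgeGraph, out: str | Path) -> int:
    """Write the taxon_parent forest as Newick, one tree per root.

    Leaves are strain-level microbes (class ``Microorganism``); internal
    node labels are the higher taxa.  Returns the total leaf count.
    """
    parent = g.taxon_parent_map()
    members = set(parent) | set(parent.values())
    if not members:
        raise ValidationError("taxonomy is empty; no taxon_parent edges")
    children: dict[str, list[str]] = {}
    for c, p in sorted(parent.items()):
        children.setdefault(p, []).append(c)
    roots = sorted(m for m in members if m not in parent)

    tree_list = dendropy.TreeList()
    n_leaves = 0
    for root in roots:
        tree = dendropy.Tree()
        tree.seed_node.label = root
        stack = [(root, tree.seed_node)]
        while stack:
            nid, node = stack.pop()
            for child in children.get(nid, []):
                cn = node.new_child()
                cn.label = child
                stack.append((child, cn))
        for leaf in tree.leaf_node_iter():
            taxon = dendropy.Taxon(label=leaf.label)
            tree.taxon_namespace.add_taxon(taxon)
            leaf.taxon = taxon
            n_leaves += 1
        tree_list.append(tree)
    tree_list.write(path=str(out), schema="newick", suppress_rooting=True)
    return n_leaves


def write_graph_tsv(g: KnowledgeGraph, entity_file: str | Path, triple_file: str | Path) -> None:
    """Write the entity/triple tables in the dialect :func:`load_graph` reads."""
    ent = pd.DataFrame(
        [
            {
                "id": e.id,
                "class": e.cls,
                "label": e.label,
                "description": e.description,
                "year": "" if e.year is None else e.year,
                "lineage": format_lineage(e.lineage),
            }
            for e in g.entities.values()
        ],
        columns=ENTITY_COLUMNS,
    )
    tri = pd.DataFrame(
        [
            {
                "head": t.head,
                "relation": t.relation,
                "tail": t.tail,
                "year": "" if t.year is None else t.year,
            }
            for t in g.triples
        ],
        columns=TRIPLE_COLUMNS,
    )
    ent.to_csv(entity_file, sep="\t", index=False)
    tri.to_csv(triple_file, sep="\t", index=False)
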