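"""Synthetic knowledge-graph generator with planted, heritable synthesis traits.

Real reports of microbial nanomaterial synthesis are sparse (a few hundred
microbes, fewer than a hundred materials) and phylogenetically clustered:
the ability to deposit a given metal behaves like a heritable functional
trait of clades.  This generator reproduces exactly that structure at desk
scale so the embedding model and evaluation protocols can be exercised
end-to-end with a known ground truth:

* a balanced taxonomy (phylum → genus → species → strain),
* element entities and materials composed of 1..k distinct elements,
  grouped into "families" by leading element,
* microbe—synthesizes—material edges planted clade-wise: each
  (genus, material family) is capable with probability ``clade_trait_prob``;
  strains inherit the clade trait with probability ``trait_heritability``
  and otherwise redraw it independently; capable strain×material pairs link
  with ``capable_edge_prob``, the rest with ``base_edge_prob``,
* a uniform publication year per edge (for temporal splits), and
* short templated descriptions whose keywords correlate with the planted
  capabilities (the semantic signal).

Defaults give 40 strains and 10 materials — about one tenth of the
reported-literature scale (≈400 microbes, ≈90 materials) with the same
microbe:material ratio.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kg_core import (
    EntityRecord,
    KnowledgeGraph,
    TripleRecord,
    ValidationError,
    export_taxonomy_newick,
    load_graph,
    write_graph_tsv,
)

logger = logging.getLogger(__name__)

ELEMENT_SYMBOLS = [
    ("Au", "gold"), ("Ag", "silver"), ("Pd", "palladium"), ("Pt", "platinum"),
    ("Se", "selenium"), ("Fe", "iron"), ("Cu", "copper"), ("Zn", "zinc"),
    ("Te", "tellurium"), ("Ni", "nickel"), ("Co", "cobalt"), ("Ti", "titanium"),
    ("Cd", "cadmium"), ("Mn", "manganese"), ("Pb", "lead"), ("Sn", "tin"),
]

_NOISE_WORDS = [
    "aerobic", "anaerobic", "mesophilic", "thermophilic", "halotolerant",
    "motile", "nonmotile", "sporulating", "pigmented", "filamentous",
    "rod-shaped", "coccoid", "marine", "soil-dwelling", "acidophilic",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs; one config fully determines one dataset."""

    n_phyla: int = 2
    n_genera_per_phylum: int = 5
    n_species_per_genus: int = 2
    n_strains_per_species: int = 2
    n_elements: int = 6
    n_materials: int = 10
    max_elements_per_material: int = 3
    trait_heritability: float = 0.9
    clade_trait_prob: float = 0.3
    base_edge_prob: float = 0.05
    capable_edge_prob: float = 0.8
    year_range: tuple[int, int] = (2010, 2022)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_phyla, self.n_genera_per_phylum, self.n_species_per_genus,
            self.n_strains_per_species, self.n_elements, self.n_materials,
            self.max_elements_per_material,
        )
        if any(c < 1 for c in counts):
            raise ValidationError(f"all counts must be >= 1, got {counts}")
        if not 0.0 <= self.trait_heritability <= 1.0:
            raise ValidationError("trait_heritability must be in [0, 1]")
        if not 0.0 <= self.clade_trait_prob <= 1.0:
            raise ValidationError("clade_trait_prob must be in [0, 1]")
        if not 0.0 < self.base_edge_prob < 1.0:
            raise ValidationError("base_edge_prob must be in (0, 1)")
        if not 0.0 < self.capable_edge_prob < 1.0:
            raise ValidationError("capable_edge_prob must be in (0, 1)")
        if self.capable_edge_prob <= self.base_edge_prob:
            raise ValidationError("capable_edge_prob must exceed base_edge_prob")
        if self.max_elements_per_material > self.n_elements:
            raise ValidationError("max_elements_per_material exceeds n_elements")
        if self.n_elements > len(ELEMENT_SYMBOLS):
            raise ValidationError(f"at most {len(ELEMENT_SYMBOLS)} elements supported")
        if self.year_range[0] > self.year_range[1]:
            raise ValidationError("year_range min must be <= max")

    @property
    def n_strains(self) -> int:
        return (
            self.n_phyla * self.n_genera_per_phylum
            * self.n_species_per_genus * self.n_strains_per_species
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["year_range"] = tuple(d["year_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Bookkeeping of every Bernoulli draw made while planting edges.

    ``capable_pairs`` holds (strain id, material id) pairs whose strain-level
    trait is capable; ``clade_traits`` maps (genus id, family id) to the
    clade-level draw; ``draws`` maps (strain id, material id) to
    (capable flag, edge flag, year or None) for every pair considered.
    """

    capable_pairs: set[tuple[str, str]] = field(default_factory=set)
    clade_traits: dict[tuple[str, str], bool] = field(default_factory=dict)
    draws: dict[tuple[str, str], tuple[bool, bool, int | None]] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def generate_taxonomy(cfg: SyntheticConfig) -> KnowledgeGraph:
    """Balanced 4-level taxonomy; each strain carries its full lineage."""
    cfg.validate()
    g = KnowledgeGraph()
    triples: list[TripleRecord] = []
    s_i = 0
    for p in range(cfg.n_phyla):
        pid = f"phy{p:02d}"
        g.add_entity(EntityRecord(pid, "Phylum", label=f"Phylum-{p:02d}",
                                  lineage=(("phylum", pid),)))
        for ge in range(cfg.n_genera_per_phylum):
            gid = f"{pid}.gen{ge:02d}"
            g.add_entity(EntityRecord(gid, "Genus", label=f"Genus-{p:02d}-{ge:02d}",
                                      lineage=(("phylum", pid), ("genus", gid))))
            triples.append(TripleRecord(gid, "taxon_parent", pid))
            for sp in range(cfg.n_species_per_genus):
                sid = f"{gid}.sp{sp:02d}"
                g.add_entity(EntityRecord(
                    sid, "Species", label=f"Species-{p:02d}-{ge:02d}-{sp:02d}",
                    lineage=(("phylum", pid), ("genus", gid), ("species", sid)),
                ))
                triples.append(TripleRecord(sid, "taxon_parent", gid))
                for st in range(cfg.n_strains_per_species):
                    tid = f"{sid}.st{st:02d}"
                    g.add_entity(EntityRecord(
                        tid, "Microorganism", label=f"Strain-{s_i:03d}",
                        lineage=(
                            ("phylum", pid), ("genus", gid),
                            ("species", sid), ("strain", tid),
                        ),
                    ))
                    triples.append(TripleRecord(tid, "taxon_parent", sid))
                    s_i += 1
    g.add_triples(triples, dedup=False)
    g.validate()
    return g


def material_family(g: KnowledgeGraph, material_id: str) -> str:
    """Family id of a material = its leading (first-listed) element."""
    for t in g.triples:
        if t.relation == "composed_of" and t.head == material_id:
            return t.tail
    raise KeyError(f"material {material_id!r} has no composed_of edges")


def generate_materials(cfg: SyntheticConfig) -> KnowledgeGraph:
    """Element entities plus materials composed of 1..k distinct elements.

    The first-drawn element of each material defines its family; the leading
    element is drawn from a skewed distribution so that several materials
    share a family (required for clade-wise trait planting to generalize).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    g = KnowledgeGraph()
    symbols = ELEMENT_SYMBOLS[: cfg.n_elements]
    for sym, name in symbols:
        g.add_entity(EntityRecord(sym, "Metals", label=name,
                                  description=f"chemical element {name} symbol {sym}"))
    # skewed leading-element weights -> repeated families
    w = 1.0 / (1.0 + np.arange(cfg.n_elements))
    w /= w.sum()
    triples = []
    for m in range(cfg.n_materials):
        k = int(rng.integers(1, cfg.max_elements_per_material + 1))
        lead = int(rng.choice(cfg.n_elements, p=w))
        others = [i for i in range(cfg.n_elements) if i != lead]
        rest = sorted(rng.choice(others, size=k - 1, replace=False)) if k > 1 else []
        idx = [lead] + [int(i) for i in rest]
        syms = [symbols[i][0] for i in idx]
        mid = f"mat{m:02d}_{''.join(syms)}"
        g.add_entity(EntityRecord(mid, "Material", label="".join(syms)))
        for s in syms:
            triples.append(TripleRecord(mid, "composed_of", s))
    g.add_triples(triples, dedup=False)
    g.validate()
    return g


def plant_synthesis_edges(
    taxonomy: KnowledgeGraph, materials: KnowledgeGraph, cfg: SyntheticConfig
) -> tuple[list[TripleRecord], GroundTruth]:
    """Plant clade-heritable microbe—synthesizes—material edges.

    For each (genus, family) a Bernoulli(``clade_trait_prob``) draw marks the
    clade capable.  Each strain inherits the clade trait with probability
    ``trait_heritability`` and otherwise redraws an independent
    Bernoulli(``clade_trait_prob``) trait, so heritability interpolates
    between pure clade-level (1) and pure strain-level (0) traits.  Capable
    strain×material pairs receive an edge with ``capable_edge_prob``, all
    others with ``base_edge_prob``; each edge gets a uniform year.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    truth = GroundTruth()
    strains = sorted(e.id for e in taxonomy.microbes())
    mats = sorted(e.id for e in materials.materials())
    families = {m: material_family(materials, m) for m in mats}
    genera = sorted(e.id for e in taxonomy.entities_of_class("Genus"))
    fam_ids = sorted(set(families.values()))
    for gid in genera:
        for fam in fam_ids:
            truth.clade_traits[(gid, fam)] = bool(rng.random() < cfg.clade_trait_prob)
    genus_by_strain = {
        e.id: e.lineage_rank("genus") for e in taxonomy.microbes()
    }
    # strain-level trait per (strain, family)
    strain_trait: dict[tuple[str, str], bool] = {}
    for s in strains:
        gid = genus_by_strain[s]
        for fam in fam_ids:
            clade = truth.clade_traits[(gid, fam)]
            if rng.random() < cfg.trait_heritability:
                strain_trait[(s, fam)] = clade
            else:
                strain_trait[(s, fam)] = bool(rng.random() < cfg.clade_trait_prob)
    triples: list[TripleRecord] = []
    y0, y1 = cfg.year_range
    for s in strains:
        for m in mats:
            capable = strain_trait[(s, families[m])]
            p = cfg.capable_edge_prob if capable else cfg.base_edge_prob
            edge = bool(rng.random() < p)
            year = int(rng.integers(y0, y1 + 1)) if edge else None
            truth.draws[(s, m)] = (capable, edge, year)
            if capable:
                truth.capable_pairs.add((s, m))
            if edge:
                triples.append(TripleRecord(s, "synthesizes", m, year))
    return triples, truth


def generate_descriptions(g: KnowledgeGraph, truth: GroundTruth, cfg: SyntheticConfig) -> KnowledgeGraph:
    """Attach deterministic templated descriptions to every entity.

    Microbe texts name the lineage plus the element keywords of families the
    strain is capable of (plus seeded noise words); material texts name their
    constituent elements.  Same (config, seed) → same texts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    name_of = {sym: nm for sym, nm in ELEMENT_SYMBOLS}
    fam_of_pair: dict[str, set[str]] = {}
    for (s, m), (capable, _, _) in truth.draws.items():
        if capable:
            fam_of_pair.setdefault(s, set()).add(material_family(g, m))
    out = KnowledgeGraph(classes=dict(g.classes), triples=list(g.triples),
                         dedup_count=g.dedup_count)
    for e in sorted(g.entities.values(), key=lambda e: e.id):
        noise = " ".join(rng.choice(_NOISE_WORDS, size=2, replace=False))
        if e.cls == "Microorganism":
            gid = e.lineage_rank("genus") or "unknown-genus"
            fams = sorted(fam_of_pair.get(e.id, ()))
            words = " ".join(name_of.get(f, f) for f in fams) or "no reported metal"
            desc = (
                f"{noise} strain {e.label} of genus {gid} reported to reduce "
                f"{words} precursors into nanoparticles"
            )
        elif e.cls == "Material":
            elems = sorted(t.tail for t in g.triples
                           if t.relation == "composed_of" and t.head == e.id)
            lead = name_of.get(material_family(g, e.id), "metal")
            kind = "alloy" if len(elems) > 1 else "single metal"
            words = " ".join(name_of.get(s, s) for s in elems)
            desc = f"{lead} rich {kind} nanoparticle composed of {words}"
        elif e.cls in ("Metals", "Nonmetals"):
            desc = e.description or f"chemical element {e.label} symbol {e.id}"
        else:
            desc = f"{e.cls.lower()} taxon {e.label} {noise}"
        out.entities[e.id] = dataclasses.replace(e, description=desc)
    return out


def generate_dataset(cfg: SyntheticConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Full pipeline: taxonomy + materials + planted edges + descriptions."""
    cfg.validate()
    tax = generate_taxonomy(cfg)
    mat = generate_materials(cfg)
    g = KnowledgeGraph()
    g.classes.update(tax.classes)
    g.classes.update(mat.classes)
    g.entities.update(tax.entities)
    g.entities.update(mat.entities)
    g.add_triples(tax.triples + mat.triples, dedup=False)
    edges, truth = plant_synthesis_edges(tax, mat, cfg)
    g.add_triples(edges, dedup=False)
    g = generate_descriptions(g, truth, cfg)
    g.validate()
    return g, truth


def write_dataset(
    g: KnowledgeGraph, truth: GroundTruth, cfg: SyntheticConfig, out_dir: str | Path
) -> dict[str, str]:
    """Write entity/triple TSVs, Newick taxonomy, ground truth and config.

    Returns a manifest mapping role → file path; ``load_graph`` on the
    written tables round-trips the graph.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "entities": str(out / "entities.tsv"),
        "triples": str(out / "triples.tsv"),
        "taxonomy": str(out / "taxonomy.nwk"),
        "ground_truth": str(out / "ground_truth.tsv"),
        "config": str(out / "config.json"),
    }
    write_graph_tsv(g, manifest["entities"], manifest["triples"])
    export_taxonomy_newick(g, manifest["taxonomy"])
    rows = [
        {
            "microbe": s, "material": m, "capable": int(capable),
            "edge": int(edge), "year": "" if year is None else year,
        }
        for (s, m), (capable, edge, year) in sorted(truth.draws.items())
    ]
    pd.DataFrame(rows).to_csv(manifest["ground_truth"], sep="\t", index=False)
    Path(manifest["config"]).write_text(cfg.to_json())
    return manifest


def load_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"microbe": str, "material": str})
    truth = GroundTruth()
    for r in df.itertuples(index=False):
        year = None if pd.isna(r.year) else int(r.year)
        truth.draws[(r.microbe, r.material)] = (bool(r.capable), bool(r.edge), year)
        if r.capable:
            truth.capable_pairs.add((r.microbe, r.material))
    return truth
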