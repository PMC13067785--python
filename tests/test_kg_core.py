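"""Knowledge-graph loading, validation, splitting and serialization."""

import numpy as np
import pytest

from biosynkg.kg_core import (
    EntityRecord,
    KnowledgeGraph,
    OntologyClass,
    TripleRecord,
    ValidationError,
    export_ntriples,
    export_taxonomy_newick,
    genus_of,
    import_ntriples,
    load_graph,
    temporal_subgraph,
    write_graph_tsv,
)
from biosynkg.synthetic_data import SyntheticConfig, generate_dataset

from conftest import make_toy_graph


ENTITY_TSV = """id\tclass\tlabel\tdescription\tyear\tlineage
MR-1\tMicroorganism\tShewanella MR-1\telectroactive microbe\t\tgenus:Shewanella;strain:MR-1
Pd-NP\tMaterial\tPd\tpalladium nanoparticle\t\t
Pd\tMetals\tpalladium\t\t\t
"""

TRIPLE_TSV = """head\trelation\ttail\tyear
MR-1\tsynthesizes\tPd-NP\t2015
Pd-NP\tcomposed_of\tPd\t
"""


def write_files(tmp_path, entity_text=ENTITY_TSV, triple_text=TRIPLE_TSV):
    e, t = tmp_path / "entities.tsv", tmp_path / "triples.tsv"
    e.write_text(entity_text)
    t.write_text(triple_text)
    return e, t


class TestLoadGraph:
    def test_loads_toy_files(self, tmp_path):
        e, t = write_files(tmp_path)
        g = load_graph(e, t)
        assert len(g.entities) == 3
        assert len(g.triples) == 2
        assert g.dedup_count == 0

    def test_dangling_endpoint_names_offender(self, tmp_path):
        bad = TRIPLE_TSV + "MR-1\tsynthesizes\tX99\t2020\n"
        e, t = write_files(tmp_path, triple_text=bad)
        with pytest.raises(ValidationError, match="X99"):
            load_graph(e, t)

    def test_duplicate_triples_deduplicated_and_counted(self, tmp_path):
        dup = TRIPLE_TSV + "MR-1\tsynthesizes\tPd-NP\t2015\n"
        e, t = write_files(tmp_path, triple_text=dup)
        g = load_graph(e, t)
        assert len(g.triples) == 2
        assert g.dedup_count == 1

    def test_missing_file_fatal(self, tmp_path):
        e, t = write_files(tmp_path)
        with pytest.raises(FileNotFoundError):
            load_graph(tmp_path / "nope.tsv", t)

    def test_lineage_parsed(self, tmp_path):
        e, t = write_files(tmp_path)
        g = load_graph(e, t)
        assert g.entities["MR-1"].lineage == (("genus", "Shewanella"), ("strain", "MR-1"))

    def test_taxonomy_tsv_adds_parent_edges(self, tmp_path):
        extra = ENTITY_TSV + "Shew\tGenus\tShewanella\t\t\t\n"
        e, t = write_files(tmp_path, entity_text=extra)
        tax = tmp_path / "tax.tsv"
        tax.write_text("child\tparent\nMR-1\tShew\n")
        g = load_graph(e, t, tax)
        assert g.taxon_parent_map() == {"MR-1": "Shew"}


class TestInvariants:
    def test_lineage_ranks_must_descend(self):
        with pytest.raises(ValidationError):
            EntityRecord("x", "Microorganism",
                         lineage=(("strain", "a"), ("genus", "b")))

    def test_taxonomy_cycle_rejected(self, toy_graph):
        toy_graph.add_entity(EntityRecord("g1", "Genus"))
        toy_graph.add_triples([
            TripleRecord("MR-1", "taxon_parent", "g1"),
            TripleRecord("g1", "taxon_parent", "MR-1"),
        ])
        with pytest.raises(ValidationError, match="cycle"):
            toy_graph.validate()

    def test_unknown_class_rejected_on_add(self, toy_graph):
        with pytest.raises(ValidationError, match="unknown class"):
            toy_graph.add_entity(EntityRecord("q", "NotAClass"))


class TestTemporalSubgraph:
    def _graph_with_years(self, years):
        g = KnowledgeGraph()
        g.add_entity(EntityRecord("m", "Microorganism"))
        for i, y in enumerate(years):
            g.add_entity(EntityRecord(f"mat{i}", "Material"))
            g.add_triples([TripleRecord("m", "synthesizes", f"mat{i}", y)])
        g.validate()
        return g

    def test_before_keeps_strictly_earlier(self):
        g = self._graph_with_years([2015, 2018, 2019, 2020])
        out = temporal_subgraph(g, 2019, "before")
        assert len(out.triples_with("synthesizes")) == 2

    def test_from_keeps_cutoff_and_later(self):
        g = self._graph_with_years([2015, 2018, 2019, 2020])
        out = temporal_subgraph(g, 2019, "from")
        years = sorted(t.year for t in out.triples_with("synthesizes"))
        assert years == [2019, 2020]

    def test_cutoff_beyond_max_keeps_all(self):
        g = self._graph_with_years([2015, 2018, 2019, 2020])
        out = temporal_subgraph(g, 2050, "before")
        assert len(out.triples_with("synthesizes")) == 4

    def test_sides_partition_dated_edges(self):
        g = self._graph_with_years([2010, 2015, 2019, 2021, 2022])
        before = temporal_subgraph(g, 2019, "before")
        after = temporal_subgraph(g, 2019, "from")
        n = len(before.triples_with("synthesizes")) + len(after.triples_with("synthesizes"))
        assert n == 5

    def test_structural_triples_kept_both_sides(self, toy_graph):
        before = temporal_subgraph(toy_graph, 2000, "before")
        assert len(before.triples_with("composed_of")) == 1

    def test_all_undated_is_an_error(self):
        g = self._graph_with_years([None, None])
        with pytest.raises(ValidationError, match="year"):
            temporal_subgraph(g, 2019, "before")


class TestGenusOf:
    def test_from_lineage(self, toy_graph):
        assert genus_of(toy_graph, "MR-1") == "Shewanella"

    def test_none_when_unrecorded(self):
        g = KnowledgeGraph()
        g.add_entity(EntityRecord("m", "Microorganism"))
        assert genus_of(g, "m") is None

    def test_graph_walk_to_genus_class(self):
        g = KnowledgeGraph()
        g.add_entity(EntityRecord("gen", "Genus"))
        g.add_entity(EntityRecord("sp", "Species"))
        g.add_entity(EntityRecord("st", "Microorganism"))
        g.add_triples([
            TripleRecord("st", "taxon_parent", "sp"),
            TripleRecord("sp", "taxon_parent", "gen"),
        ])
        assert genus_of(g, "sp") == "gen"
        assert genus_of(g, "st") == "gen"

    def test_non_microbe_is_type_error(self, toy_graph):
        with pytest.raises(TypeError):
            genus_of(toy_graph, "Pd-NP")

    def test_constant_along_strain_species_path(self, synth_default):
        _, g, _ = synth_default
        for strain in g.microbes()[:8]:
            species = strain.lineage_rank("species")
            assert genus_of(g, strain.id) == genus_of(g, species)


class TestNTriples:
    def _minimal(self):
        g = KnowledgeGraph(classes={
            "Thing": OntologyClass("Thing", None),
            "Material": OntologyClass("Material", "Thing"),
            "Microorganism": OntologyClass("Microorganism", None),
            "Metals": OntologyClass("Metals", None),
        })
        g.add_entity(EntityRecord("m1", "Microorganism"))
        g.add_entity(EntityRecord("x1", "Material"))
        g.add_entity(EntityRecord("e1", "Metals"))
        g.add_triples([
            TripleRecord("m1", "synthesizes", "x1"),
            TripleRecord("x1", "composed_of", "e1"),
        ])
        return g

    def test_statement_count(self, tmp_path):
        # 1 subclass edge + 3 rdf:type + 2 domain triples = 6 statements
        n = export_ntriples(self._minimal(), tmp_path / "g.nt")
        assert n == 6

    def test_empty_graph_zero_statements(self, tmp_path):
        g = KnowledgeGraph(classes={"Thing": OntologyClass("Thing", None)})
        out = tmp_path / "empty.nt"
        assert export_ntriples(g, out) == 0
        assert out.exists()

    def test_quote_in_label_roundtrips(self, tmp_path):
        g = self._minimal()
        g.entities["m1"] = EntityRecord("m1", "Microorganism", label='say "cheese"')
        out = tmp_path / "q.nt"
        export_ntriples(g, out)
        back = import_ntriples(out)
        assert back.entities["m1"].label == 'say "cheese"'

    def test_structure_lossless_roundtrip(self, tmp_path):
        g = self._minimal()
        export_ntriples(g, tmp_path / "g.nt")
        back = import_ntriples(tmp_path / "g.nt")
        assert set(back.entities) == set(g.entities)
        assert {t.key() for t in back.triples} == {t.key() for t in g.triples}


class TestNewickExport:
    def test_balanced_counts(self, tmp_path):
        g = KnowledgeGraph()
        g.add_entity(EntityRecord("gen", "Genus"))
        triples = []
        for s in range(2):
            g.add_entity(EntityRecord(f"sp{s}", "Species"))
            triples.append(TripleRecord(f"sp{s}", "taxon_parent", "gen"))
            for t in range(2):
                g.add_entity(EntityRecord(f"sp{s}.st{t}", "Microorganism"))
                triples.append(TripleRecord(f"sp{s}.st{t}", "taxon_parent", f"sp{s}"))
        g.add_triples(triples)
        out = tmp_path / "tax.nwk"
        assert export_taxonomy_newick(g, out) == 4
        import dendropy
        trees = dendropy.TreeList.get(path=str(out), schema="newick")
        assert sum(len(t.leaf_nodes()) for t in trees) == 4

    def test_empty_taxonomy_errors(self, toy_graph, tmp_path):
        with pytest.raises(ValidationError):
            export_taxonomy_newick(toy_graph, tmp_path / "t.nwk")

    def test_generated_taxonomy_leaf_count_matches_config(self, synth_default, tmp_path):
        cfg, g, _ = synth_default
        assert export_taxonomy_newick(g, tmp_path / "t.nwk") == cfg.n_strains


class TestTsvRoundTrip:
    def test_write_then_load_preserves_counts_and_triples(self, tmp_path, synth_default):
        _, g, _ = synth_default
        e, t = tmp_path / "e.tsv", tmp_path / "t.tsv"
        write_graph_tsv(g, e, t)
        back = load_graph(e, t)
        assert len(back.entities) == len(g.entities)
        assert sorted(t.key() + (t.year,) for t in back.triples) == sorted(
            t.key() + (t.year,) for t in g.triples
        )
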