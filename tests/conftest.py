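import logging

import numpy as np
import pytest

from biosynkg.kg_core import (
    EntityRecord,
    KnowledgeGraph,
    TripleRecord,
)
from biosynkg.fusion_train import FusionModel, TrainConfig
from biosynkg.synthetic_data import SyntheticConfig, generate_dataset

logging.getLogger("biosynkg").setLevel(logging.ERROR)


def make_toy_graph() -> KnowledgeGraph:
    """One microbe, one material, one element; synthesizes + composed_of."""
    g = KnowledgeGraph()
    g.add_entity(EntityRecord("MR-1", "Microorganism", label="Shewanella MR-1",
                              description="electroactive strain reducing palladium",
                              lineage=(("genus", "Shewanella"), ("strain", "MR-1"))))
    g.add_entity(EntityRecord("Pd-NP", "Material", label="Pd",
                              description="palladium nanoparticle"))
    g.add_entity(EntityRecord("Pd", "Metals", label="palladium",
                              description="chemical element palladium"))
    g.add_triples([
        TripleRecord("MR-1", "synthesizes", "Pd-NP", 2015),
        TripleRecord("Pd-NP", "composed_of", "Pd"),
    ])
    g.validate()
    return g


@pytest.fixture
def toy_graph() -> KnowledgeGraph:
    return make_toy_graph()


@pytest.fixture(scope="session")
def synth_default():
    """Default-condition synthetic dataset (40 strains, 10 materials)."""
    cfg = SyntheticConfig(seed=7)
    g, truth = generate_dataset(cfg)
    return cfg, g, truth


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced dataset for the faster training tests."""
    return SyntheticConfig(
        n_phyla=2, n_genera_per_phylum=3, n_species_per_genus=2,
        n_strains_per_species=1, n_elements=4, n_materials=6,
        max_elements_per_material=2, seed=11,
    )


@pytest.fixture(scope="session")
def trained_small(small_cfg):
    """One trained model on a small planted dataset, shared across tests."""
    g, truth = generate_dataset(small_cfg)
    cfg = TrainConfig(seed=3, epochs=40, snapshot_start=10)
    model = FusionModel(g, cfg).fit()
    return g, truth, model


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
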