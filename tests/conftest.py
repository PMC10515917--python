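"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

from epilineage.phylo import LineageChain
from epilineage.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def chain():
    return LineageChain()


@pytest.fixture(scope="session")
def small_dataset():
    """50 GREs with a few planted substitutions and motif events."""
    cfg = SimulationConfig(
        seed=42, n_gres=50, n_genes=20, gre_length_range=(300, 500),
        n_motifs=4,
        planted_events=[("gre_1", "Human", 42, "A", "T"),
                        ("gre_2", "Ape", 10, "C", "G"),
                        ("gre_3", "Hominin", 100, "G", "A"),
                        ("gre_4", "GreatApe", 7, "T", "C"),
                        ("gre_5", "AfricanGreatApe", 55, "A", "C")],
        planted_motif_events=[("gre_10", "MOTIF_0", "Human", "gain"),
                              ("gre_11", "MOTIF_1", "Ape", "loss"),
                              ("gre_12", "MOTIF_2", "Hominin", "gain")],
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def linked_dataset():
    """Multiome-focused dataset with planted GRE-gene links and one RDG."""
    links = [(f"gre_{i}", f"gene_{i}", 0.8) for i in range(15)]
    rdg_links = [(f"gre_{100 + j}", "gene_50", 0.7) for j in range(8)]
    cfg = SimulationConfig(seed=7, n_gres=300, n_genes=60, n_pseudobulk=200,
                           planted_links=links + rdg_links)
    return simulate_dataset(cfg)
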