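import numpy as np
import pytest

from cyclerelax.alignment import CodonAlignment
from cyclerelax.simulate import SimulationConfig, build_labeled_tree, simulate_alignment
from cyclerelax.trees import LabeledTree

THREE_TAXON_NEWICK = "((A:0.1,B:0.2):0.15,C:0.3);"
THREE_TAXON_TRAITS = {"A": "monoecious", "B": "heteroecious", "C": "heteroecious"}


@pytest.fixture(scope="session")
def three_taxon_tree() -> LabeledTree:
    return LabeledTree.from_newick(THREE_TAXON_NEWICK, THREE_TAXON_TRAITS)


@pytest.fixture(scope="session")
def three_taxon_alignment() -> CodonAlignment:
    return CodonAlignment(("A", "B", "C"), ("ATGAAA", "ATGAAC", "ATGTTT"))


@pytest.fixture(scope="session")
def random_freqs() -> np.ndarray:
    pi = np.random.default_rng(0).dirichlet(np.ones(61))
    return pi / pi.sum()


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated 8-taxon, 120-codon ortholog under the default medians."""
    config = SimulationConfig(n_codons=120, seed=5)
    tree = build_labeled_tree(config)
    return tree, simulate_alignment(tree, config), config
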