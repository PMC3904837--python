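"""Shared fixtures: small hand-built trees and one simulated dataset."""

import pytest
from hypothesis import settings

from geodiv import Biome, BiomeStateTable, parse_newick
from geodiv.simulate import make_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def four_tip_tree():
    """((A:1,B:1):1,(C:1.5,D:1.5):0.5); height 2.0."""
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:1.5,B:1.5);")


def clade_ages(tree):
    """Map frozenset of descendant tip labels -> node age, for topology
    comparisons that ignore node ordering."""
    labels = tree.tip_labels
    desc = {}
    for i in range(tree.n_nodes):
        if i < tree.n_tips:
            desc[i] = frozenset([labels[i]])
        else:
            c1, c2 = tree.children[i]
            desc[i] = desc[c1] | desc[c2]
    return {desc[i]: tree.ages[i] for i in range(tree.n_nodes)}


@pytest.fixture(scope="session")
def oot_dataset():
    """One moderate simulated out-of-the-tropics dataset (shared)."""
    return make_dataset("out_of_tropics", seed=42, target_tips=150)


@pytest.fixture
def all_tropical_states():
    def make(tree):
        return BiomeStateTable({lab: Biome.TROPICAL for lab in tree.tip_labels})

    return make
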