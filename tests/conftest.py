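import numpy as np
import pytest

from trimevol.models import SelectionRegime
from trimevol.simulate import simulate_codon_alignment
from trimevol.trees import random_tree


@pytest.fixture(scope="session")
def tree12():
    """A 12-taxon tree with total length ~4 substitutions/codon."""
    return random_tree(12, np.random.default_rng(7), mean_branch=0.2)


@pytest.fixture(scope="session")
def m1a_regime():
    return SelectionRegime.m1a(0.7, 0.2, kappa=2.0)


@pytest.fixture(scope="session")
def m2a_regime():
    return SelectionRegime.m2a(0.6, 0.25, 0.2, 4.0, kappa=2.0)


@pytest.fixture(scope="session")
def null_alignment(tree12, m1a_regime):
    """200 codons simulated under the neutral-null regime on tree12."""
    return simulate_codon_alignment(tree12, m1a_regime, 200, seed=11)
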