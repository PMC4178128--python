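from fractions import Fraction

import pytest

from degenlib.genetic_code import VariantDistribution, amino_acid_distribution


@pytest.fixture(scope="session")
def nnn_dist():
    return amino_acid_distribution("NNN")


@pytest.fixture(scope="session")
def nnk_dist():
    return amino_acid_distribution("NNK")


@pytest.fixture(scope="session")
def nnm_dist():
    return amino_acid_distribution("NNM")


@pytest.fixture
def coin_dist():
    """Two variants, probability 1/2 each."""
    return VariantDistribution.from_probs({"A": Fraction(1, 2), "C": Fraction(1, 2)})
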