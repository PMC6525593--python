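import numpy as np
import pytest

from cladecord import TaxonSet, parse_newick, random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def abcde():
    return TaxonSet(list("ABCDE"))


@pytest.fixture
def tree5(abcde):
    return parse_newick("((A,B),(C,D),E);", abcde)


def make_random_trees(n, n_leaves, seed):
    """A list of independent random binary trees on a shared label set."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    return [random_tree(labels, rng) for _ in range(n)]
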