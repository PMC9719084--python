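import numpy as np
import pytest

from phyloniche import read_newick, simulate_tree


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


@pytest.fixture
def star8():
    labels = ",".join(f"t{i}:1" for i in range(8))
    return read_newick(f"({labels});")


@pytest.fixture
def tree64():
    return simulate_tree(64, seed=640)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def star_tree(n: int, length: float = 1.0):
    labels = ",".join(f"t{i}:{length}" for i in range(n))
    return read_newick(f"({labels});")
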