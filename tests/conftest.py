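import itertools

import numpy as np
import pytest

from paleomet.phylo import read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tree(rng, n_tips, height=10.0):
    """Random ultrametric tree (random topology and node ages), built as a
    Newick string independently of the package's simulators."""
    counter = itertools.count(1)

    def clade(n, age):
        if n == 1:
            return f"t{next(counter)}"
        n1 = int(rng.integers(1, n))
        n2 = n - n1
        a1 = 0.0 if n1 == 1 else float(rng.uniform(0.05, age))
        a2 = 0.0 if n2 == 1 else float(rng.uniform(0.05, age))
        return (
            f"({clade(n1, a1)}:{age - a1:.12f},{clade(n2, a2)}:{age - a2:.12f})"
        )

    h = float(rng.uniform(0.5, 1.5)) * height
    return read_newick(clade(n_tips, h) + ";")
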