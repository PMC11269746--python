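import numpy as np
import pytest

from convloss.trees import Phylogeny


@pytest.fixture
def two_tip_tree():
    """Symmetric two-tip tree with branch length 0.4 each."""
    return Phylogeny(["R", "a", "b"], [-1, 0, 0], [0.0, 0.4, 0.4])


@pytest.fixture
def balanced_4tip():
    """((a,b)i1,(c,d)i2)R with assorted branch lengths."""
    return Phylogeny(
        ["R", "i1", "a", "b", "i2", "c", "d"],
        [-1, 0, 1, 1, 0, 4, 4],
        [0.0, 0.3, 0.5, 0.2, 0.4, 0.6, 0.1],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
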