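import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from phylom import TraitTable, read_newick, yule_tree


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def caterpillar():
    return read_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def balanced8():
    return read_newick(
        "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
    )


@pytest.fixture
def gower_fixture():
    """4 species x 3 traits (continuous + nominal + ordinal), fully observed."""
    df = pd.DataFrame(
        {
            "size": [1.0, 3.0, 5.0, 2.0],
            "color": ["red", "blue", "red", "green"],
            "threat": [0.0, 1.0, 2.0, 1.0],  # low < med < high
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return TraitTable(
        df, {"size": "continuous", "color": "nominal", "threat": "ordinal"}
    )


def random_dm(tree, rng):
    """Random symmetric trait distance matrix over a tree's tips."""
    n = tree.n_tips
    x = rng.random((n, n))
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 0.0)
    return DistanceMatrix(x, ids=list(tree.tip_labels))


@pytest.fixture
def random_tree_factory():
    def make(n_tips, seed):
        return yule_tree(n_tips, 0.05, seed)

    return make
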