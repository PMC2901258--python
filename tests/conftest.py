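import numpy as np
import pytest

from divclock import DatedTree, RatedTree

# caterpillar with branching times {10, 7, 4, 2} below a crown age of 10
FIVE_TIP_NEWICK = "((((A:2,B:2):2,C:4):3,D:7):3,E:10);"

# caterpillar with branching times {12, 9, 7, 5, 3.5, 2, 1}
EIGHT_TIP_NEWICK = (
    "(((((((A:1,B:1):1,C:2):1.5,D:3.5):1.5,E:5):2,F:7):2,G:9):3,H:12);"
)


@pytest.fixture
def five_tip_tree() -> DatedTree:
    return DatedTree.from_string(FIVE_TIP_NEWICK)


@pytest.fixture
def eight_tip_tree() -> DatedTree:
    return DatedTree.from_string(EIGHT_TIP_NEWICK)


def make_rated(newick: str, rates_by_label: dict[str, float]) -> RatedTree:
    """Build a RatedTree assigning rates by tip label / internal clade key.

    Internal branches are keyed by the sorted, '|'-joined labels of the
    leaves below them.
    """
    dated = DatedTree.from_string(newick)
    rates = {}
    for node, _ in dated.branches():
        if node.is_leaf():
            key = node.taxon.label
        else:
            key = "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
        rates[node] = rates_by_label[key]
    return RatedTree(dated, rates)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
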