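import numpy as np
import pytest

from epiforest.trees import ExpressionTree, Node


def tree_from_sexp(nodes):
    """Build an ExpressionTree from a prefix list of (kind, value) pairs."""
    return ExpressionTree([Node(k, v) for k, v in nodes])


@pytest.fixture
def xor_tree():
    """XOR(GT(X1, 0), GT(X2, 0)): the canonical planted two-way interaction."""
    return tree_from_sexp(
        [("op", "XOR"),
         ("op", "GT"), ("feat", 0), ("const", 0),
         ("op", "GT"), ("feat", 1), ("const", 0)]
    )


@pytest.fixture
def identity_tree():
    """GT(X1, 0): a single-feature main effect."""
    return tree_from_sexp([("op", "GT"), ("feat", 0), ("const", 0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)
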