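import dendropy
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_tree():
    """Four equidistant tips: Brownian covariance proportional to identity."""
    return dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
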