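import numpy as np
import pytest

from museumdiv.phylo import as_chronogram, parse_tree


@pytest.fixture
def comb4():
    """Four-tip comb chronogram with node ages 3, 2, 1."""
    return as_chronogram(parse_tree("(((A:1,B:1):1,C:2):1,D:3);"))


@pytest.fixture
def balanced4():
    return as_chronogram(parse_tree("((A:1,B:1):2,(C:2,D:2):1);"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
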