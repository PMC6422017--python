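import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

sys.path.insert(0, str(Path(__file__).parent))

from cladesig.treeio import read_newick


@pytest.fixture
def caterpillar3():
    return read_newick("((A,B),C);")


@pytest.fixture
def balanced4():
    return read_newick("((A,B),(C,D));")


@pytest.fixture
def star4():
    return read_newick("(A,B,C,D);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
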