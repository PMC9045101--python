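import numpy as np
import pytest

from mica.io_formats import OTUTable, read_newick


@pytest.fixture
def three_taxon_tree():
    """((t1:1,t2:1):1,t3:2); patristic d(t1,t2)=2, d(t1,t3)=d(t2,t3)=4."""
    return read_newick("((t1:1,t2:1):1,t3:2);")


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 5, 0, 1],
            [8, 0, 3, 2],
            [0, 7, 6, 0],
        ]
    )
    return OTUTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
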