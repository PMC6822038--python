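import dendropy
import numpy as np
import pandas as pd
import pytest

from phyloniche import core_io
from phyloniche.core_io import TimeTree


def tree_of(newick: str) -> TimeTree:
    """Build a TimeTree straight from a Newick string."""
    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=True)
    return TimeTree(t, is_ultrametric=core_io._check_ultrametric(t))


@pytest.fixture
def tree3() -> TimeTree:
    """((A:1,B:1):1,C:2); — the smallest tree with shared history."""
    return tree_of("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def tree5() -> TimeTree:
    """A 5-tip ultrametric fixture with uneven topology."""
    return tree_of("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5):0;")


@pytest.fixture
def constant_raster():
    from phyloniche.core_io import ClimateRaster
    return ClimateRaster(np.full((10, 10), 7.0), (0.0, 0.0, 10.0, 10.0),
                         1.0, nodata=-9999.0, variable_id="BIO5")


@pytest.fixture
def occ_simple() -> pd.DataFrame:
    return pd.DataFrame({
        "species": ["a", "a", "b"],
        "lon": [1.5, 2.5, 3.5],
        "lat": [1.5, 2.5, 3.5],
    })
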