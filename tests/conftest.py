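import numpy as np
import pandas as pd
import pytest

from synteny3d import simdata
from synteny3d.hicmat import ContactMatrix


def make_matrix(values, resolution=1000, chrom="chr1"):
    """ContactMatrix from a dense array on a single chromosome."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    bins = pd.DataFrame({"chrom": chrom,
                         "start": np.arange(n) * resolution,
                         "end": (np.arange(n) + 1) * resolution})
    return ContactMatrix(bins, values, resolution)


@pytest.fixture
def small_genome():
    return simdata.simulate_ancestor(2, 100, 10_000, 50_000, seed=11)


@pytest.fixture
def toy_genome():
    return simdata.simulate_ancestor(1, 30, 10_000, 50_000, seed=5)
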