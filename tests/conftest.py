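import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sch5io.synthetic import make_synthetic_dataset


@pytest.fixture
def small_dataset():
    """A complete synthetic dataset exercising every component."""
    return make_synthetic_dataset(
        n_cells=60,
        n_genes=40,
        density=0.15,
        n_layers=2,
        n_reductions=2,
        n_graphs=2,
        with_spatial=True,
        with_raw=True,
        seed=7,
    )


@pytest.fixture
def tiny_frames():
    """Minimal X/obs/var triple for constructor tests."""
    X = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]]))
    obs = pd.DataFrame({"group": ["a", "b", "a"]}, index=["c0", "c1", "c2"])
    var = pd.DataFrame({"hv": [True, False]}, index=["g0", "g1"])
    return X, obs, var


def dense_triplet_oracle(dense, orientation):
    """Brute-force compressed-sparse encoding by scanning the dense matrix.

    Independent of the codec under test: walks rows (or columns) in order,
    collecting (index, value) pairs for nonzero entries and accumulating
    per-segment counts into indptr.
    """
    dense = np.asarray(dense)
    m, p = dense.shape
    major = m if orientation == "row-major" else p
    indptr = [0]
    indices = []
    values = []
    for i in range(major):
        line = dense[i, :] if orientation == "row-major" else dense[:, i]
        for j, v in enumerate(line):
            if v != 0:
                indices.append(j)
                values.append(v)
        indptr.append(len(values))
    return (
        np.asarray(indptr, dtype=np.int64),
        np.asarray(indices, dtype=np.int64),
        np.asarray(values),
    )
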