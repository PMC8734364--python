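"""Compressed-sparse triplet codec versus an independent dense-scan oracle."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sch5io.codecs import (
    COLUMN_MAJOR,
    ROW_MAJOR,
    MalformedSparseError,
    SparseTriplet,
    decode_sparse,
    encode_sparse,
)

from conftest import dense_triplet_oracle


def test_known_matrix_row_major_triplet():
    # [[1,0,2],[0,0,3]] scanned row by row: (0,1),(2,2) | (2,3)
    M = sp.csr_matrix(np.array([[1.0, 0.0, 2.0], [0.0, 0.0, 3.0]]))
    t = encode_sparse(M, ROW_MAJOR)
    np.testing.assert_array_equal(t.indptr, [0, 2, 3])
    np.testing.assert_array_equal(t.indices, [0, 2, 2])
    np.testing.assert_array_equal(t.values, [1.0, 2.0, 3.0])
    back = decode_sparse(t, ROW_MAJOR)
    np.testing.assert_array_equal(back.toarray(), M.toarray())


def test_zero_matrix_empty_triplet():
    t = encode_sparse(sp.csr_matrix((2, 3)), ROW_MAJOR)
    np.testing.assert_array_equal(t.indptr, [0, 0, 0])
    assert len(t.indices) == 0 and len(t.values) == 0
    assert decode_sparse(t).nnz == 0


@pytest.mark.parametrize("orientation,expected_len", [(ROW_MAJOR, 5), (COLUMN_MAJOR, 8)])
def test_indptr_length_follows_orientation(orientation, expected_len):
    # m×p with row-major indptr of m+1 and column-major of p+1
    M = sp.random(4, 7, density=0.3, random_state=0)
    t = encode_sparse(M, orientation)
    assert len(t.indptr) == expected_len


def test_explicit_zeros_are_dropped():
    M = sp.csr_matrix(np.array([[0.0, 5.0], [0.0, 0.0]]))
    M.data[0] = 0.0  # forge an explicit zero
    t = encode_sparse(M, ROW_MAJOR)
    assert t.nnz == 0


@pytest.mark.parametrize(
    "triplet_kwargs, match",
    [
        (dict(indptr=[0, 2], indices=[0, 1, 1], values=[1, 2, 3]), "indptr length"),
        (dict(indptr=[0, 2, 2], indices=[0, 1, 1], values=[1, 2, 3]), "terminal"),
        (dict(indptr=[1, 2, 3], indices=[0, 1, 1], values=[1, 2, 3]), "start at 0"),
        (dict(indptr=[0, 3, 2, 3], indices=[0, 1, 1], values=[1, 2, 3]), "indptr length"),
        (dict(indptr=[0, 2, 3], indices=[0, 9, 1], values=[1, 2, 3]), "out of bounds"),
        (dict(indptr=[0, 2, 3], indices=[0, 1], values=[1, 2, 3]), "length"),
    ],
)
def test_malformed_triplets_are_rejected(triplet_kwargs, match):
    t = SparseTriplet(
        indptr=np.asarray(triplet_kwargs["indptr"]),
        indices=np.asarray(triplet_kwargs["indices"]),
        values=np.asarray(triplet_kwargs["values"]),
        orientation=ROW_MAJOR,
        shape=(2, 3),
    )
    with pytest.raises(MalformedSparseError, match=match):
        decode_sparse(t)


def test_non_2d_input_rejected():
    with pytest.raises(ValueError, match="2-D"):
        encode_sparse(np.arange(5))


def _random_dense(rng, shape, density, dtype):
    dense = np.zeros(shape, dtype=dtype)
    total = shape[0] * shape[1]
    if total and density > 0:
        nnz = total if density >= 1.0 else rng.binomial(total, density)
        flat = rng.choice(total, size=nnz, replace=False)
        vals = rng.integers(1, 100, size=nnz)
        dense.flat[flat] = vals.astype(dtype)
    return dense


@pytest.mark.parametrize("orientation", [ROW_MAJOR, COLUMN_MAJOR])
@pytest.mark.parametrize("dtype", [np.int64, np.float64])
def test_codec_matches_dense_scan_oracle_randomized(orientation, dtype):
    """decode∘encode is the identity and the triplet equals a brute-force scan."""
    rng = np.random.default_rng(42 if dtype == np.int64 else 43)
    for _ in range(60):
        shape = (int(rng.integers(0, 50)), int(rng.integers(0, 50)))
        density = float(rng.choice([0.0, 0.01, 0.3, 1.0]))
        dense = _random_dense(rng, shape, density, dtype)
        t = encode_sparse(sp.csr_matrix(dense), orientation)
        o_indptr, o_indices, o_values = dense_triplet_oracle(dense, orientation)
        np.testing.assert_array_equal(t.indptr, o_indptr)
        np.testing.assert_array_equal(t.indices, o_indices)
        np.testing.assert_array_equal(t.values, o_values)
        # indptr differences are exactly the per-segment nonzero counts
        axis = 1 if orientation == ROW_MAJOR else 0
        np.testing.assert_array_equal(np.diff(t.indptr), (dense != 0).sum(axis=axis))
        back = decode_sparse(t, orientation)
        np.testing.assert_array_equal(back.toarray(), dense)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    dense=hnp.arrays(
        dtype=np.int64,
        shape=st.tuples(st.integers(0, 12), st.integers(0, 12)),
        elements=st.integers(-5, 5),
    ),
    flip=st.booleans(),
)
def test_orientation_flip_preserves_values(dense, flip):
    t = encode_sparse(sp.csr_matrix(dense), ROW_MAJOR if flip else COLUMN_MAJOR)
    a = decode_sparse(t, ROW_MAJOR)
    b = decode_sparse(t, COLUMN_MAJOR)
    np.testing.assert_array_equal(a.toarray(), dense)
    np.testing.assert_array_equal(b.toarray(), dense)


def test_scipy_csr_agrees_as_independent_cross_check():
    """scipy's own CSR arrays must match the codec's triplet (dual route)."""
    rng = np.random.default_rng(3)
    dense = _random_dense(rng, (23, 17), 0.2, np.float64)
    t = encode_sparse(sp.csr_matrix(dense), ROW_MAJOR)
    ref = sp.csr_matrix(dense)
    ref.sort_indices()
    np.testing.assert_array_equal(t.indptr, ref.indptr)
    np.testing.assert_array_equal(t.indices, ref.indices)
    np.testing.assert_array_equal(t.values, ref.data)
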