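"""Exact-equality assertions for datasets and an access-counting shim.

Round-trip identity is the format's core contract, so equality here is
strict: elementwise-exact matrices (dense vs sparse storage must also
match), frame equality including dtype, column order, index labels,
category level order and codes, and recursive structural equality for
nested mappings.
"""

from __future__ import annotations

import contextlib
from typing import Any

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import SingleCellDataset, is_loaded

__all__ = [
    "assert_matrices_equal",
    "assert_mappings_equal",
    "assert_datasets_equal",
    "record_dataset_reads",
]


def assert_matrices_equal(a, b, context: str = "matrix", exact_storage: bool = True) -> None:
    assert a.shape == b.shape, f"{context}: shape {a.shape} != {b.shape}"
    if exact_storage:
        assert sp.issparse(a) == sp.issparse(b), (
            f"{context}: storage kind differs (sparse={sp.issparse(a)} vs {sp.issparse(b)})"
        )
    da = a.toarray() if sp.issparse(a) else np.asarray(a)
    db = b.toarray() if sp.issparse(b) else np.asarray(b)
    assert da.dtype.kind == db.dtype.kind, f"{context}: dtype kind {da.dtype} != {db.dtype}"
    np.testing.assert_array_equal(da, db, err_msg=context)
    if sp.issparse(a) and sp.issparse(b):
        assert a.nnz == b.nnz, f"{context}: nnz {a.nnz} != {b.nnz}"


def _assert_leaf_equal(a: Any, b: Any, context: str) -> None:
    if isinstance(a, dict):
        assert_mappings_equal(a, b, context)
    elif isinstance(a, pd.DataFrame):
        assert isinstance(b, pd.DataFrame), f"{context}: {type(b).__name__} is not a DataFrame"
        pd.testing.assert_frame_equal(a, b, check_dtype=True, check_categorical=True)
    elif sp.issparse(a) or sp.issparse(b):
        assert_matrices_equal(a, b, context)
    elif isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        np.testing.assert_array_equal(np.asarray(a), np.asarray(b), err_msg=context)
    elif isinstance(a, float) and isinstance(b, float) and np.isnan(a) and np.isnan(b):
        pass
    else:
        assert type(a) is type(b) or (
            isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer))
        ), f"{context}: type {type(a).__name__} != {type(b).__name__}"
        assert a == b, f"{context}: {a!r} != {b!r}"


def assert_mappings_equal(a: dict, b: dict, context: str = "uns") -> None:
    assert isinstance(b, dict), f"{context}: expected dict, got {type(b).__name__}"
    assert set(a) == set(b), f"{context}: keys {sorted(a)} != {sorted(b)}"
    for key in a:
        _assert_leaf_equal(a[key], b[key], f"{context}[{key!r}]")


def assert_datasets_equal(
    a: SingleCellDataset,
    b: SingleCellDataset,
    slots: tuple[str, ...] = ("X", "rawX", "layers", "obs", "var", "dimR", "graphs", "uns", "spatial"),
    exact_storage: bool = True,
) -> None:
    """Assert component-wise exact equality on the requested slots."""
    for slot in slots:
        va, vb = getattr(a, slot), getattr(b, slot)
        assert is_loaded(va) == is_loaded(vb), f"{slot}: loaded state differs"
        if not is_loaded(va):
            continue
        if slot in ("X", "rawX"):
            if va is None or vb is None:
                assert va is None and vb is None, f"{slot}: presence differs"
            else:
                assert_matrices_equal(va, vb, slot, exact_storage)
        elif slot in ("layers", "graphs"):
            assert set(va) == set(vb), f"{slot}: keys {sorted(va)} != {sorted(vb)}"
            for k in va:
                assert_matrices_equal(va[k], vb[k], f"{slot}[{k!r}]", exact_storage)
        elif slot == "dimR":
            assert set(va) == set(vb), f"dimR: keys {sorted(va)} != {sorted(vb)}"
            for k in va:
                np.testing.assert_array_equal(
                    np.asarray(va[k]), np.asarray(vb[k]), err_msg=f"dimR[{k!r}]"
                )
        elif slot in ("obs", "var"):
            pd.testing.assert_frame_equal(va, vb, check_dtype=True, check_categorical=True)
        elif slot == "uns":
            assert_mappings_equal(va, vb)
        elif slot == "spatial":
            if va is None or vb is None:
                assert va is None and vb is None, "spatial: presence differs"
                continue
            np.testing.assert_array_equal(
                np.asarray(va.coordinates), np.asarray(vb.coordinates), err_msg="spatial.coordinates"
            )
            assert set(va.images) == set(vb.images), "spatial: image libraries differ"
            for lib in va.images:
                img_a, sf_a = va.images[lib]
                img_b, sf_b = vb.images[lib]
                np.testing.assert_array_equal(img_a, img_b, err_msg=f"spatial.images[{lib!r}]")
                assert_mappings_equal(dict(sf_a), dict(sf_b), f"spatial.scalefactors[{lib!r}]")


@contextlib.contextmanager
def record_dataset_reads(record: list[str]):
    """Context manager recording the HDF5 path of every dataset element read.

    Patches ``h5py.Dataset.__getitem__``; used to prove that a partial read
    never opens datasets outside the requested selection.
    """
    original = h5py.Dataset.__getitem__

    def counting(self, key):
        record.append(self.name)
        return original(self, key)

    h5py.Dataset.__getitem__ = counting
    try:
        yield record
    finally:
        h5py.Dataset.__getitem__ = original
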