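"""Bidirectional HDF5 payload codecs with attribute-driven type dispatch.

Every group or dataset written by this module carries exactly one
``datatype`` attribute drawn from a closed vocabulary; the decoder dispatches
on that attribute alone, which makes every file self-describing:

========== =============================================================
datatype    payload
========== =============================================================
Array       a dense numeric dataset (scalar, 1-D or 2-D)
SparseMatrix a group of three datasets ``indptr``/``indices``/``values``
DataFrame   a group with one dataset per column plus a ``category`` group
Mapping     a group whose children are any payloads (nested freely)
Category    the level vocabulary of one categorical column
String      a variable-length UTF-8 string dataset
Image       an H×W×C pixel array
========== =============================================================

Sparse matrices are serialized as the compressed-sparse triplet: for an
``m × p`` matrix with ``n`` explicit nonzeros, ``values`` holds the ``n``
entries collapsed by row (or column), ``indices`` the cross-dimension index
of each entry, and ``indptr`` — length ``m+1`` row-major or ``p+1``
column-major — delimits each row's (column's) slice.  ``indptr`` and
``indices`` are written as 64-bit integers unconditionally so that files
with > 2^31 nonzeros (million-cell atlases) never overflow.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping
from typing import Any, Literal

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SparseTriplet",
    "DATATYPE_ATTR",
    "DATATYPE_VOCABULARY",
    "ROW_MAJOR",
    "COLUMN_MAJOR",
    "encode_sparse",
    "decode_sparse",
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
    "write_mapping",
    "read_mapping",
    "write_array",
    "read_array",
    "MalformedSparseError",
    "CorruptCategoryError",
    "NameCollisionError",
    "UnsupportedLeafError",
]

DATATYPE_ATTR = "datatype"
DATATYPE_VOCABULARY = frozenset(
    {"Array", "SparseMatrix", "DataFrame", "Mapping", "Category", "String", "Image"}
)

ROW_MAJOR = "row-major"
COLUMN_MAJOR = "column-major"
Orientation = Literal["row-major", "column-major"]

_ENCODING_ATTR = "encoding"  # "boolean" | "category" on integer-backed datasets
_MISSING_MASK_ATTR = "missing-mask"
_INDEX_DATASET = "index"
_INDEX_NAME_ATTR = "index-name"
_COLUMN_ORDER_ATTR = "column-order"
_ORDERED_ATTR = "ordered"
_CATEGORY_GROUP = "category"

_STR_DTYPE = h5py.string_dtype(encoding="utf-8")


class MalformedSparseError(ValueError):
    """indptr/indices arrays violate the compressed-sparse invariants."""


class CorruptCategoryError(ValueError):
    """Category codes address levels outside the stored vocabulary."""


class NameCollisionError(ValueError):
    """A column name collides with the reserved index dataset."""


class UnsupportedLeafError(TypeError):
    """A mapping leaf has no payload encoding; the message names the path."""


# ---------------------------------------------------------------------------
# sparse triplet codec
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SparseTriplet:
    """On-disk sparse encoding: offset/index/value arrays plus orientation.

    ``indptr`` has length ``shape[0]+1`` when row-major and ``shape[1]+1``
    when column-major; within each segment the indices strictly increase
    (canonical form) and every index is below the cross dimension.
    """

    indptr: np.ndarray
    indices: np.ndarray
    values: np.ndarray
    orientation: Orientation
    shape: tuple[int, int]

    @property
    def nnz(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        """Raise :class:`MalformedSparseError` on any invariant violation."""
        m, p = self.shape
        major = m if self.orientation == ROW_MAJOR else p
        minor = p if self.orientation == ROW_MAJOR else m
        if len(self.indices) != len(self.values):
            raise MalformedSparseError(
                f"indices length {len(self.indices)} != values length {len(self.values)}"
            )
        if len(self.indptr) != major + 1:
            raise MalformedSparseError(
                f"indptr length {len(self.indptr)} != {major + 1} "
                f"for {self.orientation} shape {self.shape}"
            )
        if len(self.indptr) == 0 or self.indptr[0] != 0:
            raise MalformedSparseError("indptr must start at 0")
        if self.indptr[-1] != self.nnz:
            raise MalformedSparseError(
                f"indptr terminal {self.indptr[-1]} != nnz {self.nnz}"
            )
        if np.any(np.diff(self.indptr) < 0):
            raise MalformedSparseError("indptr is not non-decreasing")
        if self.nnz and (self.indices.min() < 0 or self.indices.max() >= minor):
            raise MalformedSparseError(
                f"indices out of bounds for cross dimension {minor}"
            )


def encode_sparse(M: "np.ndarray | sp.spmatrix", orientation: Orientation = ROW_MAJOR) -> SparseTriplet:
    """Convert a matrix to its canonical compressed-sparse triplet.

    Explicit zeros are dropped and duplicate entries summed, so the triplet
    is a pure function of the matrix's elementwise values.
    """
    if getattr(M, "ndim", None) != 2:
        raise ValueError(f"sparse encoding requires a 2-D matrix, got ndim={getattr(M, 'ndim', None)}")
    if orientation not in (ROW_MAJOR, COLUMN_MAJOR):
        raise ValueError(f"unknown orientation {orientation!r}")
    cls = sp.csr_matrix if orientation == ROW_MAJOR else sp.csc_matrix
    m = cls(M).copy()
    m.sum_duplicates()
    m.eliminate_zeros()
    m.sort_indices()
    return SparseTriplet(
        indptr=np.asarray(m.indptr, dtype=np.int64),
        indices=np.asarray(m.indices, dtype=np.int64),
        values=np.asarray(m.data),
        orientation=orientation,
        shape=(int(M.shape[0]), int(M.shape[1])),
    )


def decode_sparse(t: SparseTriplet, target_orientation: Orientation | None = None) -> sp.spmatrix:
    """Reconstruct the sparse matrix a triplet describes.

    Orientation conversion (row- to column-major or back) is exact on
    elementwise values.  Malformed triplets raise before any matrix is built.
    """
    t.validate()
    if t.orientation == ROW_MAJOR:
        m = sp.csr_matrix((t.values, t.indices, t.indptr), shape=t.shape)
    else:
        m = sp.csc_matrix((t.values, t.indices, t.indptr), shape=t.shape)
    if target_orientation is not None and target_orientation != t.orientation:
        m = m.tocsr() if target_orientation == ROW_MAJOR else m.tocsc()
    return m


# ---------------------------------------------------------------------------
# low-level array payloads
# ---------------------------------------------------------------------------


def _compress_kwargs(arr: np.ndarray, compression: int | None) -> dict:
    # gzip requires chunked storage, which zero-size datasets cannot have
    if compression is None or arr.size == 0 or arr.ndim == 0:
        return {}
    return {"compression": "gzip", "compression_opts": int(compression)}


def write_array(
    parent: h5py.Group,
    name: str,
    arr: Any,
    compression: int | None = None,
    datatype: str | None = None,
) -> h5py.Dataset:
    """Write a scalar or array leaf, preserving value type through decode.

    Strings become variable-length UTF-8 (datatype ``String``); booleans are
    stored as 8-bit integers with an ``encoding`` attribute; missing strings
    (None/NaN) become empty strings plus a sidecar mask attribute.  Numeric
    dtypes are stored as-is, so integers stay integers.
    """
    mask = None
    if isinstance(arr, (str, bytes, bool, np.bool_, int, float, np.number)):
        arr = np.asarray(arr)
    elif not isinstance(arr, np.ndarray):
        arr = np.asarray(arr)

    if arr.dtype == object or arr.dtype.kind in "US":
        flat = arr.ravel()
        isna = np.array([x is None or (isinstance(x, float) and np.isnan(x)) for x in flat.tolist()])
        if isna.any():
            mask = isna.astype(np.int8).reshape(arr.shape)
            flat = np.array(["" if bad else str(x) for bad, x in zip(isna, flat.tolist())], dtype=object)
        else:
            flat = np.array([str(x) for x in flat.tolist()], dtype=object)
        ds = parent.create_dataset(
            name, data=flat.reshape(arr.shape), dtype=_STR_DTYPE, **_compress_kwargs(arr, compression)
        )
        ds.attrs[DATATYPE_ATTR] = datatype or "String"
        if mask is not None:
            ds.attrs[_MISSING_MASK_ATTR] = mask
        return ds
    if arr.dtype.kind == "b":
        ds = parent.create_dataset(
            name, data=arr.astype(np.int8), **_compress_kwargs(arr, compression)
        )
        ds.attrs[DATATYPE_ATTR] = datatype or "Array"
        ds.attrs[_ENCODING_ATTR] = "boolean"
        return ds
    if arr.dtype.kind not in "iuf":
        raise UnsupportedLeafError(f"cannot encode array of dtype {arr.dtype} at {parent.name}/{name}")
    ds = parent.create_dataset(name, data=arr, **_compress_kwargs(arr, compression))
    ds.attrs[DATATYPE_ATTR] = datatype or "Array"
    return ds


def read_array(ds: h5py.Dataset) -> Any:
    """Inverse of :func:`write_array`; scalars come back as Python scalars."""
    value = ds[()]
    if ds.attrs.get(_ENCODING_ATTR) == "boolean":
        value = np.asarray(value).astype(bool)
        return bool(value[()]) if value.ndim == 0 else value
    if h5py.check_string_dtype(ds.dtype) is not None:
        arr = np.asarray(value)
        decoded = np.array(
            [x.decode("utf-8") if isinstance(x, bytes) else str(x) for x in arr.ravel().tolist()],
            dtype=object,
        ).reshape(arr.shape)
        mask = ds.attrs.get(_MISSING_MASK_ATTR)
        if decoded.ndim == 0:
            if mask is not None and bool(np.asarray(mask)):
                return None
            return decoded[()]
        if mask is not None:
            decoded = decoded.copy()
            decoded[np.asarray(mask).astype(bool)] = None
        return decoded
    arr = np.asarray(value)
    if arr.ndim == 0:
        return arr.item()
    return arr


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def write_matrix(
    parent: h5py.Group,
    name: str,
    M: "np.ndarray | sp.spmatrix",
    compression: int | None = None,
    orientation: Orientation = ROW_MAJOR,
) -> h5py.HLObject:
    """Write a 2-D matrix payload.

    Dense matrices are stored directly as one dataset with datatype
    ``Array``; sparse matrices become a group with datatype ``SparseMatrix``
    holding exactly the three datasets ``indptr``/``indices``/``values``,
    plus ``shape`` and ``orientation`` attributes.  The on-disk default is
    row-major (cell-major), matching the in-memory convention; the attribute
    makes the choice self-describing for column-major-native readers.
    """
    if sp.issparse(M):
        t = encode_sparse(M, orientation)
        grp = parent.create_group(name)
        grp.attrs[DATATYPE_ATTR] = "SparseMatrix"
        grp.attrs["shape"] = np.asarray(t.shape, dtype=np.int64)
        grp.attrs["orientation"] = t.orientation
        for part, arr in (("indptr", t.indptr), ("indices", t.indices), ("values", t.values)):
            d = grp.create_dataset(part, data=arr, **_compress_kwargs(arr, compression))
            d.attrs[DATATYPE_ATTR] = "Array"
        return grp
    arr = np.asarray(M)
    if arr.ndim != 2:
        raise ValueError(f"matrix payload must be 2-D, got shape {arr.shape}")
    if arr.dtype.kind not in "iuf":
        raise TypeError(f"matrix payload must be numeric, got dtype {arr.dtype}")
    ds = parent.create_dataset(name, data=arr, **_compress_kwargs(arr, compression))
    ds.attrs[DATATYPE_ATTR] = "Array"
    return ds


def read_sparse_payload(grp: h5py.Group, target_orientation: Orientation | None = None) -> sp.spmatrix:
    """Materialize a ``SparseMatrix`` group."""
    t = SparseTriplet(
        indptr=np.asarray(grp["indptr"][()]),
        indices=np.asarray(grp["indices"][()]),
        values=np.asarray(grp["values"][()]),
        orientation=str(grp.attrs.get("orientation", ROW_MAJOR)),
        shape=tuple(int(x) for x in grp.attrs["shape"]),
    )
    return decode_sparse(t, target_orientation)


def read_matrix(node: "h5py.Dataset | h5py.Group") -> "np.ndarray | sp.spmatrix":
    """Read back a matrix payload, dense or sparse, by datatype dispatch."""
    kind = node.attrs.get(DATATYPE_ATTR)
    if kind == "SparseMatrix" or (kind is None and isinstance(node, h5py.Group)):
        return read_sparse_payload(node, ROW_MAJOR)
    return np.asarray(node[()])


# ---------------------------------------------------------------------------
# annotated tables
# ---------------------------------------------------------------------------


def write_table(
    parent: h5py.Group, name: str, df: pd.DataFrame, compression: int | None = None
) -> h5py.Group:
    """Write an annotation DataFrame as a ``DataFrame`` group.

    Each column becomes one dataset keyed by the column name; the row labels
    go to the reserved ``index`` dataset (the original index name rides in an
    attribute) and a ``column-order`` attribute preserves ordering exactly.
    Categorical columns store their integer codes, with the level vocabulary
    — including unobserved levels, in original order — under the ``category``
    subgroup so that factors survive the round trip between ecosystems.
    Missing categories are code ``-1``, never a level.
    """
    if _INDEX_DATASET in df.columns:
        raise NameCollisionError(
            f"column {_INDEX_DATASET!r} collides with the reserved index dataset"
        )
    if df.columns.duplicated().any():
        raise NameCollisionError(f"duplicate column names: {df.columns[df.columns.duplicated()].tolist()}")
    grp = parent.create_group(name)
    grp.attrs[DATATYPE_ATTR] = "DataFrame"
    grp.attrs[_COLUMN_ORDER_ATTR] = np.array([str(c) for c in df.columns], dtype=object)
    grp.attrs[_INDEX_NAME_ATTR] = str(df.index.name) if df.index.name is not None else ""
    write_array(grp, _INDEX_DATASET, np.asarray(df.index), compression)
    cat_grp: h5py.Group | None = None
    for col in df.columns:
        series = df[col]
        if isinstance(series.dtype, pd.CategoricalDtype):
            if cat_grp is None:
                cat_grp = grp.create_group(_CATEGORY_GROUP)
                cat_grp.attrs[DATATYPE_ATTR] = "Mapping"
            codes = series.cat.codes.to_numpy(dtype=np.int64)
            ds = grp.create_dataset(str(col), data=codes, **_compress_kwargs(codes, compression))
            ds.attrs[DATATYPE_ATTR] = "Array"
            ds.attrs[_ENCODING_ATTR] = "category"
            levels = write_array(
                cat_grp, str(col), np.asarray(series.cat.categories), compression, datatype="Category"
            )
            levels.attrs[_ORDERED_ATTR] = np.int8(1 if series.cat.ordered else 0)
        else:
            write_array(grp, str(col), series.to_numpy(), compression)
    return grp


def read_table(
    grp: h5py.Group, columns: "list[str] | None" = None
) -> pd.DataFrame:
    """Inverse of :func:`write_table`.

    With *columns*, only the index and the named column datasets are opened
    (partial loading).  A file lacking the column-order attribute is decoded
    in lexicographic column order with a warning; codes addressing levels
    outside the stored vocabulary raise :class:`CorruptCategoryError`.
    """
    if _COLUMN_ORDER_ATTR in grp.attrs:
        order = [
            c.decode("utf-8") if isinstance(c, bytes) else str(c)
            for c in grp.attrs[_COLUMN_ORDER_ATTR]
        ]
    else:
        order = sorted(k for k in grp.keys() if k not in (_INDEX_DATASET, _CATEGORY_GROUP))
        warnings.warn(
            f"{grp.name}: missing column-order attribute; falling back to lexicographic order",
            UserWarning,
            stacklevel=2,
        )
    if columns is not None:
        missing = [c for c in columns if c not in order]
        if missing:
            raise KeyError(f"unknown columns {missing}; available: {order}")
        order = [c for c in order if c in set(columns)]
    index = read_array(grp[_INDEX_DATASET])
    index = pd.Index(np.asarray(index, dtype=object) if getattr(index, "dtype", None) == object else index)
    name_attr = grp.attrs.get(_INDEX_NAME_ATTR, "")
    if isinstance(name_attr, bytes):
        name_attr = name_attr.decode("utf-8")
    index.name = name_attr or None

    data: dict[str, Any] = {}
    for col in order:
        ds = grp[col]
        if ds.attrs.get(_ENCODING_ATTR) == "category":
            codes = np.asarray(ds[()], dtype=np.int64)
            levels_ds = grp[_CATEGORY_GROUP][col]
            levels = read_array(levels_ds)
            ordered = bool(levels_ds.attrs.get(_ORDERED_ATTR, 0))
            if codes.size and (codes.min() < -1 or codes.max() >= len(levels)):
                raise CorruptCategoryError(
                    f"{grp.name}/{col}: codes outside level range [−1, {len(levels) - 1}]"
                )
            dtype = pd.CategoricalDtype(categories=list(np.asarray(levels)), ordered=ordered)
            data[col] = pd.Categorical.from_codes(codes, dtype=dtype)
        else:
            data[col] = read_array(ds)
    df = pd.DataFrame(data, index=index, columns=order)
    return df


# ---------------------------------------------------------------------------
# nested mappings
# ---------------------------------------------------------------------------


def write_mapping(
    parent: h5py.Group, name: str, mapping: Mapping[str, Any], compression: int | None = None
) -> h5py.Group:
    """Write an arbitrarily nested string-keyed mapping.

    Leaves may be scalars (str/int/float/bool), 1-D or 2-D arrays, sparse
    matrices, DataFrames, or sub-mappings.  Anything else raises
    :class:`UnsupportedLeafError` naming the offending path.
    """
    grp = parent.create_group(name)
    grp.attrs[DATATYPE_ATTR] = "Mapping"
    for key, value in mapping.items():
        if not isinstance(key, str):
            raise TypeError(f"mapping keys must be strings, got {type(key).__name__} at {grp.name}")
        _write_leaf(grp, key, value, compression)
    return grp


def _write_leaf(grp: h5py.Group, key: str, value: Any, compression: int | None) -> None:
    if isinstance(value, Mapping):
        write_mapping(grp, key, value, compression)
    elif isinstance(value, pd.DataFrame):
        write_table(grp, key, value, compression)
    elif sp.issparse(value):
        write_matrix(grp, key, value, compression)
    elif isinstance(value, (str, bytes, bool, np.bool_, int, float, np.number)):
        write_array(grp, key, value, compression)
    elif isinstance(value, (list, tuple, np.ndarray, pd.Series, pd.Index)):
        arr = np.asarray(value)
        if arr.ndim > 2:
            raise UnsupportedLeafError(f"{grp.name}/{key}: arrays above 2-D are not supported")
        try:
            write_array(grp, key, arr, compression)
        except UnsupportedLeafError:
            raise UnsupportedLeafError(
                f"{grp.name}/{key}: cannot encode array of dtype {arr.dtype}"
            ) from None
    elif value is None:
        ds = grp.create_dataset(key, data=np.asarray("", dtype=_STR_DTYPE))
        ds.attrs[DATATYPE_ATTR] = "String"
        ds.attrs[_MISSING_MASK_ATTR] = np.int8(1)
    else:
        raise UnsupportedLeafError(
            f"{grp.name}/{key}: unsupported leaf type {type(value).__name__}"
        )


def read_mapping(grp: h5py.Group) -> dict[str, Any]:
    """Inverse of :func:`write_mapping`: dispatch each child on its datatype."""
    out: dict[str, Any] = {}
    for key in grp.keys():
        out[key] = read_payload(grp[key])
    return out


def read_payload(node: "h5py.Group | h5py.Dataset") -> Any:
    """Decode any payload node by its datatype attribute (total dispatch)."""
    kind = node.attrs.get(DATATYPE_ATTR)
    if isinstance(kind, bytes):
        kind = kind.decode("utf-8")
    if kind == "Mapping":
        return read_mapping(node)
    if kind == "DataFrame":
        return read_table(node)
    if kind == "SparseMatrix":
        return read_sparse_payload(node, ROW_MAJOR)
    if kind in ("Array", "String", "Category", "Image", None):
        if isinstance(node, h5py.Group):
            return read_mapping(node)
        value = read_array(node)
        if kind == "String" and node.ndim == 0 and node.attrs.get(_MISSING_MASK_ATTR) is not None:
            return None
        return value
    raise ValueError(f"{node.name}: unknown datatype attribute {kind!r}")
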