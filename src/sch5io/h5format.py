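"""The eight-group ``.h5`` single-cell file layout: writer, reader, validator.

Layout (every node self-describing via its ``datatype`` attribute)::

    /                       attrs: format-version, producer
    ├── data                X (required) and optional rawX, dense or sparse
    ├── layers              matrices sharing X's exact shape
    ├── obs                 cell annotation DataFrame (+ category levels)
    ├── var                 gene annotation DataFrame (+ category levels)
    ├── dimR                low-dimensional embeddings, cells × k
    ├── graphs              square sparse cell-affinity matrices
    ├── uns                 nested unstructured metadata
    └── spatial             tissue images, scale factors, spot coordinates

The eight top-level groups are always present; an absent component is an
empty group, so "exactly 8 groups" is a file invariant rather than a common
case.  Readers can materialize any subset of the file (a
:class:`PartialSpec`) without ever opening the excluded matrix datasets —
the point of the layout for million-cell files where one often needs the
cell annotations but not the counts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import h5py
import numpy as np

from . import codecs
from .codecs import DATATYPE_ATTR, DATATYPE_VOCABULARY, ROW_MAJOR
from .datamodel import (
    UNLOADED,
    InvalidDatasetError,
    SingleCellDataset,
    SpatialBundle,
    Unloaded,
    is_loaded,
    validate_dataset,
)

__all__ = [
    "GROUPS",
    "FORMAT_VERSION",
    "PartialSpec",
    "SchemaNode",
    "ValidationReport",
    "write_h5",
    "read_h5",
    "validate_h5",
    "list_contents",
    "format_tree",
    "ValidationFailureError",
    "UnknownKeyError",
    "NotHDF5Error",
]

GROUPS = ("data", "layers", "obs", "var", "dimR", "graphs", "uns", "spatial")
FORMAT_VERSION = "1.0"
_VERSION_ATTR = "format-version"
_PRODUCER_ATTR = "producer"
_ORIGINAL_NAME_ATTR = "original-name"
_UNLOADED_ATTR = "unloaded"
_RESERVED_DATA_KEYS = frozenset({"X", "rawX"})


class ValidationFailureError(ValueError):
    """A file failed schema validation; carries the full report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        errs = "; ".join(f"{p}: {m}" for p, s, m in report.findings if s == "error")
        super().__init__(f"file failed validation: {errs}")


class UnknownKeyError(KeyError):
    """A partial read requested a key the file does not contain."""


class NotHDF5Error(OSError):
    """The path does not point at a readable HDF5 file."""


@dataclasses.dataclass
class PartialSpec:
    """Declaration of which parts of a file to materialize on read.

    ``groups`` restricts to a subset of the eight top-level groups;
    ``obs_columns``/``var_columns`` restrict annotation columns; the
    ``*_keys`` fields restrict named entries of their group.  A default
    (empty) spec means "read everything".
    """

    groups: set[str] | None = None
    obs_columns: list[str] | None = None
    var_columns: list[str] | None = None
    layers_keys: list[str] | None = None
    dimR_keys: list[str] | None = None
    graphs_keys: list[str] | None = None

    def __post_init__(self) -> None:
        if self.groups is not None:
            self.groups = {str(g) for g in self.groups}
            unknown = self.groups - set(GROUPS)
            if unknown:
                raise ValueError(f"unknown groups {sorted(unknown)}; valid: {list(GROUPS)}")

    @property
    def is_everything(self) -> bool:
        return (
            self.groups is None
            and self.obs_columns is None
            and self.var_columns is None
            and self.layers_keys is None
            and self.dimR_keys is None
            and self.graphs_keys is None
        )

    def wants(self, group: str) -> bool:
        return self.groups is None or group in self.groups


@dataclasses.dataclass
class SchemaNode:
    """Typed description of one HDF5 node, for listing and validation."""

    path: str
    node_kind: str  # "group" | "dataset"
    datatype_attr: str
    dtype: str | None = None
    shape: tuple[int, ...] | None = None


@dataclasses.dataclass
class ValidationReport:
    """Findings of :func:`validate_h5`; ``ok`` iff no error-severity finding."""

    findings: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for _, sev, _ in self.findings)

    def error(self, path: str, message: str) -> None:
        self.findings.append((path, "error", message))

    def warning(self, path: str, message: str) -> None:
        self.findings.append((path, "warning", message))

    def __str__(self) -> str:
        if not self.findings:
            return "ok: no findings"
        lines = [f"{'ok' if self.ok else 'INVALID'}: {len(self.findings)} finding(s)"]
        lines += [f"  [{sev}] {path}: {msg}" for path, sev, msg in self.findings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def write_h5(
    ds: SingleCellDataset,
    path,
    *,
    compression: int | None = None,
    orientation: str = ROW_MAJOR,
) -> None:
    """Write a dataset to the eight-group ``.h5`` layout.

    The dataset is validated first; a file is only produced for a
    well-formed input.  ``data/X`` is written whenever X is loaded;
    ``data/rawX`` only when a raw matrix is present.  Unloaded slots (from a
    partial read) are written as empty groups marked with an ``unloaded``
    attribute so a later reader does not mistake them for empty components.
    """
    violations = validate_dataset(ds)
    if violations:
        raise InvalidDatasetError(violations)
    if is_loaded(ds.layers):
        bad = _RESERVED_DATA_KEYS & set(ds.layers)
        if bad:
            raise codecs.NameCollisionError(
                f"layer name(s) {sorted(bad)} collide with reserved data slots"
            )

    with h5py.File(path, "w") as f:
        f.attrs[_VERSION_ATTR] = FORMAT_VERSION
        f.attrs[_PRODUCER_ATTR] = "sch5io"

        data = f.create_group("data")
        data.attrs[DATATYPE_ATTR] = "Mapping"
        if is_loaded(ds.X):
            codecs.write_matrix(data, "X", ds.X, compression, orientation)
            if ds.rawX is not None and is_loaded(ds.rawX):
                codecs.write_matrix(data, "rawX", ds.rawX, compression, orientation)
        else:
            data.attrs[_UNLOADED_ATTR] = np.int8(1)

        layers = f.create_group("layers")
        layers.attrs[DATATYPE_ATTR] = "Mapping"
        if is_loaded(ds.layers):
            for name, m in ds.layers.items():
                codecs.write_matrix(layers, name, m, compression, orientation)
        else:
            layers.attrs[_UNLOADED_ATTR] = np.int8(1)

        for slot, name in ((ds.obs, "obs"), (ds.var, "var")):
            if is_loaded(slot):
                codecs.write_table(f, name, slot, compression)
            else:
                g = f.create_group(name)
                g.attrs[DATATYPE_ATTR] = "Mapping"
                g.attrs[_UNLOADED_ATTR] = np.int8(1)

        dimr = f.create_group("dimR")
        dimr.attrs[DATATYPE_ATTR] = "Mapping"
        if is_loaded(ds.dimR):
            for name, arr in ds.dimR.items():
                # keys normalized to lower case for deterministic matching
                # across ecosystems; the conventional spelling rides along
                node = codecs.write_matrix(dimr, name.lower(), np.asarray(arr, dtype=float), compression)
                node.attrs[_ORIGINAL_NAME_ATTR] = name
        else:
            dimr.attrs[_UNLOADED_ATTR] = np.int8(1)

        graphs = f.create_group("graphs")
        graphs.attrs[DATATYPE_ATTR] = "Mapping"
        if is_loaded(ds.graphs):
            import scipy.sparse as sp

            for name, m in ds.graphs.items():
                codecs.write_matrix(
                    graphs, name, m if sp.issparse(m) else sp.csr_matrix(m), compression, orientation
                )
        else:
            graphs.attrs[_UNLOADED_ATTR] = np.int8(1)

        if is_loaded(ds.uns):
            codecs.write_mapping(f, "uns", ds.uns, compression)
        else:
            g = f.create_group("uns")
            g.attrs[DATATYPE_ATTR] = "Mapping"
            g.attrs[_UNLOADED_ATTR] = np.int8(1)

        spatial = f.create_group("spatial")
        spatial.attrs[DATATYPE_ATTR] = "Mapping"
        if not is_loaded(ds.spatial):
            spatial.attrs[_UNLOADED_ATTR] = np.int8(1)
        elif ds.spatial is not None:
            # coordinates live here, not in obs; the attribute records the
            # table whose rows they index
            spatial.attrs["coordinates-of"] = "obs"
            if ds.spatial.coordinates is not None:
                coords = np.asarray(ds.spatial.coordinates, dtype=float)
                codecs.write_matrix(spatial, "coordinates", coords, compression)
            if ds.spatial.images:
                imgs = spatial.create_group("images")
                imgs.attrs[DATATYPE_ATTR] = "Mapping"
                for lib, (img, scalef) in ds.spatial.images.items():
                    lib_grp = imgs.create_group(lib)
                    lib_grp.attrs[DATATYPE_ATTR] = "Mapping"
                    arr = np.asarray(img)
                    d = lib_grp.create_dataset(
                        "image", data=arr, **codecs._compress_kwargs(arr, compression)
                    )
                    d.attrs[DATATYPE_ATTR] = "Image"
                    codecs.write_mapping(lib_grp, "scalefactors", dict(scalef), compression)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------


def _available(grp: h5py.Group) -> list[str]:
    return sorted(grp.keys())


def _check_keys(requested: Iterable[str] | None, grp: h5py.Group, what: str) -> None:
    if requested is None:
        return
    missing = [k for k in requested if k not in grp]
    if missing:
        raise UnknownKeyError(
            f"unknown {what} {missing}; available: {_available(grp)}"
        )


def read_h5(path, sel: PartialSpec | None = None) -> SingleCellDataset:
    """Read a ``.h5`` file, fully or partially.

    The file is first checked against the schema (structural checks only on
    this path — shapes, attributes, indptr lengths — so no matrix data is
    touched for excluded groups).  With an empty *sel* the result is the
    exact dataset that was written; with a restrictive *sel*, loaded slots
    equal the corresponding projection of a full read and everything else is
    the :data:`UNLOADED` sentinel.
    """
    sel = sel or PartialSpec()
    report = validate_h5(path, deep=False)
    if not report.ok:
        raise ValidationFailureError(report)

    with h5py.File(path, "r") as f:
        X: object = UNLOADED
        rawX: object = UNLOADED
        if sel.wants("data") and not f["data"].attrs.get(_UNLOADED_ATTR):
            X = codecs.read_matrix(f["data"]["X"])
            rawX = codecs.read_matrix(f["data"]["rawX"]) if "rawX" in f["data"] else None

        layers: object = UNLOADED
        if sel.wants("layers") and not f["layers"].attrs.get(_UNLOADED_ATTR):
            _check_keys(sel.layers_keys, f["layers"], "layer(s)")
            keys = sel.layers_keys if sel.layers_keys is not None else _available(f["layers"])
            layers = {k: codecs.read_matrix(f["layers"][k]) for k in keys}

        obs: object = UNLOADED
        if sel.wants("obs") and not f["obs"].attrs.get(_UNLOADED_ATTR):
            obs = codecs.read_table(f["obs"], columns=sel.obs_columns)
        var: object = UNLOADED
        if sel.wants("var") and not f["var"].attrs.get(_UNLOADED_ATTR):
            var = codecs.read_table(f["var"], columns=sel.var_columns)

        dimR: object = UNLOADED
        if sel.wants("dimR") and not f["dimR"].attrs.get(_UNLOADED_ATTR):
            _check_keys(sel.dimR_keys, f["dimR"], "reduction(s)")
            keys = sel.dimR_keys if sel.dimR_keys is not None else _available(f["dimR"])
            dimR = {}
            for k in keys:
                node = f["dimR"][k]
                name = node.attrs.get(_ORIGINAL_NAME_ATTR, k)
                if isinstance(name, bytes):
                    name = name.decode("utf-8")
                dimR[str(name)] = codecs.read_matrix(node)

        graphs: object = UNLOADED
        if sel.wants("graphs") and not f["graphs"].attrs.get(_UNLOADED_ATTR):
            _check_keys(sel.graphs_keys, f["graphs"], "graph(s)")
            keys = sel.graphs_keys if sel.graphs_keys is not None else _available(f["graphs"])
            graphs = {k: codecs.read_matrix(f["graphs"][k]) for k in keys}

        uns: object = UNLOADED
        if sel.wants("uns") and not f["uns"].attrs.get(_UNLOADED_ATTR):
            uns = codecs.read_mapping(f["uns"])

        spatial: object = UNLOADED
        if sel.wants("spatial") and not f["spatial"].attrs.get(_UNLOADED_ATTR):
            sgrp = f["spatial"]
            if len(sgrp) == 0:
                spatial = None
            else:
                coords = codecs.read_matrix(sgrp["coordinates"]) if "coordinates" in sgrp else None
                images: dict = {}
                if "images" in sgrp:
                    for lib in sgrp["images"]:
                        lib_grp = sgrp["images"][lib]
                        img = np.asarray(lib_grp["image"][()])
                        scalef = codecs.read_mapping(lib_grp["scalefactors"])
                        images[lib] = (img, scalef)
                spatial = SpatialBundle(images=images, coordinates=coords)

    if rawX is UNLOADED and X is not UNLOADED:
        rawX = None
    if spatial is not UNLOADED and isinstance(spatial, SpatialBundle) and spatial.coordinates is None and not spatial.images:
        spatial = None
    return SingleCellDataset(
        X=X, obs=obs, var=var, rawX=rawX, layers=layers,
        dimR=dimR, graphs=graphs, uns=uns, spatial=spatial,
    )


# ---------------------------------------------------------------------------
# validator
# ---------------------------------------------------------------------------


def _node_datatype(node) -> str | None:
    kind = node.attrs.get(DATATYPE_ATTR)
    if isinstance(kind, bytes):
        kind = kind.decode("utf-8")
    return kind


def _payload_shape(node) -> tuple[int, int] | None:
    """Shape of a matrix payload from metadata only (no element reads)."""
    kind = _node_datatype(node)
    if kind == "SparseMatrix":
        shp = node.attrs.get("shape")
        return None if shp is None else tuple(int(x) for x in shp)
    if isinstance(node, h5py.Dataset) and node.ndim == 2:
        return tuple(int(x) for x in node.shape)
    return None


def _check_sparse(node: h5py.Group, report: ValidationReport, deep: bool) -> None:
    path = node.name
    for part in ("indptr", "indices", "values"):
        if part not in node:
            report.error(path, f"sparse payload missing dataset {part!r}")
            return
    shp = node.attrs.get("shape")
    if shp is None:
        report.error(path, "sparse payload missing shape attribute")
        return
    m, p = (int(x) for x in shp)
    orientation = node.attrs.get("orientation", ROW_MAJOR)
    if isinstance(orientation, bytes):
        orientation = orientation.decode("utf-8")
    major, minor = (m, p) if orientation == ROW_MAJOR else (p, m)
    n_indptr = node["indptr"].shape[0] if node["indptr"].ndim else 0
    if n_indptr != major + 1:
        report.error(
            path,
            f"indptr length {n_indptr} != {major + 1} for {orientation} shape ({m}, {p})",
        )
    nnz = node["values"].shape[0] if node["values"].ndim else 0
    if node["indices"].shape != node["values"].shape:
        report.error(path, "indices and values lengths differ")
    if deep and n_indptr == major + 1:
        indptr = np.asarray(node["indptr"][()])
        if indptr.size and indptr[0] != 0:
            report.error(path, "indptr does not start at 0")
        if indptr.size and indptr[-1] != nnz:
            report.error(path, f"indptr terminal {indptr[-1]} != nnz {nnz}")
        if np.any(np.diff(indptr) < 0):
            report.error(path, "indptr is not non-decreasing")
        if nnz:
            indices = np.asarray(node["indices"][()])
            if indices.min() < 0 or indices.max() >= minor:
                report.error(path, f"indices out of bounds for cross dimension {minor}")


def _check_table(grp: h5py.Group, report: ValidationReport, deep: bool) -> None:
    if codecs._INDEX_DATASET not in grp:
        if not grp.attrs.get(_UNLOADED_ATTR) and _node_datatype(grp) == "DataFrame":
            report.error(grp.name, "table missing reserved 'index' dataset")
        return
    if not deep:
        return
    cat = grp.get(codecs._CATEGORY_GROUP)
    for col in grp:
        node = grp[col]
        if isinstance(node, h5py.Dataset) and node.attrs.get(codecs._ENCODING_ATTR) == "category":
            if cat is None or col not in cat:
                report.error(f"{grp.name}/{col}", "categorical column without stored levels")
                continue
            codes = np.asarray(node[()])
            n_levels = cat[col].shape[0]
            if codes.size and (codes.min() < -1 or codes.max() >= n_levels):
                report.error(
                    f"{grp.name}/{col}",
                    f"category codes outside level range [−1, {n_levels - 1}]",
                )


def validate_h5(path, deep: bool = True) -> ValidationReport:
    """Validate a file against the schema.

    Shallow checks read only structure — group presence, datatype
    attributes, dataset shapes and indptr lengths.  ``deep=True`` (default)
    additionally reads index arrays to check indptr monotonicity, index
    bounds and category-code ranges.
    """
    report = ValidationReport()
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise NotHDF5Error(f"{path}: not a readable HDF5 file ({exc})") from exc
    with f:
        present = set(f.keys())
        for g in GROUPS:
            if g not in present:
                report.error(f"/{g}", "required top-level group missing")
        for extra in sorted(present - set(GROUPS)):
            report.warning(f"/{extra}", "unknown top-level group")
        if _VERSION_ATTR in f.attrs:
            version = f.attrs[_VERSION_ATTR]
            if isinstance(version, bytes):
                version = version.decode("utf-8")
            major = str(version).split(".")[0]
            if major != FORMAT_VERSION.split(".")[0]:
                report.error("/", f"incompatible format version {version}")
            elif str(version) != FORMAT_VERSION:
                report.warning("/", f"newer format version {version}; reading best-effort")
        if "data" in present:
            data = f["data"]
            if "X" not in data and not data.attrs.get(_UNLOADED_ATTR):
                report.error("/data/X", "required primary matrix missing")

        def visit(name, node):
            kind = _node_datatype(node)
            if kind is None:
                report.error(f"/{name}", "missing datatype attribute")
            elif kind not in DATATYPE_VOCABULARY:
                report.error(f"/{name}", f"datatype {kind!r} not in vocabulary")
            if kind == "SparseMatrix" and isinstance(node, h5py.Group):
                _check_sparse(node, report, deep)

        f.visititems(visit)

        for name in ("obs", "var"):
            if name in f and isinstance(f[name], h5py.Group):
                _check_table(f[name], report, deep)
        x_shape = None
        if "data" in f and "X" in f["data"]:
            x_shape = _payload_shape(f["data"]["X"])
        if x_shape is not None and "layers" in f:
            for name in f["layers"]:
                shp = _payload_shape(f["layers"][name])
                if shp is not None and shp != x_shape:
                    report.error(f"/layers/{name}", f"shape {shp} != X shape {x_shape}")
        if "graphs" in f:
            for name in f["graphs"]:
                shp = _payload_shape(f["graphs"][name])
                if shp is not None and shp[0] != shp[1]:
                    report.error(f"/graphs/{name}", f"not square: shape {shp}")
                elif shp is not None and x_shape is not None and shp[0] != x_shape[0]:
                    report.error(
                        f"/graphs/{name}", f"side {shp[0]} != cell count {x_shape[0]}"
                    )
    return report


# ---------------------------------------------------------------------------
# listing
# ---------------------------------------------------------------------------


def list_contents(path) -> list[SchemaNode]:
    """Flat, path-ordered description of every node in the file."""
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise NotHDF5Error(f"{path}: not a readable HDF5 file ({exc})") from exc
    nodes: list[SchemaNode] = []
    with f:
        def visit(name, node):
            kind = _node_datatype(node) or "unknown"
            if isinstance(node, h5py.Dataset):
                nodes.append(
                    SchemaNode(f"/{name}", "dataset", kind, str(node.dtype), tuple(node.shape))
                )
            else:
                nodes.append(SchemaNode(f"/{name}", "group", kind))

        f.visititems(visit)
    nodes.sort(key=lambda n: n.path)
    return nodes


def format_tree(nodes: list[SchemaNode]) -> str:
    """Render a node list as an indented tree for terminal display."""
    lines = []
    for node in nodes:
        depth = node.path.count("/") - 1
        indent = "  " * depth
        label = node.path.rsplit("/", 1)[-1]
        if node.node_kind == "dataset":
            lines.append(f"{indent}{label}  [{node.datatype_attr}] {node.dtype} {node.shape}")
        else:
            lines.append(f"{indent}{label}/  [{node.datatype_attr}]")
    return "\n".join(lines)
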