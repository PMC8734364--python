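"""Canonical in-memory representation of a single-cell dataset.

The container is ecosystem-neutral and cell-major: rows of every matrix are
cells, columns of the primary matrix are genes.  Gene-major ecosystems
(e.g. R's SingleCellExperiment) transpose at their adapter boundary, never
here.  Tables are pandas DataFrames; a pandas ``Categorical`` column carries
its level vocabulary and integer codes (code ``-1`` marks a missing value and
is never a level).  Matrices are numpy arrays or scipy sparse matrices.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Matrix2D",
    "SpatialBundle",
    "SingleCellDataset",
    "Violation",
    "UNLOADED",
    "Unloaded",
    "new_dataset",
    "validate_dataset",
    "is_loaded",
    "ShapeMismatchError",
    "DuplicateIndexError",
    "InvalidDatasetError",
]

#: A two-dimensional numeric matrix, dense or sparse.  Dense and sparse forms
#: of the same matrix compare equal elementwise; sparse storage keeps only
#: explicit nonzeros.
Matrix2D = Union[np.ndarray, sp.spmatrix]


class ShapeMismatchError(ValueError):
    """A component's shape is inconsistent with the primary matrix."""


class DuplicateIndexError(ValueError):
    """A cell or gene index contains duplicate labels."""


class InvalidDatasetError(ValueError):
    """A dataset failed validation; carries the violation records."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"dataset invalid: {lines}")


class Unloaded:
    """Sentinel marking a slot skipped by a partial read.

    Distinct from ``None``/empty so downstream code cannot mistake
    "not loaded" for "not present".
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "<unloaded>"

    def __bool__(self) -> bool:
        return False


UNLOADED = Unloaded()


def is_loaded(slot: Any) -> bool:
    """True unless *slot* is the partial-read sentinel."""
    return slot is not UNLOADED


@dataclasses.dataclass
class SpatialBundle:
    """Spatial transcriptomics payload: tissue images plus spot positions.

    Parameters
    ----------
    images
        Mapping of library id to ``(image, scalefactors)`` where *image* is a
        nonnegative H×W×C array and *scalefactors* a flat mapping of floats
        (e.g. spot diameter, high-resolution scale factor).
    coordinates
        Dense ``(n_cells, 2)`` array of spot positions, one row per cell.
    """

    images: dict[str, tuple[np.ndarray, dict]] = dataclasses.field(default_factory=dict)
    coordinates: np.ndarray | None = None


@dataclasses.dataclass
class Violation:
    """One validation finding: which component broke which rule."""

    component: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"{self.component}: {self.rule} ({self.message})"


@dataclasses.dataclass
class SingleCellDataset:
    """The canonical bundle of single-cell information.

    Slots mirror the eight on-disk groups: the primary matrix ``X`` (cells ×
    genes) with an optional unprocessed ``rawX``, same-shape ``layers``,
    cell/gene annotation tables ``obs``/``var``, low-dimensional embeddings
    ``dimR``, square cell-affinity ``graphs``, a nested unstructured mapping
    ``uns`` and an optional ``spatial`` bundle.  Any slot may hold the
    :data:`UNLOADED` sentinel after a partial read.
    """

    X: Matrix2D | Unloaded
    obs: pd.DataFrame | Unloaded
    var: pd.DataFrame | Unloaded
    rawX: Matrix2D | Unloaded | None = None
    layers: dict[str, Matrix2D] | Unloaded = dataclasses.field(default_factory=dict)
    dimR: dict[str, np.ndarray] | Unloaded = dataclasses.field(default_factory=dict)
    graphs: dict[str, Matrix2D] | Unloaded = dataclasses.field(default_factory=dict)
    uns: dict[str, Any] | Unloaded = dataclasses.field(default_factory=dict)
    spatial: SpatialBundle | Unloaded | None = None

    @property
    def n_cells(self) -> int:
        if is_loaded(self.X):
            return int(self.X.shape[0])
        if is_loaded(self.obs):
            return len(self.obs)
        raise ValueError("cell count unavailable: X and obs both unloaded")

    @property
    def n_genes(self) -> int:
        if is_loaded(self.X):
            return int(self.X.shape[1])
        if is_loaded(self.var):
            return len(self.var)
        raise ValueError("gene count unavailable: X and var both unloaded")

    def __repr__(self) -> str:
        parts = []
        try:
            parts.append(f"n_cells={self.n_cells}, n_genes={self.n_genes}")
        except ValueError:
            parts.append("shape=unloaded")
        for name in ("layers", "dimR", "graphs", "uns"):
            slot = getattr(self, name)
            if is_loaded(slot) and slot:
                parts.append(f"{name}={sorted(slot)}")
        if is_loaded(self.rawX) and self.rawX is not None:
            parts.append("rawX")
        if is_loaded(self.spatial) and self.spatial is not None:
            parts.append("spatial")
        return f"SingleCellDataset({', '.join(parts)})"


def _shape(m: Matrix2D) -> tuple[int, int]:
    return int(m.shape[0]), int(m.shape[1])


def validate_dataset(ds: SingleCellDataset) -> list[Violation]:
    """Check every structural invariant; return a list of violations.

    Total function: never raises, an empty list means the dataset is
    well-formed.  Unloaded slots are skipped (their invariants were checked
    when the file was written).
    """
    out: list[Violation] = []
    n_cells = n_genes = None
    if is_loaded(ds.X):
        if getattr(ds.X, "ndim", 2) != 2:
            out.append(Violation("X", "not 2-D", f"ndim={ds.X.ndim}"))
            return out
        n_cells, n_genes = _shape(ds.X)

    if is_loaded(ds.obs):
        if not ds.obs.index.is_unique:
            dup = ds.obs.index[ds.obs.index.duplicated()][:3].tolist()
            out.append(Violation("obs", "duplicate index", f"e.g. {dup}"))
        if n_cells is None:
            n_cells = len(ds.obs)
        elif len(ds.obs) != n_cells:
            out.append(
                Violation("obs", "row count != cell count", f"{len(ds.obs)} vs {n_cells}")
            )
    if is_loaded(ds.var):
        if not ds.var.index.is_unique:
            dup = ds.var.index[ds.var.index.duplicated()][:3].tolist()
            out.append(Violation("var", "duplicate index", f"e.g. {dup}"))
        if n_genes is None:
            n_genes = len(ds.var)
        elif len(ds.var) != n_genes:
            out.append(
                Violation("var", "row count != gene count", f"{len(ds.var)} vs {n_genes}")
            )

    if is_loaded(ds.layers):
        for name, m in ds.layers.items():
            if n_cells is not None and _shape(m) != (n_cells, n_genes):
                out.append(
                    Violation(
                        f"layers[{name!r}]",
                        "shape != X shape",
                        f"{_shape(m)} vs {(n_cells, n_genes)}",
                    )
                )
    if is_loaded(ds.graphs):
        for name, m in ds.graphs.items():
            r, c = _shape(m)
            if r != c:
                out.append(Violation(f"graphs[{name!r}]", "not square", f"shape {(r, c)}"))
            elif n_cells is not None and r != n_cells:
                out.append(
                    Violation(f"graphs[{name!r}]", "side != cell count", f"{r} vs {n_cells}")
                )
    if is_loaded(ds.dimR):
        for name, m in ds.dimR.items():
            arr = np.asarray(m)
            if arr.ndim != 2 or arr.shape[1] < 1:
                out.append(Violation(f"dimR[{name!r}]", "not cells × k (k ≥ 1)", f"shape {arr.shape}"))
            elif n_cells is not None and arr.shape[0] != n_cells:
                out.append(
                    Violation(
                        f"dimR[{name!r}]", "row count != cell count", f"{arr.shape[0]} vs {n_cells}"
                    )
                )
    if is_loaded(ds.spatial) and ds.spatial is not None:
        coords = ds.spatial.coordinates
        if coords is not None:
            coords = np.asarray(coords)
            if n_cells is not None and coords.shape[0] != n_cells:
                out.append(
                    Violation(
                        "spatial.coordinates",
                        "row count != cell count",
                        f"{coords.shape[0]} vs {n_cells}",
                    )
                )
        for lib, (img, _sf) in ds.spatial.images.items():
            if np.asarray(img).min(initial=0) < 0:
                out.append(Violation(f"spatial.images[{lib!r}]", "negative pixel values", ""))
    return out


def new_dataset(
    X: Matrix2D,
    obs: pd.DataFrame,
    var: pd.DataFrame,
    *,
    rawX: Matrix2D | None = None,
    layers: Mapping[str, Matrix2D] | None = None,
    dimR: Mapping[str, np.ndarray] | None = None,
    graphs: Mapping[str, Matrix2D] | None = None,
    uns: Mapping[str, Any] | None = None,
    spatial: SpatialBundle | None = None,
) -> SingleCellDataset:
    """Build a validated :class:`SingleCellDataset`.

    Raises
    ------
    ShapeMismatchError
        If any component's shape is inconsistent with ``X`` (the message
        names the offending component).
    DuplicateIndexError
        If ``obs`` or ``var`` carries duplicate row labels.
    InvalidDatasetError
        For any other invariant violation.
    """
    ds = SingleCellDataset(
        X=X,
        obs=obs,
        var=var,
        rawX=rawX,
        layers=dict(layers or {}),
        dimR={k: np.asarray(v) for k, v in (dimR or {}).items()},
        graphs=dict(graphs or {}),
        uns=dict(uns or {}),
        spatial=spatial,
    )
    violations = validate_dataset(ds)
    if violations:
        if any("duplicate index" in v.rule for v in violations):
            raise DuplicateIndexError(str(violations[0]))
        if any("shape" in v.rule or "count" in v.rule or "square" in v.rule for v in violations):
            raise ShapeMismatchError("; ".join(str(v) for v in violations))
        raise InvalidDatasetError(violations)
    return ds
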