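"""Converters to neighboring on-disk formats and a small IO benchmark.

The ``.h5ad`` pathway maps slots one-to-one onto the AnnData container
(Scanpy's native format): X↔X, rawX↔raw, layers↔layers, obs/var↔obs/var,
embeddings↔``obsm['X_<name>']``, graphs↔``obsp``, uns↔uns, and the spatial
bundle onto the Visium convention (``obsm['spatial']`` coordinates plus
``uns['spatial'][library_id]``).  Entries with no counterpart slot are
preserved under a reserved ``uns`` namespace instead of being dropped, so
conversion is never destructive.

MatrixMarket export writes the standard 1-based coordinate file with TSV
sidecars for the cell/gene annotation tables; a small JSON sidecar records
column dtypes and category level order, which plain TSV cannot carry.

Conversion from R's ``.rds`` serialization requires the companion module in
the R ecosystem and is not available here.
"""

from __future__ import annotations

import json
import time
import tracemalloc
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import SingleCellDataset, SpatialBundle, is_loaded, new_dataset

__all__ = [
    "from_h5ad",
    "to_h5ad",
    "export_mtx",
    "import_mtx",
    "benchmark_io",
    "rds_not_supported",
    "CompanionModuleRequiredError",
    "UNMAPPED_KEY",
]

#: reserved uns namespace for slots that have no counterpart in the target
UNMAPPED_KEY = "interop-unmapped"


class CompanionModuleRequiredError(NotImplementedError):
    """Raised for `.rds` pathways, which live in the companion R module."""


def rds_not_supported(path) -> None:
    raise CompanionModuleRequiredError(
        f"{path}: '.rds' conversion requires the companion R module; "
        "convert to '.h5' on the R side first"
    )


# ---------------------------------------------------------------------------
# .h5ad
# ---------------------------------------------------------------------------


def _plain(value):
    """Recursively strip AnnData's mapping views down to plain dicts/arrays."""
    if isinstance(value, pd.DataFrame):
        return value.copy()
    if hasattr(value, "keys") and not isinstance(value, (str, bytes)):
        try:
            return {str(k): _plain(value[k]) for k in value.keys()}
        except TypeError:
            pass
    if isinstance(value, np.generic):
        return value.item()
    return value


def to_h5ad(ds: SingleCellDataset, path) -> None:
    """Write a dataset as an ``.h5ad`` file (AnnData on-disk format)."""
    for slot in ("X", "obs", "var"):
        if not is_loaded(getattr(ds, slot)):
            raise ValueError(f"cannot export to .h5ad: slot {slot!r} was not loaded")
    obsm = {}
    uns = {k: v for k, v in ds.uns.items()} if is_loaded(ds.uns) else {}
    if is_loaded(ds.dimR):
        for name, arr in ds.dimR.items():
            obsm[f"X_{name}"] = np.asarray(arr)
    if is_loaded(ds.spatial) and ds.spatial is not None:
        if ds.spatial.coordinates is not None:
            obsm["spatial"] = np.asarray(ds.spatial.coordinates)
        if ds.spatial.images:
            uns_spatial = {}
            for lib, (img, scalef) in ds.spatial.images.items():
                uns_spatial[lib] = {
                    "images": {"hires": np.asarray(img)},
                    "scalefactors": dict(scalef),
                }
            uns["spatial"] = uns_spatial
    adata = ad.AnnData(
        X=ds.X,
        obs=ds.obs.copy(),
        var=ds.var.copy(),
        layers={k: v for k, v in ds.layers.items()} if is_loaded(ds.layers) else None,
        obsm=obsm or None,
        obsp={k: sp.csr_matrix(v) for k, v in ds.graphs.items()}
        if is_loaded(ds.graphs) and ds.graphs
        else None,
        uns=uns or None,
    )
    if is_loaded(ds.rawX) and ds.rawX is not None:
        raw_var = pd.DataFrame(index=ds.var.index) if ds.rawX.shape[1] == ds.X.shape[1] else None
        if raw_var is None:
            raw_var = pd.DataFrame(index=[f"raw_gene_{i}" for i in range(ds.rawX.shape[1])])
        adata.raw = ad.AnnData(X=ds.rawX, obs=pd.DataFrame(index=ds.obs.index), var=raw_var)
    # keep str columns as strings: silent str→categorical coercion would
    # break round-trip identity on obs/var dtypes
    adata.write_h5ad(Path(path), convert_strings_to_categoricals=False)


def from_h5ad(path) -> SingleCellDataset:
    """Read an ``.h5ad`` file into the canonical dataset.

    ``obsm`` entries named ``X_<name>`` become embeddings keyed ``<name>``;
    ``obsm['spatial']`` plus ``uns['spatial']`` reassemble the spatial
    bundle; anything else in ``obsm`` is kept under
    ``uns[UNMAPPED_KEY]['obsm']`` with a warning rather than dropped.
    """
    try:
        adata = ad.read_h5ad(Path(path))
    except Exception as exc:
        raise OSError(f"{path}: unreadable or schema-violating .h5ad file ({exc})") from exc

    dimR: dict[str, np.ndarray] = {}
    spatial_coords = None
    unmapped_obsm: dict[str, np.ndarray] = {}
    for key in adata.obsm.keys():
        arr = np.asarray(adata.obsm[key])
        if key == "spatial":
            spatial_coords = arr
        elif key.startswith("X_"):
            dimR[key[2:]] = arr
        else:
            unmapped_obsm[key] = arr

    uns = _plain(adata.uns) if adata.uns is not None else {}
    images: dict = {}
    uns_spatial = uns.pop("spatial", None)
    if isinstance(uns_spatial, dict):
        for lib, entry in uns_spatial.items():
            imgs = entry.get("images", {}) if isinstance(entry, dict) else {}
            scalef = entry.get("scalefactors", {}) if isinstance(entry, dict) else {}
            for _img_key, img in imgs.items():
                images[lib] = (np.asarray(img), dict(scalef))
                break
    elif uns_spatial is not None:
        uns["spatial"] = uns_spatial

    if unmapped_obsm:
        warnings.warn(
            f"obsm entries {sorted(unmapped_obsm)} have no canonical slot; "
            f"preserved under uns[{UNMAPPED_KEY!r}]",
            UserWarning,
            stacklevel=2,
        )
        uns.setdefault(UNMAPPED_KEY, {})["obsm"] = unmapped_obsm

    spatial = None
    if spatial_coords is not None or images:
        spatial = SpatialBundle(images=images, coordinates=spatial_coords)

    rawX = None
    if adata.raw is not None:
        rawX = adata.raw.X
        if sp.issparse(rawX):
            rawX = sp.csr_matrix(rawX)

    X = adata.X
    if sp.issparse(X):
        X = sp.csr_matrix(X)
    return new_dataset(
        X,
        adata.obs.copy(),
        adata.var.copy(),
        rawX=rawX,
        layers={k: (sp.csr_matrix(v) if sp.issparse(v) else np.asarray(v)) for k, v in adata.layers.items()},
        dimR=dimR,
        graphs={k: sp.csr_matrix(adata.obsp[k]) for k in adata.obsp.keys()},
        uns=uns,
        spatial=spatial,
    )


# ---------------------------------------------------------------------------
# MatrixMarket
# ---------------------------------------------------------------------------

_MTX_FILE = "matrix.mtx"
_OBS_FILE = "obs.tsv"
_VAR_FILE = "var.tsv"
_META_FILE = "columns.json"


def _column_meta(df: pd.DataFrame) -> dict:
    meta: dict = {"index_name": df.index.name, "columns": {}}
    for col in df.columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            meta["columns"][str(col)] = {
                "kind": "category",
                "categories": [str(c) for c in s.cat.categories],
                "ordered": bool(s.cat.ordered),
            }
        elif s.dtype.kind == "b":
            meta["columns"][str(col)] = {"kind": "bool"}
        elif s.dtype.kind in "iu":
            meta["columns"][str(col)] = {"kind": "int"}
        elif s.dtype.kind == "f":
            meta["columns"][str(col)] = {"kind": "float"}
        else:
            meta["columns"][str(col)] = {"kind": "str"}
    return meta


def _apply_column_meta(df: pd.DataFrame, meta: dict) -> pd.DataFrame:
    df = df.copy()
    df.index = df.index.astype(str)
    df.index.name = meta.get("index_name")
    for col, info in meta.get("columns", {}).items():
        kind = info["kind"]
        if kind == "category":
            dtype = pd.CategoricalDtype(info["categories"], ordered=info["ordered"])
            raw = df[col].where(df[col].notna(), None).tolist()
            vals = np.array([None if v is None else str(v) for v in raw], dtype=object)
            df[col] = pd.Categorical(vals, dtype=dtype)
        elif kind == "bool":
            df[col] = df[col].astype(bool)
        elif kind == "int":
            df[col] = df[col].astype(np.int64)
        elif kind == "float":
            df[col] = df[col].astype(np.float64)
        else:
            df[col] = df[col].astype(object).astype(str)
    return df[list(meta.get("columns", {}).keys())]


def export_mtx(ds: SingleCellDataset, directory) -> None:
    """Write X as a 1-based MatrixMarket coordinate file with TSV sidecars.

    The header's three integers are rows, columns and the explicit nonzero
    count.  ``obs.tsv``/``var.tsv`` carry the annotation tables (index in
    the first column); ``columns.json`` records dtypes and category levels
    so the tables re-import exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = ds.X if sp.issparse(ds.X) else sp.coo_matrix(np.asarray(ds.X))
    scipy.io.mmwrite(directory / _MTX_FILE, sp.coo_matrix(X))
    ds.obs.to_csv(directory / _OBS_FILE, sep="\t")
    ds.var.to_csv(directory / _VAR_FILE, sep="\t")
    meta = {"obs": _column_meta(ds.obs), "var": _column_meta(ds.var)}
    (directory / _META_FILE).write_text(json.dumps(meta, indent=1))


def import_mtx(directory) -> SingleCellDataset:
    """Inverse of :func:`export_mtx` on the X/obs/var slots."""
    directory = Path(directory)
    mtx = directory / _MTX_FILE
    if not mtx.exists():
        candidates = sorted(directory.glob("*.mtx"))
        if not candidates:
            raise FileNotFoundError(f"no MatrixMarket file in {directory}")
        mtx = candidates[0]
    try:
        X = sp.csr_matrix(scipy.io.mmread(mtx))
    except ValueError as exc:
        raise ValueError(f"{mtx}: malformed MatrixMarket header ({exc})") from exc
    obs = pd.read_csv(directory / _OBS_FILE, sep="\t", index_col=0, keep_default_na=True)
    var = pd.read_csv(directory / _VAR_FILE, sep="\t", index_col=0, keep_default_na=True)
    meta_path = directory / _META_FILE
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        obs = _apply_column_meta(obs, meta["obs"])
        var = _apply_column_meta(var, meta["var"])
    return new_dataset(X, obs, var)


# ---------------------------------------------------------------------------
# IO benchmark
# ---------------------------------------------------------------------------


def benchmark_io(
    ds_sizes=((2000, 1000, 0.05),),
    formats=("h5", "mtx"),
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure write/read wall time and peak memory per format.

    Datasets are generated deterministically from *seed* at each
    ``(n_cells, n_genes, density)`` size.  Timing reps run untraced; one
    extra instrumented rep per (format, direction) records peak memory via
    ``tracemalloc`` so the tracer never distorts the timings.  Returns a
    tidy frame with one row per (size, format, direction); downstream
    assertions should compare orderings, never absolute values.
    """
    import tempfile

    from . import h5format
    from .synthetic import make_synthetic_dataset

    rows = []
    for n_cells, n_genes, density in ds_sizes:
        ds = make_synthetic_dataset(
            n_cells=n_cells,
            n_genes=n_genes,
            density=density,
            n_layers=0,
            n_reductions=0,
            n_graphs=0,
            with_spatial=False,
            with_raw=False,
            seed=seed,
        )
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            for fmt in formats:
                if fmt == "h5":
                    target = tmp / "bench.h5"
                    write = lambda: h5format.write_h5(ds, target)
                    read = lambda: h5format.read_h5(target)
                elif fmt == "h5ad":
                    target = tmp / "bench.h5ad"
                    write = lambda: to_h5ad(ds, target)
                    read = lambda: from_h5ad(target)
                elif fmt == "mtx":
                    target = tmp / "bench_mtx"
                    write = lambda: export_mtx(ds, target)
                    read = lambda: import_mtx(target)
                else:
                    raise ValueError(f"unknown benchmark format {fmt!r}")

                for direction, fn in (("write", write), ("read", read)):
                    times = []
                    for _ in range(reps):
                        t0 = time.perf_counter()
                        fn()
                        times.append(time.perf_counter() - t0)
                    tracemalloc.start()
                    fn()
                    _, peak = tracemalloc.get_traced_memory()
                    tracemalloc.stop()
                    rows.append(
                        {
                            "n_cells": n_cells,
                            "n_genes": n_genes,
                            "density": density,
                            "format": fmt,
                            "direction": direction,
                            "median_time_s": float(np.median(times)),
                            "peak_mem_mb": peak / 1e6,
                        }
                    )
    return pd.DataFrame(rows)
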