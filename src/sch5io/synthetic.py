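"""Deterministic synthetic single-cell datasets for tests and benchmarks.

The generator emulates the *shape* of real droplet scRNA-seq data — a
sparse nonnegative-integer count matrix with negative-binomial-like values,
categorical cell/gene annotations (including unobserved factor levels, the
hard case for serialization), 2-D embeddings, a symmetric k-nearest-neighbor
affinity graph, nested plotting metadata and a small spatial bundle.  It
makes no biological claims: there are no gene modules, batches or
trajectories, only the container structure a format must carry losslessly.
"""

from __future__ import annotations

import shutil

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import SingleCellDataset, SpatialBundle, new_dataset

__all__ = ["make_synthetic_dataset", "make_corrupt_corpus"]


def _nb_counts(rng: np.random.Generator, size: int, dtype) -> np.ndarray:
    # negative binomial shifted to exclude zero: explicit zeros would vanish
    # from the sparse structure and break nnz accounting
    vals = rng.negative_binomial(2, 0.3, size=size).astype(np.int64) + 1
    return vals.astype(dtype)


def _random_counts(
    rng: np.random.Generator, n_rows: int, n_cols: int, density: float, dtype
) -> sp.csr_matrix:
    total = n_rows * n_cols
    nnz = int(rng.binomial(total, density)) if total and density > 0 else 0
    flat = rng.choice(total, size=nnz, replace=False) if nnz else np.array([], dtype=np.int64)
    rows, cols = np.divmod(flat, max(n_cols, 1))
    m = sp.csr_matrix(
        (_nb_counts(rng, nnz, dtype), (rows, cols)), shape=(n_rows, n_cols)
    )
    m.sort_indices()
    return m


def _knn_graph(rng: np.random.Generator, n: int, k: int = 5) -> sp.csr_matrix:
    if n == 0:
        return sp.csr_matrix((0, 0))
    k = min(k, max(n - 1, 0))
    rows, cols, vals = [], [], []
    for i in range(n):
        if k == 0:
            continue
        others = rng.choice(n - 1, size=k, replace=False)
        others[others >= i] += 1  # exclude self-loop
        rows.extend([i] * k)
        cols.extend(others.tolist())
        vals.extend(rng.uniform(0.1, 1.0, size=k).tolist())
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return m.maximum(m.T).tocsr()  # symmetric, knn-style


def make_synthetic_dataset(
    n_cells: int = 200,
    n_genes: int = 100,
    density: float = 0.1,
    n_layers: int = 1,
    n_categorical: int = 2,
    n_numeric: int = 2,
    n_reductions: int = 2,
    n_graphs: int = 1,
    with_spatial: bool = True,
    with_raw: bool = True,
    dtype=np.float64,
    seed: int = 0,
) -> SingleCellDataset:
    """Generate a complete, validated synthetic dataset.

    Identical arguments (including *seed*) produce numerically identical
    datasets.  Counts are negative-binomial-like integers cast to *dtype*;
    every categorical column carries at least one unobserved level and a few
    missing values, so round-trip tests exercise level preservation and the
    code ``-1`` missing marker.
    """
    if n_cells < 0 or n_genes < 0:
        raise ValueError("n_cells and n_genes must be nonnegative")
    if not 0 <= density <= 1:
        raise ValueError(f"density must be in [0, 1], got {density}")
    rng = np.random.default_rng(seed)

    X = _random_counts(rng, n_cells, n_genes, density, dtype)

    obs_data: dict = {}
    for i in range(n_categorical):
        n_levels = int(rng.integers(2, 8))
        levels = [f"obs{i}_lv{j}" for j in range(n_levels)] + [f"obs{i}_unused"]
        codes = rng.integers(0, n_levels, size=n_cells)
        if n_cells > 3:
            codes[rng.choice(n_cells, size=max(1, n_cells // 50), replace=False)] = -1
        obs_data[f"celltype_{i}"] = pd.Categorical.from_codes(
            codes, categories=levels, ordered=bool(i % 2)
        )
    for i in range(n_numeric):
        obs_data[f"qc_metric_{i}"] = rng.normal(size=n_cells)
    obs_data["n_counts"] = rng.integers(500, 5000, size=n_cells)
    obs_data["pass_qc"] = rng.random(n_cells) > 0.1
    obs_data["sample"] = np.array(
        [f"sample_{j % 3}" for j in range(n_cells)], dtype=object
    )
    obs = pd.DataFrame(obs_data, index=[f"cell_{j:05d}" for j in range(n_cells)])
    obs.index.name = "barcode"

    var_data: dict = {
        "highly_variable": rng.random(n_genes) > 0.5,
        "mean_expr": rng.gamma(2.0, 1.0, size=n_genes),
    }
    if n_categorical:
        chroms = [f"chr{c}" for c in list(range(1, 6)) + ["X"]]
        var_data["chrom"] = pd.Categorical.from_codes(
            rng.integers(0, len(chroms) - 1, size=n_genes), categories=chroms
        )
    var = pd.DataFrame(var_data, index=[f"gene_{j:05d}" for j in range(n_genes)])
    var.index.name = "symbol"

    layers = {}
    layer_names = ["spliced", "unspliced", "ambiguous", "counts_0", "counts_1"]
    for i in range(n_layers):
        name = layer_names[i] if i < len(layer_names) else f"layer_{i}"
        m = _random_counts(rng, n_cells, n_genes, density, dtype)
        layers[name] = m.toarray() if i % 2 else m  # mix sparse and dense

    red_names = ["pca", "umap", "tsne", "diffmap"]
    dimR = {
        (red_names[i] if i < len(red_names) else f"embed_{i}"): rng.normal(
            size=(n_cells, 2)
        )
        for i in range(n_reductions)
    }

    graph_names = ["connectivities", "distances"]
    graphs = {
        (graph_names[i] if i < len(graph_names) else f"graph_{i}"): _knn_graph(rng, n_cells)
        for i in range(n_graphs)
    }

    uns = {
        "title": "synthetic droplet run",
        "params": {"neighbors_k": 5, "resolution": 0.5, "log1p": True},
        "batch_colors": ["#1f77b4", "#ff7f0e", "#2ca02c"],
        "random_offsets": rng.normal(size=4),
        "marker_table": pd.DataFrame(
            {
                "gene": np.array(["gene_00000", "gene_00001"], dtype=object),
                "score": [1.5, -0.25],
            },
            index=pd.Index(["m0", "m1"]),
        ),
        "seed": int(seed),
    }

    spatial = None
    if with_spatial:
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        spatial = SpatialBundle(
            images={
                "library_0": (
                    img,
                    {"spot_diameter_fullres": 89.4, "tissue_hires_scalef": 0.17},
                )
            },
            coordinates=rng.uniform(0, 1000, size=(n_cells, 2)),
        )

    rawX = _random_counts(rng, n_cells, n_genes, density, dtype) if with_raw else None

    return new_dataset(
        X,
        obs,
        var,
        rawX=rawX,
        layers=layers,
        dimR=dimR,
        graphs=graphs,
        uns=uns,
        spatial=spatial,
    )


# ---------------------------------------------------------------------------
# deliberately corrupted files (validator rejection corpus)
# ---------------------------------------------------------------------------


def make_corrupt_corpus(source_h5, out_dir) -> dict[str, tuple[str, str]]:
    """Derive ten corrupted copies of a valid file, one defect each.

    Returns a mapping ``name -> (path, expected_finding_prefix)`` where the
    prefix locates the HDF5 path at which the validator must report an
    error-severity finding.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus: dict[str, tuple[str, str]] = {}

    def corrupted(name: str, expected_prefix: str, mutate) -> None:
        path = out_dir / f"{name}.h5"
        shutil.copy(source_h5, path)
        with h5py.File(path, "r+") as f:
            mutate(f)
        corpus[name] = (str(path), expected_prefix)

    def _replace(grp, part, data):
        del grp[part]
        d = grp.create_dataset(part, data=data)
        d.attrs["datatype"] = "Array"

    corrupted("missing_X", "/data/X", lambda f: f["data"].__delitem__("X"))
    corrupted("missing_group", "/graphs", lambda f: f.__delitem__("graphs"))

    def truncate_indptr(f):
        indptr = f["data/X/indptr"][()]
        _replace(f["data/X"], "indptr", indptr[:-2])

    corrupted("truncated_indptr", "/data/X", truncate_indptr)

    def bad_terminal(f):
        indptr = f["data/X/indptr"][()]
        indptr[-1] += 7
        _replace(f["data/X"], "indptr", indptr)

    corrupted("indptr_terminal", "/data/X", bad_terminal)

    def non_monotone(f):
        indptr = f["data/X/indptr"][()]
        if len(indptr) > 2:
            indptr[1], indptr[2] = indptr[2] + 1, indptr[1]
        _replace(f["data/X"], "indptr", indptr)

    corrupted("indptr_non_monotone", "/data/X", non_monotone)

    def bad_codes(f):
        col = next(
            c
            for c in f["obs"]
            if isinstance(f["obs"][c], h5py.Dataset)
            and f["obs"][c].attrs.get("encoding") == "category"
        )
        codes = f["obs"][col][()]
        codes[0] = 99
        ds = f["obs"][col]
        attrs = dict(ds.attrs)
        del f["obs"][col]
        d = f["obs"].create_dataset(col, data=codes)
        for k, v in attrs.items():
            d.attrs[k] = v

    corrupted("category_code_out_of_range", "/obs", bad_codes)

    def bad_layer(f):
        name = next(iter(f["layers"]))
        del f["layers"][name]
        d = f["layers"].create_dataset(name, data=np.zeros((2, 2)))
        d.attrs["datatype"] = "Array"

    corrupted("layer_shape_mismatch", "/layers", bad_layer)

    corrupted(
        "missing_datatype_attr",
        "/data/X",
        lambda f: f["data/X"].attrs.__delitem__("datatype"),
    )

    def bad_indices(f):
        indices = f["data/X/indices"][()]
        if len(indices):
            indices[0] = 10**9
        _replace(f["data/X"], "indices", indices)

    corrupted("indices_out_of_bounds", "/data/X", bad_indices)

    def bad_vocab(f):
        f["obs"].attrs["datatype"] = "Tibble"

    corrupted("unknown_datatype_value", "/obs", bad_vocab)

    return corpus
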