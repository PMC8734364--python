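"""Conversion to/from .h5ad and MatrixMarket, and the IO benchmark table."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

import sch5io
from sch5io import interop
from sch5io.synthetic import make_synthetic_dataset
from sch5io.testing import assert_datasets_equal

SHARED_SLOTS = ("X", "rawX", "layers", "obs", "var", "dimR", "graphs", "spatial")


def test_h5ad_roundtrip_identity_on_shared_slots(tmp_path, small_dataset):
    path = tmp_path / "ds.h5ad"
    interop.to_h5ad(small_dataset, path)
    back = interop.from_h5ad(path)
    assert_datasets_equal(small_dataset, back, slots=SHARED_SLOTS)
    # uns is shared too, minus the spatial subtree that moved slots
    from sch5io.testing import assert_mappings_equal

    assert_mappings_equal(small_dataset.uns, back.uns)


def test_h5ad_then_h5_then_back(tmp_path, small_dataset):
    """The conversion-first pathway: foreign format -> .h5 -> memory."""
    h5ad = tmp_path / "ds.h5ad"
    h5 = tmp_path / "ds.h5"
    interop.to_h5ad(small_dataset, h5ad)
    sch5io.write_h5(interop.from_h5ad(h5ad), h5)
    back = sch5io.read_h5(h5)
    assert_datasets_equal(small_dataset, back, slots=SHARED_SLOTS)


def test_h5ad_categorical_levels_and_order_preserved(tmp_path):
    cat = pd.Categorical.from_codes([0, 0, 1], categories=["z_last", "a_first", "unused"])
    adata = ad.AnnData(
        X=sp.csr_matrix(np.eye(3)),
        obs=pd.DataFrame({"celltype": cat}, index=["c0", "c1", "c2"]),
        var=pd.DataFrame(index=["g0", "g1", "g2"]),
    )
    path = tmp_path / "cat.h5ad"
    adata.write_h5ad(path)
    ds = interop.from_h5ad(path)
    assert list(ds.obs["celltype"].cat.categories) == ["z_last", "a_first", "unused"]
    assert ds.obs["celltype"].cat.codes.tolist() == [0, 0, 1]


def test_h5ad_without_reductions_gives_empty_dimr(tmp_path):
    adata = ad.AnnData(X=np.ones((2, 2)), obs=pd.DataFrame(index=["a", "b"]),
                       var=pd.DataFrame(index=["g", "h"]))
    path = tmp_path / "plain.h5ad"
    adata.write_h5ad(path)
    ds = interop.from_h5ad(path)
    assert ds.dimR == {} and ds.graphs == {} and ds.spatial is None


def test_unmappable_obsm_rides_in_reserved_uns_namespace(tmp_path):
    adata = ad.AnnData(
        X=np.ones((2, 2)),
        obs=pd.DataFrame(index=["a", "b"]),
        var=pd.DataFrame(index=["g", "h"]),
        obsm={"custom_coords": np.arange(4.0).reshape(2, 2)},
    )
    path = tmp_path / "odd.h5ad"
    adata.write_h5ad(path)
    with pytest.warns(UserWarning, match="custom_coords"):
        ds = interop.from_h5ad(path)
    preserved = ds.uns[interop.UNMAPPED_KEY]["obsm"]["custom_coords"]
    np.testing.assert_array_equal(preserved, adata.obsm["custom_coords"])


def test_unreadable_h5ad_raises_oserror(tmp_path):
    bogus = tmp_path / "x.h5ad"
    bogus.write_text("not hdf5")
    with pytest.raises(OSError, match="unreadable"):
        interop.from_h5ad(bogus)


def test_mtx_header_counts_nonzeros(tmp_path, tiny_frames):
    X, obs, var = tiny_frames  # 3x2 with 3 nonzeros
    ds = sch5io.new_dataset(X, obs, var)
    interop.export_mtx(ds, tmp_path)
    header = None
    for line in (tmp_path / "matrix.mtx").read_text().splitlines():
        if not line.startswith("%"):
            header = line
            break
    assert header.split() == ["3", "2", "3"]
    # independent reader accepts the file (format conformance)
    back = scipy.io.mmread(tmp_path / "matrix.mtx")
    np.testing.assert_array_equal(back.toarray(), X.toarray())


def test_mtx_roundtrip_identity_on_x_obs_var(tmp_path, small_dataset):
    interop.export_mtx(small_dataset, tmp_path / "mtx")
    back = interop.import_mtx(tmp_path / "mtx")
    assert_datasets_equal(small_dataset, back, slots=("X", "obs", "var"))


def test_empty_matrix_exports_and_imports(tmp_path):
    ds = sch5io.new_dataset(
        sp.csr_matrix((2, 3)),
        pd.DataFrame({"g": ["a", "b"]}, index=["c0", "c1"]),
        pd.DataFrame({"h": [1, 2, 3]}, index=["g0", "g1", "g2"]),
    )
    interop.export_mtx(ds, tmp_path / "empty")
    back = interop.import_mtx(tmp_path / "empty")
    assert back.X.nnz == 0 and back.X.shape == (2, 3)


def test_rds_pathway_names_companion_module(tmp_path):
    with pytest.raises(interop.CompanionModuleRequiredError, match="companion R module"):
        interop.rds_not_supported(tmp_path / "x.rds")


def test_benchmark_table_shape_and_determinism():
    table = interop.benchmark_io(ds_sizes=((300, 200, 0.05),), formats=("h5", "mtx"), reps=2, seed=5)
    assert set(table["format"]) == {"h5", "mtx"}
    assert set(table["direction"]) == {"write", "read"}
    assert len(table) == 4
    assert (table["median_time_s"] > 0).all()
    # identical seeds generate identical inputs: nnz equal across calls
    a = make_synthetic_dataset(300, 200, 0.05, seed=5)
    b = make_synthetic_dataset(300, 200, 0.05, seed=5)
    assert a.X.nnz == b.X.nnz
    np.testing.assert_array_equal(a.X.toarray(), b.X.toarray())
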