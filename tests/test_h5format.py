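"""The eight-group file layout: writer, reader, partial loading, validator."""

import h5py
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import sch5io
from sch5io import PartialSpec, read_h5, validate_h5, write_h5
from sch5io.codecs import NameCollisionError
from sch5io.datamodel import UNLOADED, InvalidDatasetError, SingleCellDataset
from sch5io.h5format import (
    GROUPS,
    UnknownKeyError,
    format_tree,
    list_contents,
)
from sch5io.synthetic import make_corrupt_corpus, make_synthetic_dataset
from sch5io.testing import assert_datasets_equal, record_dataset_reads


@pytest.fixture
def written(tmp_path, small_dataset):
    path = tmp_path / "ds.h5"
    write_h5(small_dataset, path)
    return path, small_dataset


def test_file_has_exactly_eight_top_level_groups(written):
    path, _ = written
    with h5py.File(path, "r") as f:
        assert set(f.keys()) == set(GROUPS)
        assert "format-version" in f.attrs


def test_minimal_dataset_still_writes_eight_groups(tmp_path, tiny_frames):
    X, obs, var = tiny_frames
    path = tmp_path / "minimal.h5"
    write_h5(sch5io.new_dataset(X, obs, var), path)
    with h5py.File(path, "r") as f:
        assert set(f.keys()) == set(GROUPS)
        assert len(f["layers"]) == 0 and len(f["dimR"]) == 0
        assert "X" in f["data"] and "rawX" not in f["data"]
    back = read_h5(path)
    assert back.layers == {} and back.dimR == {} and back.spatial is None


def test_sparse_x_is_three_child_datasets(written):
    path, _ = written
    with h5py.File(path, "r") as f:
        assert set(f["data"]["X"].keys()) == {"indptr", "indices", "values"}
        assert f["data"]["X"].attrs["datatype"] == "SparseMatrix"


def test_full_roundtrip_is_identity(written):
    path, ds = written
    assert_datasets_equal(ds, read_h5(path))


def test_rewrite_of_read_file_preserves_logical_content(written, tmp_path):
    path, ds = written
    second = tmp_path / "second.h5"
    write_h5(read_h5(path), second)
    assert_datasets_equal(read_h5(path), read_h5(second))
    assert validate_h5(second).ok


def test_invalid_dataset_is_refused_before_writing(tmp_path, tiny_frames):
    X, obs, var = tiny_frames
    bad = SingleCellDataset(X=X, obs=obs, var=var, layers={"l": np.zeros((1, 1))})
    with pytest.raises(InvalidDatasetError):
        write_h5(bad, tmp_path / "bad.h5")
    assert not (tmp_path / "bad.h5").exists()


def test_layer_named_like_reserved_slot_fails(tmp_path, tiny_frames):
    X, obs, var = tiny_frames
    ds = sch5io.new_dataset(X, obs, var, layers={"X": X.copy()})
    with pytest.raises(NameCollisionError, match="X"):
        write_h5(ds, tmp_path / "c.h5")


def test_partial_read_obs_only_marks_rest_unloaded(written):
    path, ds = written
    part = read_h5(path, PartialSpec(groups={"obs"}))
    assert part.X is UNLOADED and part.layers is UNLOADED
    pd.testing.assert_frame_equal(part.obs, ds.obs)


def test_partial_read_never_opens_excluded_matrices(written):
    path, ds = written
    reads = []
    with record_dataset_reads(reads):
        part = read_h5(path, PartialSpec(groups={"obs", "var"}))
    pd.testing.assert_frame_equal(part.obs, ds.obs)
    outside = [r for r in reads if not (r.startswith("/obs") or r.startswith("/var"))]
    assert outside == []


def test_partial_read_column_subset(written):
    path, ds = written
    cols = list(ds.obs.columns[:2])
    part = read_h5(path, PartialSpec(groups={"obs"}, obs_columns=cols))
    pd.testing.assert_frame_equal(part.obs, ds.obs[cols])


def test_unknown_requested_key_lists_available(written):
    path, _ = written
    with pytest.raises(UnknownKeyError, match="available"):
        read_h5(path, PartialSpec(layers_keys=["missing"]))
    with pytest.raises(ValueError, match="unknown groups"):
        PartialSpec(groups={"nonsense"})


def test_unloaded_slots_rewrite_and_read_back_as_unloaded(written, tmp_path):
    path, ds = written
    part = read_h5(path, PartialSpec(groups={"obs", "var"}))
    out = tmp_path / "partial.h5"
    write_h5(part, out)
    with h5py.File(out, "r") as f:
        assert set(f.keys()) == set(GROUPS)
        assert len(f["data"]) == 0
    again = read_h5(out)
    assert again.X is UNLOADED
    pd.testing.assert_frame_equal(again.obs, ds.obs)


def test_validator_accepts_writer_output(written):
    path, _ = written
    report = validate_h5(path)
    assert report.ok and not report.findings


def test_validator_rejects_each_corruption_at_its_path(written, tmp_path):
    path, _ = written
    corpus = make_corrupt_corpus(path, tmp_path / "corrupt")
    assert len(corpus) == 10
    for name, (cpath, expected_prefix) in corpus.items():
        report = validate_h5(cpath, deep=True)
        assert not report.ok, f"{name}: validator accepted a corrupted file"
        errors = [p for p, sev, _ in report.findings if sev == "error"]
        assert any(p.startswith(expected_prefix) for p in errors), (
            f"{name}: no error at {expected_prefix}, got {errors}"
        )


def test_extra_group_is_warning_not_error(written):
    path, _ = written
    with h5py.File(path, "r+") as f:
        g = f.create_group("future_extension")
        g.attrs["datatype"] = "Mapping"
    report = validate_h5(path)
    assert report.ok
    assert any("future_extension" in p for p, sev, _ in report.findings if sev == "warning")


def test_newer_minor_version_warns_not_fails(written):
    path, _ = written
    with h5py.File(path, "r+") as f:
        f.attrs["format-version"] = "1.9"
    report = validate_h5(path)
    assert report.ok
    assert any("1.9" in msg for _, sev, msg in report.findings if sev == "warning")


def test_not_hdf5_raises_dedicated_error(tmp_path):
    bogus = tmp_path / "not.h5"
    bogus.write_text("plain text")
    with pytest.raises(sch5io.h5format.NotHDF5Error):
        validate_h5(bogus)


def test_list_contents_names_every_node(written):
    path, _ = written
    nodes = list_contents(path)
    paths = {n.path for n in nodes}
    for g in GROUPS:
        assert f"/{g}" in paths
    x = next(n for n in nodes if n.path == "/data/X")
    assert x.datatype_attr == "SparseMatrix" and x.node_kind == "group"
    tree = format_tree(nodes)
    assert "data/" in tree and "SparseMatrix" in tree


def test_randomized_roundtrips_across_component_combinations(tmp_path):
    """Round-trip identity over varied shapes, dtypes and optional parts."""
    rng = np.random.default_rng(11)
    for i in range(8):
        ds = make_synthetic_dataset(
            n_cells=int(rng.integers(0, 120)),
            n_genes=int(rng.integers(1, 80)),
            density=float(rng.choice([0.0, 0.05, 0.3])),
            n_layers=int(rng.integers(0, 3)),
            n_reductions=int(rng.integers(0, 3)),
            n_graphs=int(rng.integers(0, 2)),
            with_spatial=bool(i % 2),
            with_raw=bool((i // 2) % 2),
            dtype=np.int64 if i % 3 == 0 else np.float64,
            seed=100 + i,
        )
        path = tmp_path / f"r{i}.h5"
        write_h5(ds, path)
        assert_datasets_equal(ds, read_h5(path))
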