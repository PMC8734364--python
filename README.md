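# sch5io

A self-describing HDF5 interchange format for single-cell omics data, with a
Python library and a command-line tool.

## The problem

Single-cell RNA-seq analysis is split across ecosystems: Scanpy (Python,
AnnData, CSR sparse matrices, cell-major) on one side; Seurat,
SingleCellExperiment and Monocle (R, dgCMatrix, CSC sparse, gene-major) on
the other.  Each has its own serialization, so moving a processed dataset
between them is slow and lossy — factor levels vanish, graphs and embeddings
get dropped, and text formats like MatrixMarket cost minutes and gigabytes at
atlas scale.  `sch5io` defines one `.h5` layout that any HDF5-capable
language can read and write, carries every standard component of a
single-cell dataset losslessly, and supports partial loading so you can pull
the cell annotations of a million-cell file without touching its count
matrix.

## The format

One file, exactly eight top-level HDF5 groups:

| group    | contents |
|----------|----------|
| `data`   | primary matrix `X` (cells × genes) and optional `rawX` |
| `layers` | matrices with X's exact shape (e.g. spliced/unspliced counts) |
| `obs`    | cell annotation table, one dataset per column |
| `var`    | gene annotation table |
| `dimR`   | low-dimensional embeddings (PCA, UMAP, …), cells × k |
| `graphs` | square sparse cell-affinity matrices (kNN connectivities) |
| `uns`    | arbitrarily nested unstructured metadata |
| `spatial`| tissue image(s), scale factors, spot coordinates |

Every group and dataset carries a `datatype` attribute (`Array`,
`SparseMatrix`, `DataFrame`, `Mapping`, `Category`, `String`, `Image`) that
fully determines how to decode it.  A dense matrix is stored directly; a
sparse m × p matrix with n nonzeros becomes three datasets in
compressed-sparse form — `values` (the n entries collapsed by row or
column), `indices` (their cross-dimension positions) and `indptr`, of length
m+1 (row-major) or p+1 (column-major), whose adjacent entries delimit each
row's or column's slice.  Annotation tables store one dataset per column
plus a `category` subgroup holding each categorical column's level
vocabulary in order (unobserved levels included; missing values are code
−1), which is what lets R factors and pandas Categoricals round-trip
exactly.

## Worked example

```python
import sch5io
from sch5io.synthetic import make_synthetic_dataset

ds = make_synthetic_dataset(n_cells=500, n_genes=200, density=0.05, seed=0)
print(ds)
sch5io.write_h5(ds, "pbmc_like.h5")
print(sch5io.validate_h5("pbmc_like.h5"))

# partial read: cell annotations only, count matrix never opened
part = sch5io.read_h5("pbmc_like.h5", sch5io.PartialSpec(groups={"obs"}))
print(part.obs.head(3))
print("X loaded?", sch5io.is_loaded(part.X))
```

prints

```
SingleCellDataset(n_cells=500, n_genes=200, layers=['spliced'], dimR=['pca', 'umap'],
                  graphs=['connectivities'], uns=[...], rawX, spatial)
ok: no findings
           celltype_0 celltype_1  qc_metric_0  ...  n_counts  pass_qc    sample
barcode                                        ...
cell_00000   obs0_lv3   obs1_lv2    -0.102184  ...      3981     True  sample_0
cell_00001   obs0_lv3   obs1_lv2     1.057526  ...      3314    False  sample_1
cell_00002   obs0_lv1   obs1_lv0     0.419280  ...      3184     True  sample_2
X loaded? False
```

The `validate_h5` line is the schema validator's report (no findings — the
file conforms); the partial read returned the full annotation table while
leaving `X` as an explicit "unloaded" sentinel, so downstream code cannot
mistake it for an empty matrix.

The same operations from the shell:

```bash
sch5io convert --in data.h5ad --out data.h5      # AnnData -> .h5
sch5io convert --in data.h5 --out obs_only.h5 --only obs,var
sch5io validate --in data.h5                     # exit 0 iff conformant
sch5io info --in data.h5                         # print the group tree
sch5io bench --cells 20000 --genes 5000 --density 0.01
```

`.h5ad` and MatrixMarket (`.mtx` + TSV sidecars) converters are in
`sch5io.interop`; `.rds` conversion belongs to the companion R-side module
and is reported as such by the CLI.

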