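# Methods

## Data model

The in-memory container (`SingleCellDataset`) is a cell-major bundle: rows
of every matrix are cells, columns of the primary matrix are genes.
Gene-major ecosystems (R's SingleCellExperiment/Seurat) transpose at their
own adapter boundary; nothing inside this package ever holds a gene-major
matrix.  Tables are pandas DataFrames and categorical columns are pandas
Categoricals, whose `(categories, codes)` pair maps one-to-one onto the
on-disk level/code encoding.  Matrices are numpy arrays or scipy sparse
matrices; dense and sparse storage of the same values are interconvertible
but the storage kind itself is preserved through a round trip, since
downstream memory behaviour depends on it.

`rawX` is an optional unprocessed matrix. The format imposes no semantic
constraint on it (counts vs merely unfiltered is deliberately not checked);
the default in-memory model keeps it the same width as `X`, and the `.h5ad`
adapter maps it onto AnnData's `raw` slot.

## On-disk encoding

Every node carries a `datatype` attribute from a closed seven-value
vocabulary; decoding dispatches on that attribute alone.  Choices that were
genuinely open, and how they were fixed:

- **Sparse orientation.** Sparse payloads are written row-major
  (cell-major CSR) with an `orientation` attribute, so a column-major-native
  reader knows to convert rather than guess.  The decoder accepts both
  orientations; conversion is exact.  `indptr` length is rows+1 row-major,
  cols+1 column-major; within each segment indices are strictly increasing
  (canonical form), explicit zeros are dropped and duplicates summed on
  encode, so the triplet is a pure function of the matrix's values.
- **64-bit offsets.** `indptr`/`indices` are int64 unconditionally: at
  atlas scale (~2M cells) nonzero counts plausibly exceed 2^31 and a 32-bit
  file would be silently wrong.
- **Index arrays are 0-based** on disk; 1-based ecosystems convert at
  their adapter.
- **Strings** are variable-length UTF-8 (fixed-width encodings truncate
  silently).  **Booleans** are int8 with an `encoding="boolean"` attribute,
  portable across HDF5 bindings without native booleans.
- **Missing values.** Floating NaN is kept as-is; a missing category is
  code −1 and never a level, so the stored vocabulary equals the declared
  one; missing strings become empty strings plus a sidecar `missing-mask`
  attribute written only when any are present.
- **Tables.** One dataset per column keyed by column name; the row labels
  live in a reserved `index` dataset (original index name in an attribute;
  a user column named `index` is a refused name collision, not a silent
  rename), and a `column-order` attribute preserves ordering.  A file
  missing that attribute decodes in lexicographic order with a warning.
  Category codes outside the stored level range are a hard decode error.
- **Compression** defaults to none; chunked gzip at any level is available
  through the `compression=` option (`--compression` on the CLI).
  Uncompressed is the right default for an interchange format whose point
  is IO speed: deflate dominates write time at typical sparsities (measured
  ~4× slowdown at gzip-4 on a 20k×5k, 1%-density matrix) while binary CSR
  is already ~half the size of the equivalent MatrixMarket text.
- **Eight groups always.** Absent components are present-but-empty groups,
  making "exactly 8 top-level groups" a file invariant and validation
  simple; absence is encoded by emptiness.  A root `format-version`
  attribute is written; readers warn on newer minor versions and fail on
  major mismatches.
- **dimR keys** are normalized to lower case on disk (deterministic
  cross-ecosystem matching) with the conventional spelling preserved in an
  `original-name` attribute and restored on read.
- **Spatial coordinates** live under `spatial` (not in `obs`), with a
  `coordinates-of="obs"` attribute cross-referencing the table whose rows
  they index.

## Partial loading

A `PartialSpec` names the top-level groups (and optionally annotation
columns or layer/reduction/graph keys) to materialize; everything else
comes back as a distinct `UNLOADED` sentinel rather than an empty
container, so "not loaded" can never be mistaken for "empty".  The read
path runs only the *shallow* validator — group presence, datatype
attributes, shapes and indptr lengths, all available from metadata — so a
partial read performs zero element reads on excluded datasets (the test
suite proves this with a shim that counts every `h5py.Dataset.__getitem__`
call).  The standalone validator defaults to *deep* mode, which
additionally reads offset arrays and category codes to check indptr
monotonicity, index bounds and code ranges.  Writing a partially-loaded
dataset emits empty groups flagged `unloaded`, which read back as the
sentinel.

## Interop

`.h5ad` conversion maps slot-to-slot onto AnnData: `X`/`raw`/`layers`/
`obs`/`var`, embeddings to `obsm["X_<name>"]`, graphs to `obsp`, `uns` to
`uns`, and the spatial bundle onto the Visium convention
(`obsm["spatial"]` + `uns["spatial"][library_id]`).  String columns are
written as strings (AnnData's default string→categorical coercion is
disabled, since it would change dtypes through a round trip).  Entries with
no counterpart slot are preserved under a reserved `uns` namespace with a
warning — conversion is never destructive.  MatrixMarket export writes the
standard 1-based coordinate file through scipy plus TSV sidecars for
obs/var and a small JSON sidecar recording column dtypes and category level
order, which TSV alone cannot carry.  `.rds` conversion requires the R
ecosystem's serializer and is delegated to a companion R-side module; the
CLI reports this explicitly.

## Synthetic data generator

`make_synthetic_dataset` is fully deterministic given its seed.  It
emulates the *container shape* of droplet scRNA-seq: uniformly placed
nonzeros at a requested density with shifted negative-binomial values
(r=2, p=0.3, +1 so no sampled value is an implicit zero), categorical
annotations with 2–8 levels, always at least one unobserved level and ~2%
missing codes, numeric/boolean/string columns, cells×2 embeddings, a
symmetric k=5 kNN-style affinity graph, a nested `uns` tree containing a
table leaf, a 32×32×3 image with Visium-style scale factors, and spot
coordinates.  It does **not** emulate biology: no gene modules, batch
structure, mean–variance relationship or trajectories.  Passing tests
therefore demonstrate lossless carriage of structure, not fidelity of any
analysis; that is the correct scope for a format.

`make_corrupt_corpus` derives ten single-defect copies of a valid file
(missing `data/X`, missing top-level group, truncated / wrong-terminal /
non-monotone `indptr`, out-of-range category code, shape-mismatched layer,
missing datatype attribute, out-of-bounds index, out-of-vocabulary
datatype) for validator soundness checks.

## Benchmark

`benchmark_io` generates a dataset per size (matrices only — no layers,
graphs or spatial — so the comparison isolates matrix+table IO), then times
write and read per format over `reps` repetitions and reports the median.
Peak memory is measured with `tracemalloc` on one extra instrumented
repetition so the tracer never distorts the timings.  Reported results
should be compared as orderings, never absolute values: wall time depends
on hardware and library versions.  The default acceptance-scale problem is
20,000 cells × 5,000 genes at 1% density (~10⁶ nonzeros), 3 repetitions —
large enough that serialization cost dominates fixed overhead, small enough
to run in seconds on one CPU.

## Numerical and edge-case notes

- Round-trip equality in the test suite is exact (bit-level for floats):
  the codecs move bytes, so nothing weaker is acceptable.
- Degenerate shapes (0×n, n×0, empty tables, empty mappings, density 0)
  are first-class and covered by tests; gzip is skipped for zero-size
  datasets, which HDF5 cannot chunk.
- Scalar leaves decode to Python scalars with type preserved
  (str/int/float/bool/None); 0-d string datasets with the missing flag
  decode to None.
- Validator findings are `(path, severity, message)` triples; `ok` means
  no error-severity findings, warnings (unknown extra groups, newer minor
  version) do not block reading.

## Known limitations

- Ragged arrays, per-element metadata, and arrays above 2-D are not
  encodable as `uns` leaves.
- No concurrent writers and no in-place partial update of an existing
  file; writes are whole-file.
- The `.h5ad` adapter targets current AnnData slot semantics; exotic
  `uns` contents that AnnData itself cannot serialize are out of scope.
- Loom files are not supported.
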