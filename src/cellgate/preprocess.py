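"""Input handling and preprocessing.

scATAC-seq peak matrices are binarized (any count becomes 1), peaks
accessible in fewer than 0.1% of cells are dropped, and the 20,000 most
variable peaks are kept as features. scRNA-seq counts are prevalence-
filtered the same way, depth-normalised to 10,000 counts per cell,
log1p-transformed, and reduced to the 3,000 most variable genes. When
source and target were peak-called separately, source counts are remapped
onto the target's peak set by genomic-interval overlap before anything
else.

"Most variable" is scored by plain per-feature empirical variance, which
for binarized data equals p(1-p) with p the accessible fraction; the
scoring function is pluggable.

Matrices may be dense ndarrays or scipy.sparse; processed outputs are
dense float32.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

_PEAK_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _as_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense())
    return np.asarray(matrix)


@dataclass
class RawDataset:
    """A cells x features count matrix with identifiers and optional labels."""

    matrix: object  # ndarray or scipy.sparse, cells x features
    feature_ids: list
    cell_ids: list
    labels: list | None = None
    modality: str = "atac"

    def __post_init__(self):
        n, m = self.matrix.shape
        if n != len(self.cell_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"matrix is {n}x{m} but got {len(self.cell_ids)} cells / "
                f"{len(self.feature_ids)} features"
            )
        if self.modality not in ("atac", "rna"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError("labels length does not match cell count")
            self.labels = [str(l).strip() for l in self.labels]
            if any(not l for l in self.labels):
                raise ValueError("empty cell-type label")
        data = self.matrix.data if sp.issparse(self.matrix) else self.matrix
        if np.asarray(data).size and (np.any(np.asarray(data) < 0)
                                      or not np.all(np.isfinite(np.asarray(data)))):
            raise ValueError("matrix entries must be nonnegative and finite")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_features(self, indices) -> "RawDataset":
        indices = np.asarray(indices)
        matrix = self.matrix[:, indices] if not sp.issparse(self.matrix) \
            else self.matrix.tocsc()[:, indices].tocsr()
        return RawDataset(
            matrix=matrix,
            feature_ids=[self.feature_ids[i] for i in indices],
            cell_ids=list(self.cell_ids),
            labels=None if self.labels is None else list(self.labels),
            modality=self.modality,
        )


@dataclass
class ProcessedDataset:
    """Model-ready matrix restricted to selected features."""

    matrix: np.ndarray  # dense float32, cells x selected features
    selected_feature_ids: list
    cell_ids: list
    labels: list | None = None
    modality: str = "atac"
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def _prevalence_threshold(min_cell_fraction: float, n_cells: int) -> int:
    """"At least `fraction` of cells" as a cell count: max(1, ceil(f*N))."""
    return max(1, math.ceil(min_cell_fraction * n_cells))


def _nonzero_per_feature(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray((matrix != 0).sum(axis=0)).ravel()
    return np.count_nonzero(matrix, axis=0)


def prevalence_filter(raw: RawDataset, min_cell_fraction: float) -> RawDataset:
    """Drop features with a nonzero entry in fewer than max(1, ceil(f*N)) cells."""
    if not 0 <= min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must be in [0, 1)")
    if raw.n_cells == 0 or raw.n_features == 0:
        raise ValueError("empty matrix")
    threshold = _prevalence_threshold(min_cell_fraction, raw.n_cells)
    prevalence = _nonzero_per_feature(raw.matrix)
    keep = np.flatnonzero(prevalence >= threshold)
    if keep.size == 0:
        raise ValueError(
            f"all {raw.n_features} features fall below the prevalence "
            f"threshold of {threshold} cells"
        )
    return raw.subset_features(keep)


def binarize_and_filter(raw: RawDataset, min_cell_fraction: float = 0.001) -> RawDataset:
    """Binarize an accessibility matrix and apply the prevalence filter.

    Idempotent: a second application changes nothing.
    """
    if raw.modality != "atac":
        raise ValueError("binarize_and_filter applies to atac data")
    filtered = prevalence_filter(raw, min_cell_fraction)
    matrix = filtered.matrix
    if sp.issparse(matrix):
        matrix = matrix.copy()
        matrix.data = np.ones_like(matrix.data)
    else:
        matrix = (np.asarray(matrix) > 0).astype(np.float32)
    return RawDataset(matrix=matrix, feature_ids=filtered.feature_ids,
                      cell_ids=filtered.cell_ids, labels=filtered.labels,
                      modality="atac")


def feature_variance(matrix) -> np.ndarray:
    """Per-feature empirical variance (population form)."""
    if sp.issparse(matrix):
        mean = np.asarray(matrix.mean(axis=0)).ravel()
        mean_sq = np.asarray(matrix.multiply(matrix).mean(axis=0)).ravel()
        return mean_sq - mean**2
    dense = np.asarray(matrix)
    return dense.var(axis=0)


def select_highly_variable(ds: RawDataset, n_features: int,
                           score_fn=feature_variance) -> ProcessedDataset:
    """Keep the ``n_features`` highest-scoring features.

    Ties break toward the lower original column index; selected features are
    returned in their original order, so selecting n is always a subset of
    selecting n+1.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    scores = np.asarray(score_fn(ds.matrix), dtype=np.float64)
    n_keep = min(n_features, ds.n_features)
    ranked = np.argsort(-scores, kind="stable")[:n_keep]
    selected = np.sort(ranked)
    sub = ds.subset_features(selected)
    return ProcessedDataset(
        matrix=_as_dense(sub.matrix).astype(np.float32),
        selected_feature_ids=list(sub.feature_ids),
        cell_ids=list(ds.cell_ids),
        labels=None if ds.labels is None else list(ds.labels),
        modality=ds.modality,
        provenance={"n_features": n_features, "modality": ds.modality,
                    "score": getattr(score_fn, "__name__", str(score_fn))},
    )


def normalize_rna(raw: RawDataset, size_factor: float = 10_000.0) -> RawDataset:
    """Scale each cell's counts to ``size_factor`` total, then log1p."""
    if raw.modality != "rna":
        raise ValueError("normalize_rna applies to rna data")
    dense = _as_dense(raw.matrix).astype(np.float64)
    totals = dense.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {[raw.cell_ids[i] for i in zero[:5]]}"
        )
    scaled = dense * (size_factor / totals[:, None])
    return RawDataset(matrix=np.log1p(scaled), feature_ids=list(raw.feature_ids),
                      cell_ids=list(raw.cell_ids), labels=raw.labels, modality="rna")


def parse_peak(peak_id: str):
    """'chrom:start-end' -> (chrom, start, end), 0-based half-open."""
    match = _PEAK_RE.match(str(peak_id).strip())
    if match is None:
        raise ValueError(f"unparseable peak identifier: {peak_id!r}")
    start, end = int(match["start"]), int(match["end"])
    if end <= start:
        raise ValueError(f"degenerate peak interval: {peak_id!r}")
    return match["chrom"], start, end


def remap_source_to_target_peaks(source: RawDataset, target_peaks) -> RawDataset:
    """Re-express source counts over the target's peak set.

    Each target peak receives the summed counts of every source peak whose
    half-open genomic interval overlaps it; target peaks with no overlap
    get a zero column.
    """
    from intervaltree import IntervalTree

    trees: dict = {}
    for idx, pid in enumerate(source.feature_ids):
        chrom, start, end = parse_peak(pid)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, idx)

    source_dense = _as_dense(source.matrix)
    out = np.zeros((source.n_cells, len(target_peaks)), dtype=source_dense.dtype)
    for tj, pid in enumerate(target_peaks):
        chrom, start, end = parse_peak(pid)
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(start, end)]
        if hits:
            out[:, tj] = source_dense[:, hits].sum(axis=1)
    return RawDataset(matrix=out, feature_ids=list(target_peaks),
                      cell_ids=list(source.cell_ids), labels=source.labels,
                      modality=source.modality)


def align_features(source: ProcessedDataset, target: ProcessedDataset):
    """Restrict both datasets, in the source's feature order, to their
    shared features."""
    target_set = set(target.selected_feature_ids)
    shared = [f for f in source.selected_feature_ids if f in target_set]
    if not shared:
        raise ValueError(
            f"no shared features between source ({len(source.selected_feature_ids)}) "
            f"and target ({len(target.selected_feature_ids)})"
        )

    def _restrict(ds: ProcessedDataset) -> ProcessedDataset:
        index = {f: i for i, f in enumerate(ds.selected_feature_ids)}
        cols = [index[f] for f in shared]
        return ProcessedDataset(
            matrix=ds.matrix[:, cols], selected_feature_ids=list(shared),
            cell_ids=list(ds.cell_ids), labels=ds.labels, modality=ds.modality,
            provenance={**ds.provenance, "aligned_to": len(shared)},
        )

    return _restrict(source), _restrict(target)


# -- I/O ----------------------------------------------------------------------

def read_h5ad(path, label_key: str | None = None, modality: str = "atac") -> RawDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise ValueError(f"obs column {label_key!r} not found in {path}")
        labels = [str(v) for v in adata.obs[label_key]]
    return RawDataset(matrix=adata.X, feature_ids=list(adata.var_names),
                      cell_ids=list(adata.obs_names), labels=labels,
                      modality=modality)


def read_mtx(matrix_path, features_path, barcodes_path,
             labels_path=None, modality: str = "atac") -> RawDataset:
    import pandas as pd
    from scipy.io import mmread

    matrix = sp.csr_matrix(mmread(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    labels = None
    if labels_path is not None:
        table = pd.read_csv(labels_path)
        by_cell = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
        missing = [b for b in barcodes if b not in by_cell]
        if missing:
            raise ValueError(f"labels missing for barcodes: {missing[:5]}")
        labels = [by_cell[b] for b in barcodes]
    return RawDataset(matrix=matrix, feature_ids=features, cell_ids=barcodes,
                      labels=labels, modality=modality)


def to_anndata(ds):
    import anndata as ad
    import pandas as pd

    obs = pd.DataFrame(index=pd.Index([str(c) for c in ds.cell_ids], name="cell_id"))
    if ds.labels is not None:
        obs["cell_type"] = list(ds.labels)
    feature_ids = (ds.selected_feature_ids if isinstance(ds, ProcessedDataset)
                   else ds.feature_ids)
    var = pd.DataFrame(index=pd.Index([str(f) for f in feature_ids], name="feature_id"))
    X = ds.matrix if not sp.issparse(ds.matrix) else ds.matrix
    return ad.AnnData(X=np.asarray(_as_dense(X), dtype=np.float32), obs=obs, var=var)


def write_h5ad(ds, path) -> None:
    to_anndata(ds).write_h5ad(path)


def write_feature_list(ds: ProcessedDataset, path) -> None:
    with open(path, "w") as fh:
        for fid in ds.selected_feature_ids:
            fh.write(f"{fid}\n")
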