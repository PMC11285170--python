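"""Model/Results facade over the training and inference machinery.

``OpenSetAnnotator`` is constructed from a labeled source dataset and an
unlabeled target dataset (already preprocessed and feature-aligned, or via
``from_raw`` / ``from_anndata`` which run the standard pipeline);
``fit()`` returns an ``AnnotationResult`` carrying the trained network,
the learned per-head boundaries, target pseudo-labels, the loss history,
predictions, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pp
from .annotate import PredictionSet, predict, predictions_frame
from .metrics import OpenSetEval, evaluate
from .networks import AnnotatorNet, ModelConfig
from .trainer import TargetState, TrainConfig, fit as _fit


class OpenSetAnnotator:
    """Open-set domain-adaptation annotator for single-cell data.

    Parameters
    ----------
    source, target : ProcessedDataset
        Feature-aligned model inputs; ``source.labels`` is required.
    model_config, train_config : optional
        Architecture and optimization settings; defaults follow the
        modality (see ModelConfig / TrainConfig).
    """

    def __init__(self, source: pp.ProcessedDataset, target: pp.ProcessedDataset,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if source.labels is None:
            raise ValueError("source dataset must carry cell-type labels")
        if list(source.selected_feature_ids) != list(target.selected_feature_ids):
            raise ValueError("source and target features are not aligned; "
                             "use preprocess.align_features or from_raw")
        self.source = source
        self.target = target
        self.class_names = sorted(set(source.labels))
        self.model_config = model_config or ModelConfig(
            input_dim=source.matrix.shape[1],
            n_known_types=len(self.class_names),
            modality=source.modality,
        )
        self.train_config = train_config or TrainConfig()

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_raw(cls, source: pp.RawDataset, target: pp.RawDataset,
                 n_features: int | None = None, min_cell_fraction: float = 0.001,
                 model_config=None, train_config=None) -> "OpenSetAnnotator":
        """Run the standard preprocessing pipeline on raw count matrices.

        ATAC: remap source onto target peaks when the peak sets differ,
        binarize, prevalence-filter, then select the most variable peaks
        scored on source and target jointly (default 20,000). RNA:
        prevalence-filter, depth-normalise to 10,000 and log1p, then select
        3,000 most variable genes.
        """
        src_p, tgt_p = prepare_pair(source, target, n_features=n_features,
                                    min_cell_fraction=min_cell_fraction)
        return cls(src_p, tgt_p, model_config=model_config,
                   train_config=train_config)

    @classmethod
    def from_anndata(cls, source_adata, target_adata, label_key: str,
                     modality: str = "atac", **kwargs) -> "OpenSetAnnotator":
        source = pp.RawDataset(matrix=source_adata.X,
                               feature_ids=list(source_adata.var_names),
                               cell_ids=list(source_adata.obs_names),
                               labels=[str(v) for v in source_adata.obs[label_key]],
                               modality=modality)
        target = pp.RawDataset(matrix=target_adata.X,
                               feature_ids=list(target_adata.var_names),
                               cell_ids=list(target_adata.obs_names),
                               modality=modality)
        return cls.from_raw(source, target, **kwargs)

    # -- fitting --------------------------------------------------------------

    def fit(self, epochs: int | None = None, seed: int | None = None,
            callback=None) -> "AnnotationResult":
        config = self.train_config
        if epochs is not None or seed is not None:
            from dataclasses import replace
            config = replace(config,
                             epochs=config.epochs if epochs is None else epochs,
                             seed=config.seed if seed is None else seed)
        net, state, history = _fit(self.source, self.target, train_config=config,
                                   model_config=self.model_config,
                                   callback=callback)
        net.feature_ids = list(self.source.selected_feature_ids)
        return AnnotationResult(model=self, net=net, target_state=state,
                                history=history)


class AnnotationResult:
    """Fitted annotator: parameters, boundaries, pseudo-labels, history."""

    def __init__(self, model: OpenSetAnnotator, net: AnnotatorNet,
                 target_state: TargetState, history: list):
        self.model = model
        self.net = net
        self.target_state = target_state
        self.history = history
        self._predictions: PredictionSet | None = None

    @property
    def class_names(self) -> list:
        return self.model.class_names

    @property
    def boundary(self):
        return self.target_state.boundary

    @property
    def pseudo_labels(self) -> list:
        return self.target_state.pseudo_labels

    def predict(self, target=None, gate_with_boundary: bool = False) -> PredictionSet:
        """Annotate ``target`` (default: the training target set)."""
        data = target if target is not None else self.model.target
        boundary = self.boundary if gate_with_boundary else None
        return predict(self.net, data, class_names=self.class_names,
                       gate_with_boundary=boundary)

    @property
    def predictions(self) -> PredictionSet:
        if self._predictions is None:
            self._predictions = self.predict()
        return self._predictions

    def predictions_frame(self):
        return predictions_frame(self.predictions)

    def evaluate(self, truth_labels) -> OpenSetEval:
        return evaluate(self.predictions, truth_labels, self.class_names)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def save(self, path) -> None:
        self.net.save(path, boundary=self.boundary.values,
                      class_names=self.class_names,
                      extra={"feature_count": len(self.net.feature_ids)})

    def plot_history(self, ax=None):
        """Loss-term trajectories per epoch."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.history_frame()
        for term in ("kl", "recon", "sup_c", "sup_o", "sup_t", "total"):
            ax.plot(frame["epoch"], frame[term], label=term)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def summary(self) -> str:
        pred = self.predictions
        counts = {name: 0 for name in self.class_names + ["unknown"]}
        for lab in pred.labels:
            counts[lab] += 1
        lines = [
            "Open-set annotation results",
            "=" * 56,
            f"known types (K):        {len(self.class_names)}",
            f"features (m):           {self.net.config.input_dim}",
            f"embedding dim (L):      {self.net.config.embedding_dim}",
            f"source cells:           {self.model.source.matrix.shape[0]}",
            f"target cells:           {self.model.target.matrix.shape[0]}",
            f"epochs trained:         {len(self.history)}",
            f"final total loss:       {self.history[-1]['total']:.4f}"
            if self.history else "final total loss:       n/a",
            "-" * 56,
            f"{'type':<24}{'boundary P^B':>14}{'# predicted':>14}",
        ]
        for j, name in enumerate(self.class_names):
            lines.append(f"{name:<24}{self.boundary.values[j]:>14.4f}"
                         f"{counts[name]:>14d}")
        lines.append(f"{'unknown':<24}{'(gate 0.5)':>14}{counts['unknown']:>14d}")
        lines.append("=" * 56)
        return "\n".join(lines)


def prepare_pair(source: pp.RawDataset, target: pp.RawDataset,
                 n_features: int | None = None, min_cell_fraction: float = 0.001):
    """Standard preprocessing for a source/target pair; features are scored
    for variability on the two batches jointly and aligned in source order."""
    if source.modality != target.modality:
        raise ValueError("source and target modalities differ")
    modality = source.modality
    if n_features is None:
        n_features = 20_000 if modality == "atac" else 3_000

    if modality == "atac":
        if list(source.feature_ids) != list(target.feature_ids):
            source = pp.remap_source_to_target_peaks(source, list(target.feature_ids))
        source = pp.binarize_and_filter(source, min_cell_fraction)
        target = pp.binarize_and_filter(target, min_cell_fraction)
    else:
        source = pp.normalize_rna(pp.prevalence_filter(source, min_cell_fraction))
        target = pp.normalize_rna(pp.prevalence_filter(target, min_cell_fraction))

    shared = [f for f in source.feature_ids if f in set(target.feature_ids)]
    if not shared:
        raise ValueError("no shared features after filtering")
    src_idx = {f: i for i, f in enumerate(source.feature_ids)}
    tgt_idx = {f: i for i, f in enumerate(target.feature_ids)}
    source = source.subset_features([src_idx[f] for f in shared])
    target = target.subset_features([tgt_idx[f] for f in shared])

    stacked = np.vstack([pp._as_dense(source.matrix), pp._as_dense(target.matrix)])
    scores = pp.feature_variance(stacked)
    n_keep = min(n_features, len(shared))
    selected = np.sort(np.argsort(-scores, kind="stable")[:n_keep])

    def _finish(ds: pp.RawDataset) -> pp.ProcessedDataset:
        sub = ds.subset_features(selected)
        return pp.ProcessedDataset(
            matrix=pp._as_dense(sub.matrix).astype(np.float32),
            selected_feature_ids=list(sub.feature_ids),
            cell_ids=list(ds.cell_ids),
            labels=None if ds.labels is None else list(ds.labels),
            modality=modality,
            provenance={"n_features": n_features,
                        "min_cell_fraction": min_cell_fraction,
                        "scored_on": "source+target"},
        )

    return _finish(source), _finish(target)
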