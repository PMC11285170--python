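"""Inference: final per-cell annotations and the latent embedding.

Prediction is deterministic — the encoder mean mu is used, no posterior
sampling — and training-free: nothing here touches model parameters or the
boundary vector. A cell is labeled with the closed-set argmax type if that
type's one-vs-all head exceeds 0.5, otherwise "unknown". Optionally the
learned per-head boundary can replace the 0.5 gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import UNKNOWN
from .networks import AnnotatorNet
from .trainer import assign_pseudo_labels


@dataclass
class PredictionSet:
    cell_ids: list
    labels: list  # known type name or "unknown"
    closed_probs: np.ndarray  # N x K
    open_probs: np.ndarray  # N x K
    embedding: np.ndarray  # N x L encoder means
    class_names: list


def predict(net: AnnotatorNet, target, class_names=None, batch_size: int = 256,
            gate_with_boundary=None) -> PredictionSet:
    """Annotate every target cell.

    ``target`` is a ProcessedDataset or a plain matrix. If both the model
    and the dataset carry feature lists they must match exactly.
    ``gate_with_boundary`` optionally supplies a BoundaryVector to gate
    with instead of the fixed 0.5.
    """
    matrix = np.asarray(getattr(target, "matrix", target), dtype=np.float32)
    cell_ids = list(getattr(target, "cell_ids", range(matrix.shape[0])))
    if class_names is None:
        class_names = getattr(net, "class_names", None)
    if class_names is None:
        class_names = [f"type_{j + 1}" for j in range(net.config.n_known_types)]

    model_features = getattr(net, "feature_ids", None)
    data_features = getattr(target, "selected_feature_ids", None)
    if model_features is not None and data_features is not None:
        if list(model_features) != list(data_features):
            missing = [f for f in model_features if f not in set(data_features)]
            raise ValueError(
                f"target features do not match the model's; "
                f"{len(missing)} model features missing, e.g. {missing[:5]}"
            )
    if matrix.shape[1] != net.config.input_dim:
        raise ValueError(
            f"target has {matrix.shape[1]} features, model expects "
            f"{net.config.input_dim}"
        )

    mus, closed, open_ = [], [], []
    for start in range(0, matrix.shape[0], batch_size):
        latent = net.encode(matrix[start:start + batch_size])
        mus.append(latent.mu.data)
        closed.append(net.closed_forward(latent.mu).data)
        open_.append(net.open_forward(latent.mu).data)
    mu = np.concatenate(mus) if mus else np.zeros((0, net.config.embedding_dim))
    closed_probs = np.concatenate(closed) if closed else np.zeros((0, len(class_names)))
    open_probs = np.concatenate(open_) if open_ else np.zeros((0, len(class_names)))

    if gate_with_boundary is not None:
        j_star = np.argmax(closed_probs, axis=1)
        gate = open_probs[np.arange(len(j_star)), j_star]
        threshold = np.asarray(gate_with_boundary.values)[j_star]
        labels = [class_names[j] if g > t else UNKNOWN
                  for j, g, t in zip(j_star, gate, threshold)]
    else:
        labels = assign_pseudo_labels(closed_probs, open_probs, class_names)

    return PredictionSet(cell_ids=cell_ids, labels=list(labels),
                         closed_probs=closed_probs, open_probs=open_probs,
                         embedding=mu, class_names=list(class_names))


def predictions_frame(pred: PredictionSet):
    """Per-cell table: cell_id, predicted_label, closed_max_prob, open_gate_prob."""
    import pandas as pd

    j_star = np.argmax(pred.closed_probs, axis=1)
    idx = np.arange(len(j_star))
    return pd.DataFrame({
        "cell_id": [str(c) for c in pred.cell_ids],
        "predicted_label": pred.labels,
        "closed_max_prob": pred.closed_probs[idx, j_star],
        "open_gate_prob": pred.open_probs[idx, j_star],
    })


def export_embedding(pred: PredictionSet, h5ad_path=None, csv_path=None):
    """Write the latent embedding with cell ids and labels to H5AD (matrix in
    the dimensional-reduction slot) and/or CSV. Row order is preserved."""
    import anndata as ad
    import pandas as pd

    frame = pd.DataFrame(
        pred.embedding,
        index=pd.Index([str(c) for c in pred.cell_ids], name="cell_id"),
        columns=[f"latent_{i}" for i in range(pred.embedding.shape[1])],
    )
    frame.insert(0, "predicted_label", pred.labels)
    if csv_path is not None:
        frame.to_csv(csv_path)
    if h5ad_path is not None:
        obs = pd.DataFrame({"predicted_label": pred.labels},
                           index=frame.index)
        adata = ad.AnnData(X=np.zeros((len(pred.cell_ids), 0), dtype=np.float32),
                           obs=obs)
        adata.obsm["X_latent"] = np.asarray(pred.embedding, dtype=np.float32)
        adata.write_h5ad(h5ad_path)
    return frame
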