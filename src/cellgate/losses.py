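"""Training objectives.

Five terms drive training:

* ``kl_divergence`` — variational regulariser pulling the posterior
  N(mu, sigma^2) toward N(0, I).
* ``reconstruction_loss`` — Bernoulli (binary cross-entropy) for
  accessibility matrices, mean squared error for expression data.
* ``closed_loss`` — cross-entropy of the closed-set softmax on labeled
  source cells.
* ``open_source_loss`` — per-head one-vs-all loss on source cells with
  hard-example weighting (each cell's weight is its own error probability
  p_hat) and class-rebalancing alpha = #negatives/#positives on positives.
* ``open_target_loss`` — adversarial boundary loss on unlabeled target
  cells: cross-entropy toward the per-head soft boundary P^B_j, weighted by
  beta (largest for cells whose probability sits near the boundary). Routed
  through the gradient-reversal layer, the heads pull target probabilities
  toward P^B while the encoder pushes them away, separating known-type
  cells (driven above the boundary) from novel ones (driven below).

All functions accept autodiff Tensors and return scalar Tensors; the
constant weights (alpha, beta) are plain NumPy arrays, excluded from the
gradient. EPS clamps every log argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, ensure_tensor

EPS = 1e-7


class BoundaryVector:
    """Per-head probability boundary P^B, one entry per known type."""

    def __init__(self, values):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 1 or np.any(values < 0) or np.any(values > 1):
            raise ValueError("boundary must be a 1-D vector of probabilities")
        self.values = values

    @classmethod
    def initial(cls, n_heads: int) -> "BoundaryVector":
        return cls(np.full(n_heads, 0.5))

    def __len__(self):
        return len(self.values)

    def copy(self) -> "BoundaryVector":
        return BoundaryVector(self.values.copy())


@dataclass
class LossBreakdown:
    kl: float = 0.0
    recon: float = 0.0
    sup_c: float = 0.0
    sup_o: float = 0.0
    sup_t: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k))
                for k in ("kl", "recon", "sup_c", "sup_o", "sup_t", "total")}


def kl_divergence(mu, log_var) -> Tensor:
    """Mean over cells of sum over latent dims of
    (1/2)(-1 - log sigma^2 + mu^2 + sigma^2)."""
    mu, log_var = ensure_tensor(mu), ensure_tensor(log_var)
    if mu.shape != log_var.shape:
        raise ValueError("mu and log_var shapes differ")
    if not (np.all(np.isfinite(mu.data)) and np.all(np.isfinite(log_var.data))):
        raise ValueError("non-finite latent parameters")
    per_cell = (mu.square() + log_var.exp() - log_var - 1.0) * 0.5
    if per_cell.ndim == 1:
        return per_cell.sum() * (1.0 / 1)
    return per_cell.sum(axis=1).mean()


def reconstruction_loss(x_hat, x, modality: str) -> Tensor:
    """Per-cell reconstruction error, averaged over cells.

    atac: negative log-likelihood under a multivariate Bernoulli — binary
    cross-entropy summed over features (so the term is on the same
    per-cell scale as the KL, which sums over latent dimensions). rna:
    squared error summed over genes, averaged over cells.
    """
    x_hat, x = ensure_tensor(x_hat), ensure_tensor(x)
    if x_hat.shape != x.shape:
        raise ValueError("x_hat and x shapes differ")
    if modality == "atac":
        if not np.isin(x.data, (0.0, 1.0)).all():
            raise ValueError("binary reconstruction target must be 0/1")
        p = x_hat.clip(EPS, 1.0 - EPS)
        per_cell = -(x * p.log() + (1.0 - x) * (1.0 - p).log()).sum(axis=-1)
    elif modality == "rna":
        per_cell = (x_hat - x).square().sum(axis=-1)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    if per_cell.ndim == 0:
        return per_cell
    return per_cell.mean()


def closed_loss(closed_probs, labels) -> Tensor:
    """Mean negative log-probability of the true type (labels are 0-based)."""
    probs = ensure_tensor(closed_probs)
    labels = np.asarray(labels)
    n, k = probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label outside the known-type vocabulary")
    true_p = probs[np.arange(n), labels]
    return -true_p.clip(EPS, 1.0).log().mean()


def alpha_weights(labels, j: int, n_classes: int | None = None) -> np.ndarray:
    """Class-rebalancing weights for head j: positives get
    (#negatives / #positives); negatives get 1.

    With zero positives in the batch the ratio is undefined; positives do
    not exist so all weights are 1 and the head's positive term is skipped.
    """
    labels = np.asarray(labels)
    pos = labels == j
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    weights = np.ones(len(labels))
    if n_pos > 0:
        weights[pos] = n_neg / n_pos
    return weights


def open_source_loss(open_probs, labels, return_parts: bool = False) -> Tensor:
    """One-vs-all source loss over all K heads.

    For head j, a cell's error probability is p_hat = 1 - p for positives
    (true type j) and p for negatives. The per-cell term is
    -alpha * p_hat * log(1 - p_hat): the factor p_hat focuses each head on
    its hard cells, and alpha rebalances the rarer positives. Normalised by
    the number of cells only (not by K).
    """
    probs = ensure_tensor(open_probs)
    labels = np.asarray(labels)
    n, k = probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label outside the known-type vocabulary")
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    pos_counts = onehot.sum(axis=0)
    neg_counts = n - pos_counts
    alpha = np.where(onehot == 1.0,
                     neg_counts / np.maximum(pos_counts, 1.0),
                     1.0).astype(np.float32)
    p_hat = onehot * (1.0 - probs) + (1.0 - onehot) * probs
    p_hat = p_hat.clip(0.0, 1.0 - EPS)
    loss = -(Tensor(alpha) * p_hat * (1.0 - p_hat).log()).sum() * (1.0 / n)
    return loss


def beta_weights(probs_j: np.ndarray, boundary_j: float) -> np.ndarray:
    """Target-cell weights for head j given its boundary Pb.

    Branches, evaluated in order with the first match winning:
    p > Pb -> 1 - p; 1 - Pb < p <= Pb -> 1 - Pb; p <= 1 - Pb -> p.
    Weight peaks for cells near the boundary and is capped at 1 - Pb in
    the interior band.
    """
    p = np.asarray(probs_j, dtype=np.float64)
    pb = float(boundary_j)
    return np.select(
        [p > pb, (1.0 - pb < p) & (p <= pb)],
        [1.0 - p, np.full_like(p, 1.0 - pb)],
        default=p,
    )


def plain_bce_open_loss(open_probs, labels) -> Tensor:
    """Ablation variant of the source one-vs-all loss: ordinary binary
    cross-entropy per head, without hard-example or class reweighting.
    Normalised by the number of cells only, matching open_source_loss."""
    probs = ensure_tensor(open_probs)
    labels = np.asarray(labels)
    n, k = probs.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    p = probs.clip(EPS, 1.0 - EPS)
    y = Tensor(onehot)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).sum() * (1.0 / n)


def open_target_loss(open_probs, boundary: BoundaryVector,
                     use_beta: bool = True) -> Tensor:
    """Adversarial boundary loss on target cells, mean over cells and heads:
    beta * (-Pb log p - (1 - Pb) log(1 - p)).

    beta is a constant weight (no gradient); run through the
    gradient-reversal path the heads minimise this cross-entropy toward the
    soft label Pb while the encoder maximises it.
    """
    probs = ensure_tensor(open_probs)
    n, k = probs.shape
    if len(boundary) != k:
        raise ValueError("boundary length must equal the number of heads")
    pb = boundary.values.astype(np.float32)[None, :]
    if use_beta:
        beta = np.empty((n, k), dtype=np.float32)
        for j in range(k):
            beta[:, j] = beta_weights(probs.data[:, j], boundary.values[j])
    else:
        beta = np.ones((n, k), dtype=np.float32)
    p = probs.clip(EPS, 1.0 - EPS)
    ce = -(Tensor(pb) * p.log() + Tensor(1.0 - pb) * (1.0 - p).log())
    return (Tensor(beta) * ce).sum() * (1.0 / (n * k))


def total_loss(parts: dict, weights: dict | None = None) -> Tensor:
    """Weighted sum of loss terms; every coefficient defaults to 1."""
    weights = weights or {}
    if any(w < 0 for w in weights.values()):
        raise ValueError("loss coefficients must be nonnegative")
    total = None
    for name, term in parts.items():
        weighted = ensure_tensor(term) * float(weights.get(name, 1.0))
        total = weighted if total is None else total + weighted
    return total
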