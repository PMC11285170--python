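"""Training loop for the open-set annotator.

Each step draws one labeled source mini-batch and one unlabeled target
mini-batch, pushes both through the shared encoder, and takes a single
AdamW step on

    KL + reconstruction (both domains) + closed-set cross-entropy (source)
    + one-vs-all source loss + adversarial boundary loss (target, through
    the gradient-reversal layer).

After the optimizer step, the target batch's pseudo-labels (closed-set
argmax gated by its one-vs-all head at 0.5) and the per-head boundary
vector P^B (the top-5% point of the batch's head probabilities, ascending
nearest-rank) are refreshed. Ablation switches divert exactly one term
each: plain-BCE source loss, frozen boundary at 0.5, beta weights off, or
no target loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import losses
from .autodiff import Tensor
from .losses import BoundaryVector, LossBreakdown
from .metrics import UNKNOWN
from .networks import AnnotatorNet, ModelConfig


@dataclass
class Ablations:
    plain_bce_source: bool = False
    fixed_boundary: bool = False
    no_beta: bool = False
    no_target_loss: bool = False


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 4000
    learning_rate: float = 2e-4
    weight_decay: float | None = None  # resolved per modality: 5e-4 atac, 5e-5 rna
    top_interval: float = 0.05
    seed: int = 0
    boundary_momentum: float = 0.0
    loss_weights: dict = field(default_factory=dict)
    ablations: Ablations = field(default_factory=Ablations)

    def __post_init__(self):
        if not 0 <= self.top_interval < 1:
            raise ValueError("top_interval must be in [0, 1)")
        if self.batch_size < 2 or self.epochs < 1:
            raise ValueError("batch_size must be >= 2 and epochs >= 1")

    def resolved_weight_decay(self, modality: str) -> float:
        if self.weight_decay is not None:
            return self.weight_decay
        return 5e-4 if modality == "atac" else 5e-5


@dataclass
class TargetState:
    pseudo_labels: list  # per target cell, known type name or "unknown"
    boundary: BoundaryVector


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def assign_pseudo_labels(closed_probs, open_probs, class_names=None):
    """Closed-set argmax gated by its one-vs-all head at a strict 0.5.

    Returns integer type indices with -1 for unknown, or names (with
    ``"unknown"``) when ``class_names`` is given. Ties in the closed-set
    argmax go to the lowest index.
    """
    closed = np.asarray(getattr(closed_probs, "data", closed_probs))
    open_ = np.asarray(getattr(open_probs, "data", open_probs))
    j_star = np.argmax(closed, axis=1)
    gate = open_[np.arange(len(j_star)), j_star]
    labels = np.where(gate > 0.5, j_star, -1)
    if class_names is None:
        return labels
    return [class_names[j] if j >= 0 else UNKNOWN for j in labels]


def update_boundary(open_probs_batch, top_interval: float,
                    current: BoundaryVector, momentum: float = 0.0) -> BoundaryVector:
    """Per-head nearest-rank (1 - top_interval) quantile of the batch.

    Probabilities are sorted ascending and the value at 0-based index
    ceil((1 - top_interval) * n) - 1 becomes the new boundary (the top-5%
    point by default); with ``momentum`` the old value is blended in.
    """
    probs = np.asarray(getattr(open_probs_batch, "data", open_probs_batch))
    n = probs.shape[0]
    if n < 1:
        raise ValueError("boundary update needs at least one target cell")
    idx = max(int(np.ceil((1.0 - top_interval) * n)) - 1, 0)
    new_values = np.sort(probs, axis=0)[idx, :]
    blended = momentum * current.values + (1.0 - momentum) * new_values
    return BoundaryVector(blended)


def train_step(net: AnnotatorNet, optimizer: AdamW,
               source_x, source_labels, target_x,
               boundary: BoundaryVector, config: TrainConfig,
               rng: np.random.Generator):
    """One joint optimization step; returns (LossBreakdown, new_boundary,
    target pseudo-label indices for this batch)."""
    ab = config.ablations
    n_src = source_x.shape[0]
    x_all = Tensor(np.concatenate([source_x, target_x], axis=0))
    latent = net.encode(x_all)
    z = net.reparameterize(latent, rng)
    recon = net.decode(z)

    kl = losses.kl_divergence(latent.mu, latent.log_var)
    recon_loss = losses.reconstruction_loss(recon, x_all, net.config.modality)

    z_src, z_tgt = z[:n_src], z[n_src:]
    log_probs_src = net.closed_log_probs(z_src)
    sup_c = -log_probs_src[np.arange(n_src), np.asarray(source_labels)].mean()

    open_src = net.open_forward(z_src)
    if ab.plain_bce_source:
        sup_o = losses.plain_bce_open_loss(open_src, source_labels)
    else:
        sup_o = losses.open_source_loss(open_src, source_labels)

    if ab.no_target_loss:
        sup_t = Tensor(0.0)
    else:
        open_tgt_rev = net.open_forward(z_tgt, reverse=True)
        sup_t = losses.open_target_loss(open_tgt_rev, boundary,
                                        use_beta=not ab.no_beta)

    parts = {"kl": kl, "recon": recon_loss, "sup_c": sup_c,
             "sup_o": sup_o, "sup_t": sup_t}
    for name, term in parts.items():
        if not np.isfinite(term.data):
            raise RuntimeError(f"non-finite loss term: {name}")
    total = losses.total_loss(parts, config.loss_weights)

    optimizer.zero_grad()
    total.backward()
    optimizer.step()

    # bookkeeping after the step: refresh this batch's pseudo-labels and
    # boundary from the updated parameters, using the deterministic mean
    latent_t = net.encode(target_x)
    closed_t = net.closed_forward(latent_t.mu)
    open_t = net.open_forward(latent_t.mu)
    pseudo = assign_pseudo_labels(closed_t, open_t)
    if ab.fixed_boundary:
        new_boundary = boundary
    else:
        new_boundary = update_boundary(open_t, config.top_interval, boundary,
                                       config.boundary_momentum)

    breakdown = LossBreakdown(kl=float(kl.data), recon=float(recon_loss.data),
                              sup_c=float(sup_c.data), sup_o=float(sup_o.data),
                              sup_t=float(sup_t.data), total=float(total.data))
    return breakdown, new_boundary, pseudo


def _epoch_batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def fit(source, target, train_config: TrainConfig | None = None,
        model_config: ModelConfig | None = None, net: AnnotatorNet | None = None,
        callback=None):
    """Epoch loop around the joint step.

    ``source``/``target`` are ProcessedDataset-like objects (``matrix``,
    ``labels`` on source). Source and target batches are drawn
    independently with reshuffling each epoch; the shorter stream cycles.
    Returns (net, TargetState, history) where history is one aggregated
    LossBreakdown dict per epoch.
    """
    config = train_config or TrainConfig()
    if target.matrix.shape[0] == 0:
        raise ValueError("empty target dataset")
    if source.labels is None:
        raise ValueError("source labels are required")

    class_names = sorted(set(source.labels))
    if len(class_names) < 2:
        warnings.warn("fewer than 2 known types; open-set training is degenerate")
    label_index = {c: i for i, c in enumerate(class_names)}
    y_src = np.asarray([label_index[l] for l in source.labels])

    if net is None:
        if model_config is None:
            model_config = ModelConfig(input_dim=source.matrix.shape[1],
                                       n_known_types=len(class_names),
                                       modality=source.modality)
        net = AnnotatorNet(model_config, seed=config.seed)
    optimizer = AdamW(net.parameters(), lr=config.learning_rate,
                      weight_decay=config.resolved_weight_decay(net.config.modality))

    rng = np.random.default_rng(config.seed)
    boundary = BoundaryVector.initial(len(class_names))
    pseudo = np.full(target.matrix.shape[0], -1, dtype=int)
    src_x = np.asarray(source.matrix, dtype=np.float32)
    tgt_x = np.asarray(target.matrix, dtype=np.float32)

    history = []
    for epoch in range(config.epochs):
        src_batches = _epoch_batches(len(src_x), config.batch_size, rng)
        tgt_batches = _epoch_batches(len(tgt_x), config.batch_size, rng)
        n_steps = max(len(src_batches), len(tgt_batches))
        sums = np.zeros(6)
        for step in range(n_steps):
            sb = src_batches[step % len(src_batches)]
            tb = tgt_batches[step % len(tgt_batches)]
            breakdown, boundary, batch_pseudo = train_step(
                net, optimizer, src_x[sb], y_src[sb], tgt_x[tb],
                boundary, config, rng)
            pseudo[tb] = batch_pseudo
            sums += [breakdown.kl, breakdown.recon, breakdown.sup_c,
                     breakdown.sup_o, breakdown.sup_t, breakdown.total]
        epoch_mean = sums / n_steps
        history.append({"epoch": epoch,
                        "kl": epoch_mean[0], "recon": epoch_mean[1],
                        "sup_c": epoch_mean[2], "sup_o": epoch_mean[3],
                        "sup_t": epoch_mean[4], "total": epoch_mean[5]})
        if callback is not None:
            callback(epoch, history[-1])

    pseudo_names = [class_names[j] if j >= 0 else UNKNOWN for j in pseudo]
    state = TargetState(pseudo_labels=pseudo_names, boundary=boundary)
    net.class_names = class_names
    return net, state, history
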