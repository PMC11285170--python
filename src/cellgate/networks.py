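"""Network components of the open-set annotator.

A shared variational encoder embeds source and target cells into an
``L``-dimensional latent space. Three single-layer heads consume the
embedding: a decoder reconstructing the input (sigmoid outputs for binary
accessibility data), a closed-set softmax classifier over the K known cell
types, and a bank of K one-vs-all sigmoid heads (the open-set classifier).
A gradient-reversal connector makes the encoder and the open-set heads
adversaries on target data.

Source and target batches flow through identical parameters; nothing here
conditions on the domain of a batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, ensure_tensor

DEFAULT_WIDTHS = {"atac": [3200, 1600, 800, 400], "rna": [256, 128, 128]}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` defaults to the modality-specific stack
    (atac: 3200-1600-800-400, rna: 256-128-128); ``embedding_dim`` is the
    latent size L; ``grl_coefficient`` is the gradient-reversal strength
    applied on the adversarial target path.
    """

    input_dim: int = 0
    n_known_types: int = 0
    modality: str = "atac"
    encoder_widths: list = field(default_factory=list)
    embedding_dim: int = 32
    grl_coefficient: float = 1.0

    def __post_init__(self):
        if self.modality not in ("atac", "rna"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.encoder_widths:
            self.encoder_widths = list(DEFAULT_WIDTHS[self.modality])
        if self.embedding_dim < 1 or any(w < 1 for w in self.encoder_widths):
            raise ValueError("layer widths must be >= 1")
        if self.grl_coefficient < 0:
            raise ValueError("grl_coefficient must be nonnegative")


@dataclass
class LatentBatch:
    """Per-cell variational posterior: mean, log-variance and a sample z."""

    mu: Tensor
    log_var: Tensor
    z: Tensor | None = None


class Linear:
    """Affine map with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor.param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Tensor.param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    @property
    def parameters(self):
        return [self.weight, self.bias]


class AnnotatorNet:
    """Parameter container and forward passes for all four components."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.input_dim < 1 or config.n_known_types < 1:
            raise ValueError("input_dim and n_known_types must be set")
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [config.input_dim] + list(config.encoder_widths)
        self.encoder_layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        last = dims[-1]
        L = config.embedding_dim
        self.mu_head = Linear(last, L, rng)
        self.log_var_head = Linear(last, L, rng)
        self.decoder = Linear(L, config.input_dim, rng)
        self.closed_head = Linear(L, config.n_known_types, rng)
        self.open_heads = Linear(L, config.n_known_types, rng)

    def parameters(self) -> list:
        params = []
        for layer in self.encoder_layers:
            params += layer.parameters
        for head in (self.mu_head, self.log_var_head, self.decoder,
                     self.closed_head, self.open_heads):
            params += head.parameters
        return params

    # -- forward passes -------------------------------------------------------

    def encode(self, x) -> LatentBatch:
        h = ensure_tensor(x)
        if h.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"input has {h.shape[-1]} features, model expects {self.config.input_dim}"
            )
        for layer in self.encoder_layers:
            h = layer(h).relu()
        return LatentBatch(mu=self.mu_head(h), log_var=self.log_var_head(h))

    @staticmethod
    def reparameterize(latent: LatentBatch, rng: np.random.Generator) -> Tensor:
        """Sample z = mu + sigma * eps with eps ~ N(0, I)."""
        eps = rng.standard_normal(latent.mu.shape).astype(np.float32)
        z = latent.mu + (latent.log_var * 0.5).exp() * eps
        latent.z = z
        return z

    def decode(self, z: Tensor) -> Tensor:
        out = self.decoder(ensure_tensor(z))
        if self.config.modality == "atac":
            out = out.sigmoid()
        return out

    def closed_log_probs(self, z: Tensor) -> Tensor:
        return self.closed_head(ensure_tensor(z)).log_softmax(axis=-1)

    def closed_forward(self, z: Tensor) -> Tensor:
        """Softmax probabilities over the K known types."""
        return self.closed_log_probs(z).exp()

    def open_forward(self, z: Tensor, reverse: bool = False,
                     grl_coefficient: float | None = None) -> Tensor:
        """K independent one-vs-all membership probabilities.

        With ``reverse``, forward values are unchanged but gradients flowing
        from the heads back into the encoder are multiplied by -lambda
        (gradient reversal): the heads descend the adversarial loss while the
        encoder ascends it.
        """
        z = ensure_tensor(z)
        if reverse:
            lam = self.config.grl_coefficient if grl_coefficient is None else grl_coefficient
            z = z.grad_scale(-lam)
        return self.open_heads(z).sigmoid()

    # -- serialization --------------------------------------------------------

    def _named_params(self) -> dict:
        named = {}
        for i, layer in enumerate(self.encoder_layers):
            named[f"encoder/{i}/weight"] = layer.weight
            named[f"encoder/{i}/bias"] = layer.bias
        for name, head in (("mu", self.mu_head), ("log_var", self.log_var_head),
                           ("decoder", self.decoder), ("closed", self.closed_head),
                           ("open", self.open_heads)):
            named[f"{name}/weight"] = head.weight
            named[f"{name}/bias"] = head.bias
        return named

    def save(self, path, boundary=None, class_names=None, extra: dict | None = None):
        """Write all parameters plus config (and optionally the per-head
        decision boundary and label vocabulary) to one HDF5 checkpoint."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            for key, tensor in self._named_params().items():
                f.create_dataset(f"params/{key}", data=tensor.data)
            if boundary is not None:
                f.create_dataset("boundary", data=np.asarray(boundary))
            if class_names is not None:
                f.create_dataset(
                    "class_names",
                    data=np.asarray([str(c) for c in class_names], dtype="S"),
                )
            if extra:
                f.attrs["extra"] = json.dumps(extra)

    @classmethod
    def load(cls, path):
        """Read a checkpoint; returns (net, boundary, class_names)."""
        import h5py

        with h5py.File(path, "r") as f:
            config = ModelConfig(**json.loads(f.attrs["config"]))
            net = cls(config, seed=0)
            for key, tensor in net._named_params().items():
                tensor.data = f[f"params/{key}"][...].astype(np.float32)
            boundary = f["boundary"][...] if "boundary" in f else None
            class_names = (
                [c.decode() for c in f["class_names"][...]]
                if "class_names" in f else None
            )
        return net, boundary, class_names
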