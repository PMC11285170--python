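"""Synthetic source/target dataset pairs with known ground truth.

The generator emulates the open-set annotation setting: a labeled source
batch containing K known cell types and an unlabeled target batch drawn
from the same types plus extra, target-only ("novel") types. Accessibility
is a product-Bernoulli model — each type owns a disjoint set of marker
peaks that are open with probability ``p_open`` while every other peak
opens with probability ``p_background`` — and the target batch carries a
batch effect as a global shift of all open-probabilities on the logit
scale. Expression data are negative-binomial counts with marker genes
up-shifted in their type and log-normal library sizes.

Everything is deterministic under the config seed; class counts are
allocated exactly (largest-remainder), so e.g. a 20% novel fraction of 500
target cells is exactly 100 cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RawDataset


@dataclass
class SynthConfig:
    n_source: int = 500
    n_target: int = 500
    n_peaks: int = 2000
    known_types: int = 4
    n_unknown_types: int = 1
    p_open: float = 0.6
    p_background: float = 0.05
    marker_peaks_per_type: int = 150
    batch_logit_shift: float = 0.5
    source_proportions: list | None = None  # simplex over K known types
    target_proportions: list | None = None  # simplex over K + n_unknown types
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_background < self.p_open < 1:
            raise ValueError("need 0 < p_background < p_open < 1")
        total_types = self.known_types + self.n_unknown_types
        if self.marker_peaks_per_type * total_types > self.n_peaks:
            raise ValueError("marker peaks exceed the peak count")
        for props, n in ((self.source_proportions, self.known_types),
                         (self.target_proportions, total_types)):
            if props is not None:
                arr = np.asarray(props, dtype=float)
                if len(arr) != n or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                    raise ValueError("proportions must be a simplex vector")

    @property
    def known_type_names(self) -> list:
        return [f"type_{i + 1}" for i in range(self.known_types)]

    @property
    def unknown_type_names(self) -> list:
        return [f"novel_{i + 1}" for i in range(self.n_unknown_types)]


@dataclass
class SynthPair:
    source: RawDataset
    target: RawDataset
    truth: list  # true target labels, including novel types
    marker_peaks: dict  # type name -> marker column indices


def _allocate_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder integer allocation of n cells to proportions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _type_assignment(n, proportions, names, rng) -> list:
    counts = _allocate_counts(n, np.asarray(proportions, dtype=float))
    labels = [name for name, c in zip(names, counts) for _ in range(c)]
    order = rng.permutation(n)
    return [labels[i] for i in order]


def _marker_map(config: SynthConfig, rng) -> dict:
    names = config.known_type_names + config.unknown_type_names
    chosen = rng.choice(config.n_peaks,
                        size=config.marker_peaks_per_type * len(names),
                        replace=False)
    return {name: np.sort(chosen[i * config.marker_peaks_per_type:
                                 (i + 1) * config.marker_peaks_per_type])
            for i, name in enumerate(names)}


def _open_probs(labels, markers, config: SynthConfig, shift: float) -> np.ndarray:
    probs = np.full((len(labels), config.n_peaks), config.p_background)
    for i, lab in enumerate(labels):
        probs[i, markers[lab]] = config.p_open
    if shift != 0.0:
        logit = np.log(probs / (1.0 - probs)) + shift
        probs = 1.0 / (1.0 + np.exp(-logit))
    return probs


def generate_atac(config: SynthConfig) -> SynthPair:
    """Draw a binary source/target accessibility pair under the config."""
    rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    k, u = config.known_types, config.n_unknown_types
    src_props = (config.source_proportions if config.source_proportions is not None
                 else np.full(k, 1.0 / k))
    tgt_props = (config.target_proportions if config.target_proportions is not None
                 else np.full(k + u, 1.0 / (k + u)))
    src_labels = _type_assignment(config.n_source, src_props,
                                  config.known_type_names, rng)
    tgt_labels = _type_assignment(config.n_target, tgt_props,
                                  config.known_type_names + config.unknown_type_names,
                                  rng)
    peak_ids = [f"chr1:{1000 * i}-{1000 * i + 500}" for i in range(config.n_peaks)]

    src_matrix = (rng.random((config.n_source, config.n_peaks))
                  < _open_probs(src_labels, markers, config, 0.0)).astype(np.float32)
    tgt_matrix = (rng.random((config.n_target, config.n_peaks))
                  < _open_probs(tgt_labels, markers, config,
                                config.batch_logit_shift)).astype(np.float32)

    source = RawDataset(matrix=src_matrix, feature_ids=peak_ids,
                        cell_ids=[f"src_{i}" for i in range(config.n_source)],
                        labels=src_labels, modality="atac")
    target = RawDataset(matrix=tgt_matrix, feature_ids=peak_ids,
                        cell_ids=[f"tgt_{i}" for i in range(config.n_target)],
                        labels=None, modality="atac")
    return SynthPair(source=source, target=target, truth=tgt_labels,
                     marker_peaks=markers)


def generate_rna(config: SynthConfig, mean_depth: int = 5000,
                 marker_fold: float = 4.0, dispersion: float = 10.0) -> SynthPair:
    """Negative-binomial expression pair; markers are up-shifted
    ``marker_fold``-fold in their own type. The batch effect perturbs
    target gene means by exp(shift * u_g) with fixed per-gene u ~ U(-1,1)."""
    rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    k, u = config.known_types, config.n_unknown_types
    src_props = (config.source_proportions if config.source_proportions is not None
                 else np.full(k, 1.0 / k))
    tgt_props = (config.target_proportions if config.target_proportions is not None
                 else np.full(k + u, 1.0 / (k + u)))
    src_labels = _type_assignment(config.n_source, src_props,
                                  config.known_type_names, rng)
    tgt_labels = _type_assignment(config.n_target, tgt_props,
                                  config.known_type_names + config.unknown_type_names,
                                  rng)
    gene_ids = [f"gene_{i}" for i in range(config.n_peaks)]

    base = rng.gamma(shape=2.0, scale=0.5, size=config.n_peaks)
    batch_u = rng.uniform(-1.0, 1.0, size=config.n_peaks)

    def _draw(labels, batch_shift):
        rates = np.tile(base, (len(labels), 1))
        for i, lab in enumerate(labels):
            rates[i, markers[lab]] *= marker_fold
        if batch_shift:
            rates = rates * np.exp(batch_shift * batch_u)[None, :]
        depth = rng.lognormal(mean=np.log(mean_depth), sigma=0.3, size=len(labels))
        rates = rates / rates.sum(axis=1, keepdims=True) * depth[:, None]
        p = dispersion / (dispersion + rates)
        return rng.negative_binomial(dispersion, p).astype(np.float32)

    source = RawDataset(matrix=_draw(src_labels, 0.0), feature_ids=gene_ids,
                        cell_ids=[f"src_{i}" for i in range(config.n_source)],
                        labels=src_labels, modality="rna")
    target = RawDataset(matrix=_draw(tgt_labels, config.batch_logit_shift),
                        feature_ids=gene_ids,
                        cell_ids=[f"tgt_{i}" for i in range(config.n_target)],
                        labels=None, modality="rna")
    return SynthPair(source=source, target=target, truth=tgt_labels,
                     marker_peaks=markers)


def default_benchmark(seed: int = 0) -> SynthPair:
    """Canonical fixture: 4 known + 1 novel type, 500 source + 500 target
    cells (novel = exactly 20% of target), 2,000 peaks."""
    return generate_atac(SynthConfig(seed=seed))
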