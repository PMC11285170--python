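"""Canonical synthetic benchmark runs.

One call generates the default benchmark pair (4 known + 1 novel type,
500 source + 500 target cells, 2,000 peaks), trains the annotator for 300
epochs with a compact encoder (256-128, embedding 32) suited to the 2,000-
feature input, and returns the open-set evaluation against the generator's
ground truth. Used by the test suite and the results-reproduction script.
"""

from __future__ import annotations

from .metrics import OpenSetEval
from .model import OpenSetAnnotator
from .networks import ModelConfig
from .synthdata import default_benchmark
from .trainer import Ablations, TrainConfig

BENCHMARK_EPOCHS = 300
BENCHMARK_WIDTHS = [256, 128]


def run_default_benchmark(seed: int, epochs: int = BENCHMARK_EPOCHS,
                          ablations: Ablations | None = None) -> OpenSetEval:
    pair = default_benchmark(seed=seed)
    annotator = OpenSetAnnotator.from_raw(pair.source, pair.target,
                                          n_features=2000)
    annotator.model_config = ModelConfig(
        input_dim=annotator.source.matrix.shape[1],
        n_known_types=len(annotator.class_names),
        modality="atac", encoder_widths=list(BENCHMARK_WIDTHS))
    annotator.train_config = TrainConfig(
        epochs=epochs, seed=seed, ablations=ablations or Ablations())
    result = annotator.fit()
    return result.evaluate(pair.truth)
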