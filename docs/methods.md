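# Methods

## Problem setting

Automatic cell-type annotation transfers labels from an annotated (source)
single-cell dataset to an unlabeled (target) dataset. Two things make this
hard for chromatin-accessibility (scATAC-seq) data: systematic distribution
shift between batches (batch effects), and the open-set problem — the
target may contain cell types the source has never seen, which a closed-set
classifier will silently mislabel as its nearest known type. cellgate
treats annotation as open-set domain adaptation: known target cells should
receive their type, novel target cells should be rejected as "unknown".

## Model

Let `X^s ∈ R^{N_s×m}` be the processed source matrix with labels over K
known types, and `X^t ∈ R^{N_t×m}` the processed target matrix. Three
components share a single variational embedding:

* **Shared VAE.** An MLP encoder maps each cell to a posterior
  `N(μ, σ²)` over an L-dimensional latent space (L = 32 by default); a
  sampled `z = μ + σ ⊙ ε` is decoded by a single linear layer back to the
  feature space. For binary accessibility data the decoder output passes
  through a sigmoid and is scored with the multivariate-Bernoulli
  log-likelihood — binary cross-entropy summed over features, averaged over
  cells; for expression data, squared error on the same per-cell scale.
  Keeping reconstruction on the per-cell likelihood scale matters: averaged
  over entries instead, the term is m-fold too weak against the KL, the
  posterior collapses toward the prior over training, and label transfer to
  the shifted target batch degrades with training length. The KL term
  `½(−1 − log σ² + μ² + σ²)`, summed over latent dimensions and averaged
  over cells, regularises the posterior toward `N(0, I)`. Source and
  target pass through identical parameters — weight sharing is the
  domain-adaptation mechanism, and the data never tell the encoder which
  domain a cell came from.
* **Closed-set classifier.** One linear-softmax layer on the embedding,
  trained with cross-entropy on source labels; it always proposes the
  nearest known type.
* **Open-set classifier.** K one-vs-all sigmoid heads, each deciding
  membership in one known type. On source data head j minimises
  `(1/N_s) Σ_i −α_ij p̂_ij log(1 − p̂_ij)` where `p̂` is the head's error
  probability (`1−p` for positives, `p` for negatives) — the `p̂` factor
  focuses the head on its hard cells near the decision boundary — and
  `α = #neg/#pos` rebalances the rarer positives (negatives get α = 1).
  Normalisation is by the number of cells only, not by K.

### Adversarial boundary adaptation on the target

Each head j keeps a probability boundary `P^B_j`, initialised at 0.5. The
target loss is a per-head cross-entropy toward the soft label `P^B_j`,
weighted by `β`:

    L_t = (1/(N·K)) Σ_j Σ_i β_ij · (−P^B_j log p_ij − (1−P^B_j) log(1−p_ij))

with β chosen by the first matching branch of: `1−p` if `p > P^B`;
`1−P^B` if `1−P^B < p ≤ P^B`; `p` otherwise — largest for cells near the
boundary, capped in the interior band. A gradient-reversal layer sits
between the embedding and the heads on this path: the heads descend L_t
(pulling target probabilities toward the boundary) while the encoder
ascends it (pushing them away). Cells resembling a known type get pushed
above the boundary, novel cells below. After every optimizer step the
batch's `P^B_j` is replaced by the nearest-rank 95th percentile of that
head's probabilities in the batch (ascending sort, 0-based index
`ceil(0.95·n) − 1`), so the boundary rises as adaptation proceeds and
progressively excludes near-boundary impostors. Batch pseudo-labels
(closed-set argmax gated by the argmax head at a strict 0.5) are refreshed
at the same time; they are bookkeeping and final output, not a training
signal.

### Prediction

Inference is deterministic: the encoder mean μ is used (no sampling), a
cell receives the closed-set argmax type if that type's head exceeds 0.5,
otherwise "unknown". The learned `P^B` is a training device; gating on it
at test time is available as an option but is not the default.

## Preprocessing

ATAC: counts are binarized; peaks with a nonzero entry in fewer than
`max(1, ceil(0.001·N))` cells are dropped ("at least 0.1% of cells" read
as a lower bound so the filter stays meaningful on small datasets); the
20,000 most variable peaks are kept. Variability is plain per-feature
variance — for binary data this is `p(1−p)`, maximal for peaks open in
half the cells — scored on source and target jointly (the scoring function
and the choice of which batches to score on are configurable). When the
two batches were peak-called separately, source counts are first remapped
onto the target's peaks by genomic-interval overlap (0-based half-open
coordinates; a target peak receives the summed counts of all overlapping
source peaks). RNA: the same prevalence filter on nonzero counts, then
per-cell scaling to 10,000 total counts and log1p, then the 3,000 most
variable genes.

## Training defaults

| parameter | default | notes |
|---|---|---|
| encoder widths | 3200-1600-800-400 (atac), 256-128-128 (rna) | ReLU, no batch norm (keeps per-cell outputs batch-size invariant) |
| embedding L | 32 | |
| batch size | 64 | source and target batches drawn independently, reshuffled per epoch; the shorter stream cycles |
| epochs | 4000 | the synthetic benchmark uses 300 (see below) |
| optimizer | AdamW, lr 2e-4 | weight decay 5e-4 (atac), 5e-5 (rna); conventional β-moments |
| GRL coefficient λ | 1.0 | constant, no ramp-up |
| top interval | 0.05 | boundary = top-5% point per head per batch |
| boundary momentum | 0.0 | direct per-batch replacement; momentum exposed for stability experiments |
| loss weights | 1.0 each | total = KL + recon + closed CE + source OVA + target adversarial |

Numerical choices: the encoder outputs log-variance (σ² = exp) for
stability; every log argument is clamped at ε = 1e-7; closed-set argmax
ties break to the lowest type index; an open-head probability of exactly
0.5 is rejected ("greater than 0.5" is strict). All float work is float32.
Loss gradients come from a small reverse-mode autodiff engine written for
this package and validated against central finite differences in the test
suite; the gradient-reversal layer is its `grad_scale(−λ)` primitive
(identity forward, gradient scaled in backward). With a fixed seed,
training is bitwise reproducible.

Ablation switches divert exactly one term each: plain per-head BCE instead
of the hard-example-weighted source loss; `P^B` frozen at 0.5; β ≡ 1; and
dropping the target loss entirely (the boundary still tracks probabilities
in that case — it just stops receiving adversarial pressure).

## Synthetic data

The generator emulates the open-set design: K known types in the source,
the same K plus extra novel types in the target. Accessibility is a
product-Bernoulli model — each type owns 150 disjoint marker peaks open
with probability 0.6 against a 0.05 background — and the target batch is
shifted by +0.5 on the logit scale of every open-probability (the batch
effect). Class counts are allocated exactly via largest remainder, and
everything is deterministic under the seed. The default benchmark is
4 known + 1 novel type, 500 + 500 cells, 2,000 peaks, so the novel type is
exactly 20% of the target. Expression data use negative-binomial counts
(dispersion 10), 4-fold marker up-shift, log-normal library sizes around
5,000, and a per-gene multiplicative batch factor.

What the generator does **not** emulate: correlated peak programs shared
across types, per-cell depth variation in the binary model, doublets,
trajectory structure, or realistic peak-calling noise. Passing the
benchmark therefore shows that the adversarial boundary machinery
separates known from novel types under a global batch shift with
marker-based identity — not that the method attains any particular score
on real tissue atlases.

## Benchmark problem sizes

The packaged benchmark trains the compact encoder (256-128, embedding 32)
for 300 epochs on the 500+500-cell, 2,000-peak pair — sizes chosen so a
full recovery-plus-ablation sweep runs on a laptop CPU in minutes while
leaving the batch-effect and open-set structure intact. The expected
behaviour (computed, not assumed, by `tests/test_acceptance.py` and
`scripts/acceptance.py`): the full model reaches median EAS ≥ 0.8 and
EAS_M ≥ 0.7 over three seeds, and each single ablation scores no better
than the full model.

## Evaluation

EAS = `N_k^k/N_k − N_u^k/N_u` (fraction of truly-known cells kept inside
the known vocabulary minus the fraction of truly-novel cells wrongly
accepted); EAS_M replaces `N_k^k` with `N_k^true` (correct type required)
and is never above EAS. Cohen's kappa is computed over the K+1-class
confusion matrix with all novel truth types pooled into one "unknown"
class — pooling because the score cannot name unseen types, and including
the unknown class so false rejections of known cells are penalised. If an
evaluation set has no truly-novel (or no truly-known) cells the
corresponding rate is dropped and the result flagged partial, a package
convention for degenerate splits.

## Design choices where the design was open

* The gradient-reversal layer sits between the embedding and the open-set
  heads (heads minimise, encoder maximises) — the conventional adversarial
  placement; reversing the heads too is switchable via the GRL coefficient
  argument.
* α and the boundary quantile are computed per mini-batch; dataset-level
  variants are exposed via configuration (`boundary_momentum`, whole-set
  refresh is a one-call recompute).
* One joint optimizer step covers all five loss terms; no alternating
  sub-steps.
* The α-loss skips a head's positive term in batches with no positives for
  that head (the ratio is undefined there; with batch size 64 and balanced
  sources this is rare).
* Target pseudo-labels are maintained and reported but feed no loss.

## Limitations

* Dense float32 matrices internally; inputs beyond ~10⁵ cells × 2·10⁴
  features need mini-batched streaming that this implementation does not
  provide.
* The adversarial balance assumes the target actually contains novel
  cells; on closed targets the rising boundary can erode recall of rare
  known types (gate on 0.5 prediction mitigates this, but EAS is undefined
  without novel cells).
* No early stopping or λ schedule; training length is the user's choice.
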