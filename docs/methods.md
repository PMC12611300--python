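# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the open design decisions behind `exprssl`. It describes what
the code computes; every empirical statement here is something the test
suite or `scripts/acceptance.py` computes at run time.

## Problem setting

Given a samples × genes expression matrix, the package studies whether
self-supervised pre-training of a dense encoder e : ℝ^N → ℝ^d on unlabeled
profiles improves a downstream multi-class phenotype classifier trained on
a small labeled subset. The two regimes compared are always:

* **baseline** — encoder + linear head initialized randomly, trained
  end-to-end on the labeled subset only;
* **pre-trained** — encoder initialized from a pretext task, then fine-tuned
  either *unfrozen* (all parameters train) or *frozen* (head only; the
  encoder, including its batch-norm statistics, stays bit-identical).

## Pretext tasks

All three tasks share one encoder architecture: `n_layers` dense layers of
width `hidden_dim` (final layer `embedding_dim`), each followed by batch
normalization and ReLU. Heads exist only during pre-training; every
training loop returns the encoder alone.

**Contrastive (SCARF-style).** Each sample is paired with a corrupted view
in which exactly `round(c·d)` feature positions — chosen uniformly without
replacement, fresh randomness per batch — are redrawn uniformly on
[minⱼ, maxⱼ], the per-gene extrema of the *pre-training split only*. The
InfoNCE loss uses cosine similarities between the projections of the clean
and corrupted batches; the softmax denominator runs over the corrupted
projections of the full batch, including the matched one. Implementing the
corruption as a fixed count rather than per-feature Bernoulli makes the
altered count exactly testable and matches the "select a fraction" reading.
Default c = 0.30: with thousands of features and heavy inter-gene
redundancy, perturbing a modest fraction diversifies views without
destroying the sample's identity.

**Denoising (VIME-style).** A Bernoulli(p_m) mask (default p_m = 0.30,
aligned with the contrastive fraction) selects features whose values are
swapped for draws from the same gene's empirical marginal — a value of that
gene in a random *pre-training* sample; fine-tuning and test data never
feed the corruption distribution. The encoder consumes the corrupted
sample; a feature decoder reconstructs the original values (mean squared
error over all entries, L_f) and a mask decoder predicts which positions
were swapped (binary cross-entropy summed over dimensions, averaged over
the batch, L_m). Total loss L = L_m + α·L_f with α = 2.0 by default (loss
weight exposed in config). Both decoders mirror the encoder's stack with a
linear output layer; the mask decoder emits logits, converted to
probabilities (clamped to (1e-7, 1−1e-7)) for the loss.

**Teacher–student (BYOL-style).** The online branch (encoder → projector →
predictor, parameters θ) consumes the *original* sample; the target branch
(encoder → projector, parameters ξ, initialized as a copy of θ) consumes
the mask-and-swap *corrupted* sample. The loss 2 − 2·cos(q_θ, z̃_ξ) — equal
to the squared distance between the L2-normalized vectors — is minimized
with respect to θ only; the target is behind a structural stop-gradient
(its forward pass simply never enters backpropagation). After every
optimizer step, ξ ← λξ + (1−λ)θ elementwise with λ = 0.99. The EMA rule is
applied to the running batch-norm statistics as well, and the target runs
in inference mode, so λ = 1 freezes the target exactly — a property the
tests exploit. The loss is one-sided by default; a `symmetrize` flag adds
the swapped-view term for experimentation. Projector and predictor are
`linear → batchnorm → ReLU → linear` with a wide hidden layer (4096 at full
scale; narrower in the packaged study).

**Optimization.** Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3, batch
128, 100 pre-training epochs at full scale — values exposed in the configs
and recorded in run manifests, since the protocol leaves them open.
Temperature τ defaults to 1.0. Validation loss, when a validation matrix
is supplied, is evaluated each epoch with corruption drawn from a fixed
derived seed so the curve is comparable across epochs.

All layers, losses and gradients are implemented directly in numpy
(`exprssl.nn`): the forward pass is functional (explicit caches), which
lets one network run on several inputs per step and be back-propagated per
pass — needed for the two contrastive views and for freeze/stop-gradient
guarantees that are awkward to assert through a framework. Gradients of
the three losses were verified against central finite differences during
development; the suite asserts the loss values against independent oracles.

## Fine-tuning protocol

A single linear head (embedding_dim → n_classes) is attached to the
encoder. Cross-entropy, Adam at 1e-3, batch 8, at most 100 epochs with
early stopping on the fine-tuning validation loss: an epoch improves only
if it beats the best loss by more than 1e-5; after 30 epochs without
improvement training stops and the best-epoch weights are restored. The
validation carve-out is *not* re-subsampled with p — at every labeled
proportion the full fine-tuning validation set monitors early stopping,
which keeps stopping stable at tiny p. In frozen mode the optimizer is
constructed over the head's parameters only, so no optimizer state ever
exists for the encoder. Per repeat, both the labeled subsample and the
head initialization are reseeded (one derived seed drives both).

## Benchmark metrics

* **Accuracy curve** — mean ± sd test accuracy over `n_repeats` (default 5)
  fine-tuning runs at each labeled proportion p; the full grid is 0.02 to
  1.0 in steps of 0.01 (99 points), configurable down for quick runs.
* **AUPC gain** — repeats are averaged per p first; the trapezoidal
  integral of the mean curve over p ∈ [0.02, 0.3] is the AUPC, and
  g(m₁, m₂) is the difference of the two AUPCs (antisymmetric; positive
  when m₁ dominates on average). Curves on mismatched grids are linearly
  interpolated onto the union of their grid points inside the range.
* **Data savings** — 1 − p*, where p* is the smallest grid proportion at
  which the pre-trained mean curve reaches the baseline mean curve's
  maximum over its full grid; `reached=False` (savings 0) if it never does.
* **Pre-training-size sweep** — accuracy at fixed p = 0.1 as a function of
  the stratified fraction q of the pre-training split used for pre-training
  (default grid 0.01–0.05 step 0.01 plus 0.05–1 step 0.05, 24 points, with
  a q = 0 baseline row).

## Dimensional-collapse diagnostic

Embeddings are collected on a validation set; the population covariance
C = (1/N) Σ (zᵢ − z̄)(zᵢ − z̄)ᵀ (1/N normalization, matching the definition
used, not the 1/(N−1) sample form) is decomposed by SVD. A singular value
counts as collapsed when σₖ < 1e-6·σ₁ — a *relative* threshold, since an
absolute "zero" would depend on data scale; an all-zero covariance is full
collapse. For plotting, log10(σₖ + 1e-12) keeps exact zeros finite. The
spectrum of C provably equals the squared singular values of the centered
embedding matrix divided by N; the suite cross-checks the two routes.

## Synthetic data generator

The generator emulates the statistics that make this protocol interesting:
high dimension / low sample size, exact class imbalance, and blocks of
redundant genes.

* **Class counts** follow largest-remainder apportionment of the priors —
  every count is within 1 of its exact quota, deterministically. The same
  rounding rule drives stratified splits and labeled subsampling, so split
  sizes are reproducible integers rather than distributional.
* **Informative genes** (default: half the genes) are tiled into redundancy
  blocks of 5. Each (class, block) pair gets a latent mean of
  ±class_effect_size; per sample, the block latent is drawn with variance
  ρ·σ² and each gene adds independent noise with variance (1−ρ)·σ², so the
  expected within-block, within-class correlation is exactly
  ρ = s²/(s²+σ_ε²) (closed-form calibration; defaults ρ = 0.8, σ = 1,
  effect 1.0). Redundancy is what lets corruption-based pretext tasks
  recover masked information from sibling genes.
* **Remaining genes** are pure Gaussian noise; a constant baseline level
  (6.0, a typical log₂ expression magnitude) shifts all values.
* **Batch shift** for transfer scenarios is gene-wise affine,
  x → x·exp(δ_g) + β_g with δ_g, β_g drawn once per gene from centered
  normals; zero standard deviations give the identity. This produces the
  "different dataset" failure mode by the simplest mechanism.

What the generator does **not** model: RNA-Seq count distributions
(negative binomial noise, library-size effects), gene–gene correlation
beyond block structure, label noise, and realistic class-conditional
covariance differences. Passing tests on this data therefore demonstrate
protocol and implementation correctness and the *direction* of pre-training
benefits under redundancy — not absolute accuracies transferable to real
compendia.

## The packaged study (`exprssl.study`)

The reference scenario fixes 6500 samples × 500 genes, 10 balanced classes,
split 5000 / 1000 / 500 (pre-train / fine-tune / test) with 15% validation
carve-outs — a deliberate scale-down of the real protocol's geometry that
keeps the full study in the minutes range on one CPU. The study encoder is
2 × 64 (depth × width) with batch normalization; pre-training runs 15
epochs at batch 128; projection heads are narrowed proportionally (64-dim
projections, 256-dim hidden for the teacher–student heads). Accuracy
curves use 5 points spanning [0.02, 0.3] with 3 repeats; the low-label
comparison at p = 0.05 uses 5 repeats. At this scale the synthetic task is
learnable but imperfect at small p, which is exactly the regime where the
pre-training benefit expresses itself.

## Numerical choices and degenerate inputs

* Cosine similarities raise on zero-norm vectors (degenerate projections)
  rather than silently regularizing; the InfoNCE softmax is computed with
  the max-subtraction trick.
* Corruption of a zero-width feature (min = max) redraws to its only
  possible value, i.e. leaves it unchanged.
* Batch normalization with a single-sample batch falls back to running
  statistics; frozen encoders always run in inference mode.
* Ties in argmax prediction resolve to the lowest class index.
* A labeled subsample that loses a class entirely warns and proceeds
  (recorded in manifests); a structural split that cannot represent a class
  in the test or fine-tuning part raises, naming the class.
* Preprocessing for real-valued non-negative matrices is log2(x+1) then
  per-gene z-scoring with statistics from the pre-training split only;
  genes with sd below 1e-8 map to 0. The packaged study's generator
  already emits log-scale values, so the study standardizes without the log
  step.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; stage seeds are derived from the master seed via
  `SeedSequence`, and run manifests record them.

## Known limitations

* The numpy training core is single-threaded BLAS-bound; it is sized for
  the packaged study and CI-scale experiments, not for 50 000-gene
  matrices at hundreds of epochs.
* Class count of the downstream task is a free parameter of the generator;
  nothing in the package fixes the real datasets' label taxonomies.
* The architecture sweep exposes depth × width grids but the packaged
  study does not sweep by default; sweep results at desk scale are
  qualitative.
* Frozen-mode performance on synthetic data is low (a random frozen
  encoder is a fixed random projection); the frozen path is exercised for
  protocol correctness rather than accuracy claims.
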