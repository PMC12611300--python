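"""Synthetic bulk-expression data with the structure the pipeline assumes.

Real pan-cancer / pan-tissue compendia are large, labelled, highly redundant
(blocks of co-expressed genes) and class-imbalanced.  This module generates
matrices with those properties at arbitrary scale so every downstream stage —
corruption, pre-training, fine-tuning, benchmarking — can be exercised and
tested without any download:

* class sizes follow largest-remainder apportionment of the class priors, so
  the generated imbalance is exact and deterministic;
* informative genes are organised into redundancy blocks: each block shares a
  class-shifted latent signal plus independent per-gene noise, with the noise
  split calibrated in closed form so the expected within-block (within-class)
  correlation equals ``redundancy_rho`` (rho = s² / (s² + sigma²));
* remaining genes are pure noise;
* an optional gene-wise affine batch shift emulates cross-dataset transfer.

All randomness flows through a single integer seed per object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetSpec",
    "ExpressionMatrix",
    "BatchShiftSpec",
    "SplitResult",
    "largest_remainder",
    "generate_dataset",
    "apply_batch_shift",
    "split_dataset",
    "subsample_labeled",
]


@dataclass
class ExpressionMatrix:
    """Samples × genes real-valued matrix with row/column identifiers."""

    values: np.ndarray
    sample_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples × genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample IDs / {len(self.gene_ids)} gene IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DatasetSpec:
    """Recipe for one synthetic labelled expression dataset."""

    n_samples: int = 6500
    n_genes: int = 500
    n_classes: int = 10
    class_priors: np.ndarray | None = None  # None -> uniform
    n_informative_genes: int | None = None  # None -> half the genes
    redundancy_block_size: int = 5
    redundancy_rho: float = 0.8
    class_effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_expression: float = 6.0  # mean log2-scale expression level
    seed: int = 0

    def __post_init__(self):
        if self.class_priors is None:
            self.class_priors = np.full(self.n_classes, 1.0 / self.n_classes)
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if self.class_priors.shape != (self.n_classes,):
            raise ValueError("class_priors length must equal n_classes")
        if abs(self.class_priors.sum() - 1.0) > 1e-9:
            raise ValueError("class_priors must sum to 1 (within 1e-9)")
        if np.any(self.class_priors < 0):
            raise ValueError("class_priors must be non-negative")
        if self.n_informative_genes is None:
            self.n_informative_genes = self.n_genes // 2
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        if self.redundancy_block_size < 1:
            raise ValueError("redundancy_block_size must be >= 1")
        if not 0.0 <= self.redundancy_rho < 1.0:
            raise ValueError("redundancy_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class BatchShiftSpec:
    """Gene-wise affine shift x -> x * exp(delta_g) + beta_g emulating a
    second dataset (batch) with different per-gene location and scale."""

    location_shift_sd: float = 0.5
    scale_factor_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.location_shift_sd < 0 or self.scale_factor_sd < 0:
            raise ValueError("shift standard deviations must be >= 0")


@dataclass
class SplitResult:
    """Disjoint stratified index sets for the pre-train / fine-tune / test
    protocol, with validation carve-outs for the two training parts."""

    pretrain_idx: np.ndarray
    finetune_idx: np.ndarray
    test_idx: np.ndarray
    pretrain_val_idx: np.ndarray
    finetune_val_idx: np.ndarray

    def all_parts(self) -> dict:
        return {
            "pretrain": self.pretrain_idx,
            "finetune": self.finetune_idx,
            "test": self.test_idx,
            "pretrain_val": self.pretrain_val_idx,
            "finetune_val": self.finetune_val_idx,
        }


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Each entry gets the floor of its exact quota; leftover units go to the
    largest fractional remainders (ties broken by lower index).  This is the
    rounding rule used everywhere counts are derived from proportions, so the
    per-entry deviation from the exact quota is always < 1.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    leftover = total - int(base.sum())
    if leftover > 0:
        # stable argsort => ties resolved toward lower index
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:leftover]] += 1
    return base


def generate_dataset(spec: DatasetSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate (expression matrix, label vector) from a :class:`DatasetSpec`.

    Gene layout: the first ``n_informative_genes`` columns are informative and
    tiled into redundancy blocks of ``redundancy_block_size`` (the last block
    may be smaller); the rest are pure noise.  Each (class, block) pair has a
    latent mean of ±class_effect_size; per sample the block latent is drawn
    around that mean with variance rho·noise_sd² and each gene in the block
    adds independent noise with variance (1−rho)·noise_sd², giving expected
    within-block within-class correlation rho.
    """
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder(spec.class_priors, spec.n_samples)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)

    n, d = spec.n_samples, spec.n_genes
    X = np.empty((n, d))
    noise_start = spec.n_informative_genes
    X[:, noise_start:] = rng.normal(0.0, spec.noise_sd, size=(n, d - noise_start))

    block = spec.redundancy_block_size
    rho = spec.redundancy_rho
    s_lat = np.sqrt(rho) * spec.noise_sd
    s_eps = np.sqrt(1.0 - rho) * spec.noise_sd
    starts = range(0, spec.n_informative_genes, block)
    n_blocks = len(list(starts))
    # class-specific latent means: ±effect per (class, block)
    block_means = spec.class_effect_size * rng.choice(
        [-1.0, 1.0], size=(spec.n_classes, n_blocks))
    for b, start in enumerate(range(0, spec.n_informative_genes, block)):
        width = min(block, spec.n_informative_genes - start)
        latent = block_means[labels, b] + rng.normal(0.0, s_lat, size=n)
        X[:, start:start + width] = (
            latent[:, None] + rng.normal(0.0, s_eps, size=(n, width)))

    X += spec.baseline_expression
    sample_ids = [f"S{i:06d}" for i in range(n)]
    gene_ids = [f"G{j:06d}" for j in range(d)]
    return ExpressionMatrix(X, sample_ids, gene_ids), labels


def apply_batch_shift(X: ExpressionMatrix, shift: BatchShiftSpec) -> ExpressionMatrix:
    """Apply the gene-wise affine batch shift; zero sds give the identity."""
    if X.values.size == 0:
        raise ValueError("cannot shift an empty expression matrix")
    rng = np.random.default_rng(shift.seed)
    log_scale = rng.normal(0.0, shift.scale_factor_sd, size=X.n_genes) \
        if shift.scale_factor_sd > 0 else np.zeros(X.n_genes)
    offset = rng.normal(0.0, shift.location_shift_sd, size=X.n_genes) \
        if shift.location_shift_sd > 0 else np.zeros(X.n_genes)
    values = X.values * np.exp(log_scale) + offset
    return ExpressionMatrix(values, list(X.sample_ids), list(X.gene_ids))


def _stratified_take(by_class: dict, class_weights: np.ndarray, total: int,
                     part_name: str, require_all: bool = False) -> np.ndarray:
    """Remove a stratified subset of ``total`` indices from ``by_class``."""
    take = largest_remainder(class_weights, total)
    chosen = []
    for c, k in enumerate(take):
        pool = by_class[c]
        if k > len(pool):
            raise ValueError(
                f"class {c} has only {len(pool)} samples left but the "
                f"{part_name} part requires {k}; reduce part sizes or "
                f"rebalance priors")
        if require_all and k == 0 and class_weights[c] > 0 \
                and total >= len(by_class):
            raise ValueError(
                f"class {c} has too few samples to appear in the "
                f"{part_name} part; it cannot be represented in every split")
        chosen.append(pool[:k])
        by_class[c] = pool[k:]
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def split_dataset(y: np.ndarray, finetune_size: int, test_size: int,
                  val_fraction: float = 0.15, seed: int = 0) -> SplitResult:
    """Stratified pre-train / fine-tune / test split with validation carve-outs.

    Test and fine-tune parts get ``test_size`` / ``finetune_size`` samples
    apportioned across classes by largest remainder of the source class
    proportions; every remaining sample goes to the pre-training part.  A
    ``val_fraction`` (default 15%) of the pre-training and fine-tuning parts
    is then carved into validation lists, again stratified.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if finetune_size + test_size >= n:
        raise ValueError("finetune_size + test_size must be < n_samples")
    if not 0.0 <= val_fraction <= 0.5:
        raise ValueError("val_fraction must be in [0, 0.5]")
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    weights = np.empty(classes.shape[0])
    for i, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        by_class[i] = idx
        weights[i] = idx.shape[0]

    test_idx = _stratified_take(by_class, weights, test_size, "test",
                                require_all=True)
    finetune_idx = _stratified_take(by_class, weights, finetune_size,
                                    "fine-tuning", require_all=True)
    pretrain_idx = np.sort(np.concatenate([by_class[i] for i in range(len(classes))]))

    def carve_val(part: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if val_fraction == 0 or part.size == 0:
            return part, np.array([], dtype=int)
        part_by_class = {i: part[y[part] == c] for i, c in enumerate(classes)}
        w = np.array([part_by_class[i].shape[0] for i in range(len(classes))], float)
        n_val = int(round(val_fraction * part.size))
        val = _stratified_take(part_by_class, w, n_val, "validation")
        keep = np.sort(np.concatenate([part_by_class[i] for i in range(len(classes))]))
        return keep, val

    pretrain_idx, pretrain_val_idx = carve_val(pretrain_idx)
    finetune_idx, finetune_val_idx = carve_val(finetune_idx)
    return SplitResult(pretrain_idx, finetune_idx, test_idx,
                       pretrain_val_idx, finetune_val_idx)


def subsample_labeled(finetune_idx: np.ndarray, y: np.ndarray, p: float,
                      seed: int = 0) -> np.ndarray:
    """Stratified subset of round(p·|finetune_idx|) labeled indices.

    Per-class counts follow largest-remainder apportionment, so every class
    whose exact quota reaches half a sample is normally retained.  If a class
    is lost entirely a warning is emitted (downstream training proceeds).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("labeled proportion p must be in (0, 1]")
    finetune_idx = np.asarray(finetune_idx)
    if p == 1.0:
        return finetune_idx.copy()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    yf = y[finetune_idx]
    classes = np.unique(yf)
    weights = np.array([(yf == c).sum() for c in classes], dtype=float)
    total = int(round(p * finetune_idx.shape[0]))
    take = largest_remainder(weights, total)
    lost = [int(classes[i]) for i in range(len(classes))
            if take[i] == 0 and weights[i] > 0]
    if lost:
        warnings.warn(
            f"labeled subsample at p={p} lost classes {lost}", UserWarning)
    chosen = []
    for i, c in enumerate(classes):
        pool = finetune_idx[yf == c]
        pick = rng.choice(pool.shape[0], size=take[i], replace=False)
        chosen.append(pool[pick])
    return np.sort(np.concatenate(chosen))
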