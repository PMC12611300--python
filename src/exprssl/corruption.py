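"""Corruption operators defining the pretext tasks.

Two families of input perturbation are used to manufacture training views
without labels:

* **uniform-support resampling** — a fixed fraction ``c`` of each sample's
  features is selected at random and each selected value is replaced by a
  uniform draw between that gene's minimum and maximum over the pre-training
  split (the SCARF view);
* **mask-and-marginal-swap** — a Bernoulli(``p_m``) mask picks features whose
  values are swapped for values of the same gene in other reference samples,
  i.e. draws from the gene's empirical marginal (the VIME view, reused by the
  BYOL adaptation).

Both operators are pure functions of an explicit numpy Generator, so every
corrupted batch is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureBounds",
    "CorruptionConfig",
    "compute_bounds",
    "scarf_corrupt",
    "scarf_corrupt_batch",
    "sample_mask",
    "vime_corrupt",
    "vime_corrupt_batch",
]

#: default fraction of features perturbed per sample; a modest fraction is
#: enough because expression data carries heavy inter-gene redundancy.
DEFAULT_CORRUPTION_FRACTION = 0.30
DEFAULT_MASK_RATE = 0.30


@dataclass
class FeatureBounds:
    """Per-gene min/max over a reference (pre-training) matrix."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.minimum > self.maximum):
            raise ValueError("feature minimum exceeds maximum")

    def __len__(self) -> int:
        return self.minimum.shape[0]


@dataclass
class CorruptionConfig:
    """Parameters of the corruption operators.

    ``fraction`` is the fraction of features resampled per sample
    (uniform-support style); ``mask_rate`` is the per-feature Bernoulli rate
    of the mask-and-swap style.
    """

    style: str = "uniform_resample"  # or "marginal_swap"
    fraction: float = DEFAULT_CORRUPTION_FRACTION
    mask_rate: float = DEFAULT_MASK_RATE
    seed: int = 0

    def __post_init__(self):
        if self.style not in ("uniform_resample", "marginal_swap"):
            raise ValueError(f"unknown corruption style {self.style!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")


def compute_bounds(X_train: np.ndarray) -> FeatureBounds:
    """Columnwise extrema of the training matrix.

    Bounds must come from the pre-training split only; computing them on
    fine-tuning or test data would leak information across the protocol.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ValueError("cannot compute bounds of an empty matrix")
    return FeatureBounds(X_train.min(axis=0), X_train.max(axis=0))


def scarf_corrupt_batch(X: np.ndarray, bounds: FeatureBounds, c: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniform-support resampling of exactly ``round(c*d)`` features per row.

    Feature positions are chosen uniformly without replacement, independently
    per row; each chosen value is redrawn uniformly on [min_j, max_j].  A
    zero-width feature (min == max) is redrawn to its only possible value,
    i.e. left unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if len(bounds) != d:
        raise ValueError(f"bounds length {len(bounds)} != feature count {d}")
    if not 0.0 <= c <= 1.0:
        raise ValueError("corruption fraction must be in [0, 1]")
    k = int(round(c * d))
    out = X.copy()
    if k == 0:
        return out
    # per-row sample of k distinct columns: order statistics of iid uniforms
    cols = np.argpartition(rng.random((n, d)), k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = cols.ravel()
    lo = bounds.minimum[cols]
    hi = bounds.maximum[cols]
    out[rows, cols] = lo + rng.random(rows.shape[0]) * (hi - lo)
    return out


def scarf_corrupt(x: np.ndarray, bounds: FeatureBounds, c: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Corrupt one sample vector; see :func:`scarf_corrupt_batch`."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("scarf_corrupt expects a 1-D sample vector")
    return scarf_corrupt_batch(x[None, :], bounds, c, rng)[0]


def sample_mask(d: int, p_m: float, rng: np.random.Generator,
                n: int | None = None) -> np.ndarray:
    """Binary mask with independent Bernoulli(p_m) entries (optionally n × d)."""
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("mask rate must be in [0, 1]")
    shape = (d,) if n is None else (n, d)
    return (rng.random(shape) < p_m).astype(np.int8)


def vime_corrupt_batch(X: np.ndarray, X_ref: np.ndarray, M: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Mask-and-marginal-swap: x̃ = m ⊙ x̄ + (1 − m) ⊙ x.

    Masked positions take a value drawn uniformly from the same column of the
    reference matrix (the empirical marginal of that gene); unmasked positions
    pass through.  The reference must be the pre-training split to avoid
    leakage.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_ref = np.asarray(X_ref, dtype=float)
    if X_ref.size == 0:
        raise ValueError("empty reference matrix")
    M = np.atleast_2d(np.asarray(M))
    if M.shape != X.shape:
        raise ValueError(f"mask shape {M.shape} != data shape {X.shape}")
    if X_ref.shape[1] != X.shape[1]:
        raise ValueError("reference matrix feature count mismatch")
    ref_rows = rng.integers(0, X_ref.shape[0], size=X.shape)
    xbar = X_ref[ref_rows, np.arange(X.shape[1])[None, :]]
    return np.where(M == 1, xbar, X)


def vime_corrupt(x: np.ndarray, X_ref: np.ndarray, m: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Corrupt one sample vector; see :func:`vime_corrupt_batch`."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("vime_corrupt expects a 1-D sample vector")
    return vime_corrupt_batch(x[None, :], X_ref, np.asarray(m)[None, :], rng)[0]
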