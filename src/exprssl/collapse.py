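"""Dimensional-collapse diagnostics for learned representations.

A representation collapses dimensionally when the embedding variance
concentrates in a low-dimensional subspace.  The diagnostic: collect the
embedding vectors on a validation set, form the population covariance
C = (1/N) Σ (z_i − z̄)(z_i − z̄)ᵀ, take its singular value decomposition, and
count singular values that are effectively zero relative to the largest one.
A large collapsed fraction means the encoder under-uses its latent space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumResult",
    "embedding_covariance",
    "singular_spectrum",
    "diagnose_encoder",
]

#: singular values below this multiple of the largest count as collapsed
DEFAULT_RELATIVE_TOLERANCE = 1e-6
_LOG_EPS = 1e-12


@dataclass
class SpectrumResult:
    """Sorted singular values of the embedding covariance plus collapse stats."""

    singular_values: np.ndarray
    collapse_fraction: float
    tolerance: float
    d: int
    n_samples: int

    def __post_init__(self):
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be sorted descending")
        if np.any(self.singular_values < -1e-12):
            raise ValueError("singular values must be non-negative")
        if not 0.0 <= self.collapse_fraction <= 1.0:
            raise ValueError("collapse_fraction outside [0, 1]")

    @property
    def n_collapsed(self) -> int:
        return int(round(self.collapse_fraction * self.d))

    def log10_values(self) -> np.ndarray:
        """log10(σ_k + ε) for the standard sorted log-scale presentation."""
        return np.log10(self.singular_values + _LOG_EPS)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tsigma\tlog10_sigma\n")
            for k, (s, ls) in enumerate(zip(self.singular_values,
                                            self.log10_values()), start=1):
                fh.write(f"{k}\t{s!r}\t{ls!r}\n")


def embedding_covariance(Z: np.ndarray) -> np.ndarray:
    """Population covariance (1/N normalization) of N × d embeddings."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0:
        raise ValueError("empty embedding matrix")
    Zc = Z - Z.mean(axis=0)
    return (Zc.T @ Zc) / Z.shape[0]


def singular_spectrum(C: np.ndarray,
                      tolerance: float = DEFAULT_RELATIVE_TOLERANCE,
                      n_samples: int = 0) -> SpectrumResult:
    """SVD of a covariance matrix with a relative collapse count.

    A singular value counts as collapsed when σ_k < tolerance · σ_1.  An
    all-zero covariance is full collapse (fraction 1).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if np.max(np.abs(C - C.T), initial=0.0) > 1e-8:
        raise ValueError("covariance matrix is not symmetric (beyond 1e-8)")
    sigma = np.linalg.svd(C, compute_uv=False)
    d = C.shape[0]
    if sigma[0] <= 0.0:
        fraction = 1.0
    else:
        fraction = float(np.sum(sigma < tolerance * sigma[0])) / d
    return SpectrumResult(sigma, fraction, tolerance, d, n_samples)


def diagnose_encoder(encoder, X_val: np.ndarray,
                     tolerance: float = DEFAULT_RELATIVE_TOLERANCE,
                     tsv_path=None) -> SpectrumResult:
    """Embedding-spectrum diagnostic of an encoder on validation data."""
    X_val = np.asarray(getattr(X_val, "values", X_val), dtype=float)
    Z = encoder(X_val)
    if Z.shape[1] != encoder.config.embedding_dim:
        raise ValueError("embedding width does not match the encoder config")
    result = singular_spectrum(embedding_covariance(Z), tolerance,
                               n_samples=Z.shape[0])
    if tsv_path is not None:
        result.to_tsv(tsv_path)
    return result
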