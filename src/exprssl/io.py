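"""Dataset I/O, preprocessing, feature intersection and run manifests.

File dialect: expression matrices are TSV with the sample ID in the first
column and gene IDs as the header row (samples × genes); labels are
two-column TSV (sample ID, integer class label).  Round-trips are lossless
to full float precision (values are written with ``repr``).

Preprocessing is log2(x + 1) followed by per-gene standardization whose
mean/sd statistics come from the pre-training split only — fine-tuning and
test samples never influence the statistics.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, is_dataclass

import numpy as np
import pandas as pd

from .synthetic import ExpressionMatrix

__all__ = [
    "write_expression",
    "load_expression",
    "write_labels",
    "load_labels",
    "intersect_features",
    "preprocess",
    "PreprocessStats",
    "RunManifest",
]


def write_expression(X: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample_id",
              float_format=lambda v: repr(float(v)))


def load_expression(path, labels_path=None):
    """Read a matrix (and optionally labels) written in this package's dialect.

    Returns ``(ExpressionMatrix, labels-or-None)``.  Duplicate IDs, ragged
    rows and non-numeric cells raise with the offending ID named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_genes = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup_genes):
        raise ValueError(f"duplicate gene ID {dup_genes[0]!r} in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g) for g in df.columns]
    sample_ids = [str(s) for s in df.index]
    dup_samples = df.index[df.index.duplicated()]
    if len(dup_samples):
        raise ValueError(f"duplicate sample ID {dup_samples[0]!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric cell at sample {df.index[bad.argmax()]!r}, "
                    f"gene {col!r} in {path}") from exc
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at sample {sample_ids[i]!r}, "
                         f"gene {gene_ids[j]!r} in {path}")
    X = ExpressionMatrix(values, sample_ids, gene_ids)
    labels = None
    if labels_path is not None:
        labels = load_labels(labels_path, sample_ids)
    return X, labels


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": np.asarray(labels)}) \
        .to_csv(path, sep="\t", index=False)


def load_labels(path, sample_ids=None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["sample_id", "label"]:
        raise ValueError(f"label file {path} must have columns "
                         f"(sample_id, label)")
    df = df.set_index("sample_id")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"label file missing sample {missing[0]!r}")
        df = df.loc[list(sample_ids)]
    return df["label"].to_numpy(dtype=int)


def intersect_features(A: ExpressionMatrix,
                       B: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in sorted gene order.

    Needed for the transfer scenario, where the pre-training and fine-tuning
    datasets carry different gene annotations.
    """
    common = sorted(set(A.gene_ids) & set(B.gene_ids))
    if not common:
        raise ValueError("the two matrices share no gene IDs")

    def restrict(X: ExpressionMatrix) -> ExpressionMatrix:
        pos = {g: j for j, g in enumerate(X.gene_ids)}
        cols = [pos[g] for g in common]
        return ExpressionMatrix(X.values[:, cols], list(X.sample_ids),
                                list(common))

    return restrict(A), restrict(B)


@dataclass
class PreprocessStats:
    """Per-gene mean/sd of log2(x+1) values on the statistics source."""

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float = 1e-8


def fit_preprocess(stats_source: ExpressionMatrix) -> PreprocessStats:
    V = np.asarray(getattr(stats_source, "values", stats_source), float)
    if np.any(V < 0):
        raise ValueError("expression values must be non-negative before the "
                         "log transform")
    L = np.log2(V + 1.0)
    return PreprocessStats(L.mean(axis=0), L.std(axis=0))


def preprocess(X: ExpressionMatrix, stats_source: ExpressionMatrix,
               stats: PreprocessStats | None = None) -> ExpressionMatrix:
    """log2(x+1) then per-gene z-score with statistics from ``stats_source``
    (the pre-training split).  Genes with sd below the floor map to 0."""
    V = np.asarray(getattr(X, "values", X), dtype=float)
    if np.any(V < 0):
        raise ValueError("expression values must be non-negative before the "
                         "log transform")
    stats = stats or fit_preprocess(stats_source)
    L = np.log2(V + 1.0)
    sd = np.where(stats.sd < stats.sd_floor, 1.0, stats.sd)
    Z = (L - stats.mean) / sd
    Z[:, stats.sd < stats.sd_floor] = 0.0
    if isinstance(X, ExpressionMatrix):
        return ExpressionMatrix(Z, list(X.sample_ids), list(X.gene_ids))
    return ExpressionMatrix(Z, [f"S{i:06d}" for i in range(Z.shape[0])],
                            [f"G{j:06d}" for j in range(Z.shape[1])])


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Auditable record of one pipeline run: config snapshot, derived seeds,
    artifact checksums, warnings, and timestamps.  The manifest holds every
    default actually used, so hyper-parameters left open by the protocol are
    always visible."""

    command: str
    config: dict = field(default_factory=dict)
    master_seed: int = 0
    derived_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    software_version: str = ""
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record_artifact(self, name: str, path) -> None:
        self.artifacts[name] = {"path": str(path),
                                "sha256": file_checksum(path)}

    def close(self) -> None:
        self.finished = time.time()

    def write(self, path) -> None:
        if self.finished is None:
            self.close()
        with open(path, "w") as fh:
            json.dump(_jsonable(asdict(self)), fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
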