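"""The packaged benchmark study at desk scale.

This module fixes one reference scenario — a synthetic expression dataset of
6500 samples × 500 genes with 10 classes, split 5000 / 1000 / 500 into
pre-training, fine-tuning and test parts (15% validation carve-outs) — and
wires the full pipeline over it: per-gene standardization on pre-training
statistics, self-supervised pre-training, and label-efficiency evaluation.

Problem sizes and epoch counts are chosen so the complete study runs in
minutes on one CPU while preserving the protocol's structure: informative
genes arranged in correlated blocks (the redundancy the corruption operators
rely on), a compact encoder, and a small repeat count per proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import BenchmarkData, run_curve
from .finetune import FineTuneConfig
from .nn import EncoderConfig, Sequential
from .pretraining import ByolConfig, PretrainResult, ScarfConfig, VimeConfig
from .benchmark import make_pretrainer
from .synthetic import DatasetSpec, SplitResult, generate_dataset, split_dataset

__all__ = [
    "StudyData",
    "study_spec",
    "prepare_study",
    "pretrain_study_encoder",
    "study_pretrain_config",
    "study_accuracy_curve",
]

#: scaled-down study conditions (samples × genes, classes, redundancy)
STUDY_N_SAMPLES = 6500
STUDY_N_GENES = 500
STUDY_N_CLASSES = 10
STUDY_FINETUNE_SIZE = 1000
STUDY_TEST_SIZE = 500
STUDY_VAL_FRACTION = 0.15

#: compact encoder used throughout the study
STUDY_ENCODER = dict(n_layers=2, hidden_dim=64, embedding_dim=64)

#: pre-training epochs at study scale
STUDY_PRETRAIN_EPOCHS = 15


def study_spec(seed: int) -> DatasetSpec:
    """The synthetic dataset recipe of the reference study."""
    return DatasetSpec(
        n_samples=STUDY_N_SAMPLES,
        n_genes=STUDY_N_GENES,
        n_classes=STUDY_N_CLASSES,
        n_informative_genes=STUDY_N_GENES // 2,
        redundancy_block_size=5,
        redundancy_rho=0.8,
        class_effect_size=1.0,
        noise_sd=1.0,
        seed=seed,
    )


@dataclass
class StudyData:
    """Standardized matrices of the reference scenario, ready to train on."""

    spec: DatasetSpec
    split: SplitResult
    X_pretrain: np.ndarray
    X_pretrain_val: np.ndarray
    y: np.ndarray
    bench: BenchmarkData
    encoder_config: EncoderConfig


def prepare_study(seed: int) -> StudyData:
    """Generate, split and standardize the reference dataset.

    Standardization is per gene with mean/sd computed on the pre-training
    part only (the generator already emits log-scale values, so no log
    transform is applied here).
    """
    spec = study_spec(seed)
    X, y = generate_dataset(spec)
    split = split_dataset(y, STUDY_FINETUNE_SIZE, STUDY_TEST_SIZE,
                          STUDY_VAL_FRACTION, seed=seed)
    V = X.values
    mu = V[split.pretrain_idx].mean(axis=0)
    sd = V[split.pretrain_idx].std(axis=0)
    sd[sd < 1e-8] = 1.0
    Z = (V - mu) / sd
    bench = BenchmarkData(
        Z[split.finetune_idx], y[split.finetune_idx],
        Z[split.finetune_val_idx], y[split.finetune_val_idx],
        Z[split.test_idx], y[split.test_idx],
        n_classes=spec.n_classes)
    enc_cfg = EncoderConfig(input_dim=spec.n_genes, seed=seed,
                            **STUDY_ENCODER)
    return StudyData(spec, split, Z[split.pretrain_idx],
                     Z[split.pretrain_val_idx], y, bench, enc_cfg)


def study_pretrain_config(method: str, seed: int,
                          epochs: int = STUDY_PRETRAIN_EPOCHS):
    """Pre-training hyper-parameters at study scale (projection heads sized
    to the compact encoder)."""
    if method == "scarf":
        return ScarfConfig(epochs=epochs, batch_size=128, projection_dim=64,
                           seed=seed)
    if method == "vime":
        return VimeConfig(epochs=epochs, batch_size=128, seed=seed)
    if method == "byol":
        return ByolConfig(epochs=epochs, batch_size=128, projection_dim=64,
                          projection_hidden_dim=256, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def pretrain_study_encoder(study: StudyData, method: str, seed: int,
                           epochs: int = STUDY_PRETRAIN_EPOCHS,
                           with_val: bool = False) -> PretrainResult:
    cfg = study_pretrain_config(method, seed, epochs)
    model = make_pretrainer(method, study.X_pretrain, study.encoder_config,
                            cfg,
                            X_val=study.X_pretrain_val if with_val else None)
    return model.fit()


def study_accuracy_curve(study: StudyData, method: str,
                         encoder: Sequential | None = None,
                         grid: np.ndarray | None = None,
                         n_repeats: int = 5, base_seed: int = 0,
                         mode: str = "unfrozen"):
    """Accuracy curve under the study's fine-tuning protocol."""
    if grid is None:
        grid = np.array([0.02, 0.09, 0.16, 0.23, 0.30])
    return run_curve(method, study.bench, encoder=encoder,
                     encoder_config=study.encoder_config, mode=mode,
                     grid=grid, n_repeats=n_repeats, base_seed=base_seed,
                     finetune_config=FineTuneConfig())
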