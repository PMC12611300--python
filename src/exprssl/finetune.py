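"""Supervised fine-tuning of a (pre-trained or random) encoder.

A single linear classification head is attached to the encoder and trained
with cross-entropy under the label-efficiency protocol: small batches, early
stopping on the fine-tuning validation loss (patience 30, max 100 epochs),
best-epoch weight restoration, and a final test-accuracy evaluation.

Two modes:

* ``unfrozen`` — encoder and head both train;
* ``frozen`` — only the head trains; the encoder's parameters *and* its
  batch-norm statistics stay bit-identical (the encoder always runs in
  inference mode), and no optimizer state is ever created for it.

The baseline model of the benchmark is the same protocol started from a
freshly initialized encoder, always unfrozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    EncoderConfig,
    HeadConfig,
    Sequential,
    build_encoder,
    build_head,
    copy_parameters,
    snapshot_parameters,
    restore_parameters,
)

__all__ = [
    "FineTuneConfig",
    "FineTuneResult",
    "EarlyStopper",
    "FineTune",
    "baseline_train",
    "evaluate_accuracy",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def evaluate_accuracy(predict_fn, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Fraction of argmax predictions matching the labels.

    ``predict_fn`` maps a samples × genes matrix to logits (or any score
    matrix); ties in the argmax resolve to the lowest class index.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if X_test.shape[0] == 0:
        raise ValueError("test set is empty")
    scores = np.asarray(predict_fn(X_test))
    pred = scores.argmax(axis=1)
    return float(np.mean(pred == y_test))


class EarlyStopper:
    """Patience-based stopping on a validation loss sequence.

    A new loss counts as an improvement when it is below the best loss by
    more than ``min_delta``; after ``patience`` consecutive epochs without
    improvement the run stops.  The epoch index (1-based) of the best loss is
    retained so the caller can restore best-epoch weights.
    """

    def __init__(self, patience: int = 30, min_delta: float = 1e-5):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = 0
        self._since_best = 0
        self.epochs_seen = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epochs_seen += 1
        if val_loss < self.best_loss - self.min_delta:
            self.best_loss = val_loss
            self.best_epoch = self.epochs_seen
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


@dataclass
class FineTuneConfig:
    mode: str = "unfrozen"          # or "frozen"
    p: float = 1.0                  # labeled proportion (metadata for reports)
    max_epochs: int = 100
    patience: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    improvement_threshold: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("frozen", "unfrozen"):
            raise ValueError(f"unknown fine-tuning mode {self.mode!r}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("labeled proportion p must be in (0, 1]")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class FineTuneResult:
    """Outcome of one fine-tuning run."""

    test_accuracy: float
    epochs_run: int
    best_epoch: int
    train_loss_history: list
    val_loss_history: list
    encoder_was_frozen: bool
    config: FineTuneConfig
    encoder: Sequential
    head: Sequential
    method: str = "finetune"

    def __post_init__(self):
        if not 0.0 <= self.test_accuracy <= 1.0:
            raise ValueError("test accuracy outside [0, 1]")
        if self.epochs_run > self.config.max_epochs:
            raise ValueError("epochs_run exceeds max_epochs")

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.head(self.encoder(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logits(X).argmax(axis=1)

    def summary(self) -> str:
        lines = [
            f"{'Fine-tuning results':^58}",
            "=" * 58,
            f"{'Mode:':<22}{self.config.mode}",
            f"{'Labeled proportion p:':<22}{self.config.p}",
            f"{'Test accuracy:':<22}{self.test_accuracy:.4f}",
            f"{'Epochs run:':<22}{self.epochs_run}",
            f"{'Best epoch:':<22}{self.best_epoch}",
            f"{'Best val loss:':<22}{min(self.val_loss_history):.6f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "mode": self.config.mode,
            "p": self.config.p,
            "seed": self.config.seed,
            "test_accuracy": self.test_accuracy,
            "epochs_run": self.epochs_run,
            "best_epoch": self.best_epoch,
        }


class FineTune:
    """Attach a linear classifier to an encoder and train it on labeled data.

    The provided encoder is never mutated: its parameters are copied into an
    internal network, and the result carries that fine-tuned copy.  In frozen
    mode the copy stays bit-identical to the input encoder.
    """

    def __init__(self, encoder: Sequential, n_classes: int,
                 X_train, y_train, X_val, y_val, X_test, y_test,
                 config: FineTuneConfig | None = None, method: str = "finetune"):
        self.source_encoder = encoder
        self.n_classes = int(n_classes)
        self.config = config or FineTuneConfig()
        self.method = method
        self.X_train = np.asarray(getattr(X_train, "values", X_train), float)
        self.y_train = np.asarray(y_train)
        self.X_val = np.asarray(getattr(X_val, "values", X_val), float)
        self.y_val = np.asarray(y_val)
        self.X_test = np.asarray(getattr(X_test, "values", X_test), float)
        self.y_test = np.asarray(y_test)
        if self.X_train.shape[0] == 0:
            raise ValueError("fine-tuning training set is empty; the labeled "
                             "proportion is too small for this split")
        present = np.unique(self.y_train)
        if present.shape[0] < self.n_classes:
            missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
            warnings.warn(
                f"fine-tuning subset has no samples for classes {missing}",
                UserWarning)

    def _cross_entropy(self, logits: np.ndarray, y: np.ndarray):
        probs = softmax(logits)
        n = y.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        return loss, grad / n

    def _val_loss(self, encoder, head) -> float:
        logits = head(encoder(self.X_val))
        return self._cross_entropy(logits, self.y_val)[0]

    def fit(self) -> FineTuneResult:
        cfg = self.config
        frozen = cfg.mode == "frozen"
        encoder = build_encoder(self.source_encoder.config)
        copy_parameters(self.source_encoder, encoder)
        head = build_head(HeadConfig(
            "classifier", in_dim=encoder.config.embedding_dim,
            out_dim=self.n_classes, seed=cfg.seed + 17))
        modules = [head] if frozen else [encoder, head]
        self.optimizer_ = Adam(modules, lr=cfg.learning_rate)
        rng = np.random.default_rng([cfg.seed, 404])
        stopper = EarlyStopper(cfg.patience, cfg.improvement_threshold)
        best_snap = None
        train_hist, val_hist = [], []
        n = self.X_train.shape[0]
        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                xb, yb = self.X_train[idx], self.y_train[idx]
                if frozen:
                    z = encoder(xb, training=False)
                    logits, head_c = head.forward(z, training=True)
                else:
                    z, enc_c = encoder.forward(xb, training=True)
                    logits, head_c = head.forward(z, training=True)
                loss, dlogits = self._cross_entropy(logits, yb)
                self.optimizer_.zero_grad()
                dz = head.backward(dlogits, head_c)
                if not frozen:
                    encoder.backward(dz, enc_c)
                self.optimizer_.step()
                losses.append(loss)
            train_hist.append(float(np.mean(losses)))
            vl = self._val_loss(encoder, head)
            val_hist.append(vl)
            improved = vl < stopper.best_loss - stopper.min_delta
            stop = stopper.update(vl)
            if improved or best_snap is None:
                best_snap = (snapshot_parameters(encoder),
                             snapshot_parameters(head))
            if stop:
                break
        restore_parameters(encoder, best_snap[0])
        restore_parameters(head, best_snap[1])
        acc = evaluate_accuracy(lambda X: head(encoder(X)),
                                self.X_test, self.y_test)
        return FineTuneResult(
            test_accuracy=acc,
            epochs_run=stopper.epochs_seen,
            best_epoch=stopper.best_epoch,
            train_loss_history=train_hist,
            val_loss_history=val_hist,
            encoder_was_frozen=frozen,
            config=cfg,
            encoder=encoder,
            head=head,
            method=self.method,
        )


def baseline_train(encoder_config: EncoderConfig, n_classes: int,
                   X_train, y_train, X_val, y_val, X_test, y_test,
                   config: FineTuneConfig | None = None,
                   allow_frozen: bool = False) -> FineTuneResult:
    """Train the non-pre-trained reference model: a freshly initialized
    encoder plus head, whole network trained (unfrozen), same protocol.

    ``allow_frozen`` permits head-only training on a frozen random encoder as
    a diagnostic; by default the baseline is forced unfrozen.
    """
    config = config or FineTuneConfig()
    if config.mode == "frozen" and not allow_frozen:
        raise ValueError("the baseline comparison trains the whole network; "
                         "pass allow_frozen=True for the diagnostic variant")
    ec_fields = asdict(encoder_config)
    ec_fields["seed"] = config.seed + 29
    encoder = build_encoder(EncoderConfig(**ec_fields))
    model = FineTune(encoder, n_classes, X_train, y_train, X_val, y_val,
                     X_test, y_test, config, method="baseline")
    return model.fit()
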