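"""Self-supervised pre-training: InfoNCE contrastive, mask-and-reconstruct,
and teacher–student (EMA target) objectives.

Each pretext task is exposed statsmodels-style as a model object built from
the pre-training data — :class:`ScarfPretraining`, :class:`VimePretraining`,
:class:`ByolPretraining` — whose :meth:`fit` runs the training loop and
returns a :class:`PretrainResult` carrying the trained encoder, the per-epoch
loss histories and the configuration snapshot.  Only the encoder survives
pre-training; projectors, predictors and decoders are discarded, since the
downstream protocol attaches a fresh classification head to the encoder.

The loss functions (`info_nce_loss`, `byol_loss`, `vime_losses`) are public
and side-effect free; the training loops use internal variants that also
return analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .corruption import (
    compute_bounds,
    sample_mask,
    scarf_corrupt_batch,
    vime_corrupt_batch,
)
from .nn import (
    Adam,
    EncoderConfig,
    HeadConfig,
    Sequential,
    build_encoder,
    build_head,
    copy_parameters,
    ema_update,
)

__all__ = [
    "ScarfConfig",
    "VimeConfig",
    "ByolConfig",
    "PretrainResult",
    "info_nce_loss",
    "byol_loss",
    "vime_losses",
    "ScarfPretraining",
    "VimePretraining",
    "ByolPretraining",
]

_EPS_NORM = 1e-12


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _row_normalize(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Q, axis=1)
    if np.any(norms < _EPS_NORM):
        raise ValueError("degenerate input: zero-norm projection vector")
    return Q / norms[:, None], norms


def _info_nce_with_grads(Q: np.ndarray, Qt: np.ndarray, tau: float):
    """InfoNCE on cosine similarities; returns (loss, dQ, dQt).

    loss = (1/N) Σ_i −log( exp(s_ii/τ) / Σ_k exp(s_ik/τ) ), s_ij the cosine
    similarity between projection i of the clean batch and projection j of
    the corrupted batch; the denominator runs over the full batch including
    k = i.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    Qt = np.atleast_2d(np.asarray(Qt, dtype=float))
    if Q.shape != Qt.shape:
        raise ValueError("projection batches must have identical shape")
    N = Q.shape[0]
    if N < 2:
        raise ValueError("InfoNCE needs a batch of at least 2")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    U, qn = _row_normalize(Q)
    V, vn = _row_normalize(Qt)
    S = U @ V.T
    logits = S / tau
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    P = expl / expl.sum(axis=1, keepdims=True)
    loss = float(np.mean(-np.log(P[np.arange(N), np.arange(N)])))
    dS = (P - np.eye(N)) / (N * tau)
    dU = dS @ V
    dV = dS.T @ U
    # back through row normalization: d/dQ (Q/|Q|) projects out the radial part
    dQ = (dU - (dU * U).sum(axis=1, keepdims=True) * U) / qn[:, None]
    dQt = (dV - (dV * V).sum(axis=1, keepdims=True) * V) / vn[:, None]
    return loss, dQ, dQt


def info_nce_loss(Q: np.ndarray, Q_corrupt: np.ndarray, tau: float = 1.0) -> float:
    """InfoNCE contrastive loss over a batch of paired projections."""
    return _info_nce_with_grads(Q, Q_corrupt, tau)[0]


def _byol_with_grads(pred: np.ndarray, target: np.ndarray):
    """Mean over the batch of 2 − 2·cos(pred_i, target_i); grads w.r.t. pred
    only (the target branch is behind the stop-gradient barrier)."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    P, pn = _row_normalize(pred)
    T, _ = _row_normalize(target)
    cos = (P * T).sum(axis=1)
    loss = float(np.mean(2.0 - 2.0 * cos))
    N = pred.shape[0]
    dpred = (-2.0 / N) * (T - cos[:, None] * P) / pn[:, None]
    return loss, dpred


def byol_loss(pred: np.ndarray, target_proj: np.ndarray) -> float:
    """Teacher–student loss 2 − 2·⟨p, t⟩/(‖p‖‖t‖).

    Equals the squared Euclidean distance between the L2-normalized vectors;
    accepts single vectors or batches (mean over rows); range [0, 4].
    """
    return _byol_with_grads(pred, target_proj)[0]


def vime_losses(x: np.ndarray, m: np.ndarray, x_hat: np.ndarray,
                m_hat: np.ndarray, alpha: float) -> tuple[float, float, float]:
    """Mask-and-reconstruct losses (L_f, L_m, L = L_m + α·L_f).

    L_f is the mean squared error between reconstructed and original features
    over all entries; L_m is the sum over mask dimensions of binary
    cross-entropy between predicted mask probabilities and the true mask,
    averaged over the batch.  Probabilities outside (0, 1) are clamped at
    1e-7 with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    m = np.atleast_2d(np.asarray(m, dtype=float))
    m_hat = np.atleast_2d(np.asarray(m_hat, dtype=float))
    if x.shape != x_hat.shape or m.shape != m_hat.shape:
        raise ValueError("shape mismatch in reconstruction losses")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    clip = 1e-7
    if np.any(m_hat <= 0.0) or np.any(m_hat >= 1.0):
        warnings.warn("mask probabilities clamped to (1e-7, 1-1e-7)", UserWarning)
        m_hat = np.clip(m_hat, clip, 1.0 - clip)
    L_f = float(np.mean((x_hat - x) ** 2))
    bce = -(m * np.log(m_hat) + (1.0 - m) * np.log(1.0 - m_hat))
    L_m = float(bce.sum(axis=1).mean())
    return L_f, L_m, L_m + alpha * L_f


# ---------------------------------------------------------------------------
# Configs and result container
# ---------------------------------------------------------------------------

@dataclass
class ScarfConfig:
    """Contrastive pre-training hyper-parameters (τ, corruption fraction c)."""
    temperature: float = 1.0
    corruption_fraction: float = 0.30
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    projection_dim: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 2:
            raise ValueError("contrastive batch size must be >= 2")
        if not 0.0 <= self.corruption_fraction <= 1.0:
            raise ValueError("corruption fraction must be in [0, 1]")


@dataclass
class VimeConfig:
    """Mask-and-reconstruct hyper-parameters (mask rate p_m, loss weight α)."""
    mask_rate: float = 0.30
    alpha: float = 2.0
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")


@dataclass
class ByolConfig:
    """Teacher–student hyper-parameters (target decay λ, mask rate p_m)."""
    target_decay: float = 0.99
    mask_rate: float = 0.30
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    projection_dim: int = 256
    projection_hidden_dim: int = 4096
    symmetrize: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_decay <= 1.0:
            raise ValueError("target_decay must be in [0, 1]")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")


@dataclass
class PretrainResult:
    """Outcome of one pre-training run: the encoder plus loss histories."""

    encoder: Sequential
    loss_history: list
    val_loss_history: list
    config: object
    method: str

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.loss_history):
            raise ValueError("non-finite training loss in history")

    @property
    def epochs_run(self) -> int:
        return len(self.loss_history)

    def summary(self) -> str:
        lines = [
            f"{'Pre-training results':^58}",
            "=" * 58,
            f"{'Method:':<22}{self.method}",
            f"{'Epochs run:':<22}{self.epochs_run}",
            f"{'Final train loss:':<22}{self.loss_history[-1]:.6f}",
        ]
        if self.val_loss_history:
            lines.append(f"{'Final val loss:':<22}{self.val_loss_history[-1]:.6f}")
        lines.append(f"{'Encoder embedding dim:':<22}"
                     f"{self.encoder.config.embedding_dim}")
        lines.append("-" * 58)
        for k, v in asdict(self.config).items():
            lines.append(f"{k:<22}{v}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def write_history_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for i, tl in enumerate(self.loss_history):
                vl = self.val_loss_history[i] if self.val_loss_history else ""
                fh.write(f"{i + 1}\t{tl!r}\t{vl!r}\n" if vl != "" else
                         f"{i + 1}\t{tl!r}\t\n")


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _as_array(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def _batches(n: int, batch_size: int, rng: np.random.Generator, min_size: int = 2):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = perm[start:start + batch_size]
        if idx.shape[0] >= min_size:
            yield idx


def _check_finite(loss: float, method: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"{method} pre-training diverged: non-finite loss; lower the "
            f"learning rate or inspect the input scaling")


class ScarfPretraining:
    """Contrastive pre-training on uniform-support corrupted views.

    Per batch, every sample is paired with a corrupted copy (a fixed fraction
    of features redrawn uniformly inside the feature's training-set range);
    both views are encoded and projected, and the InfoNCE loss pulls each
    sample toward its own corrupted view and away from the other samples'.

    Parameters
    ----------
    X_pretrain : array or ExpressionMatrix, samples × genes
    encoder_config : EncoderConfig
    config : ScarfConfig
    X_val : optional validation matrix for per-epoch loss tracking; the
        validation corruption uses a fixed derived seed so the curve is
        comparable across epochs.
    """

    method = "scarf"

    def __init__(self, X_pretrain, encoder_config: EncoderConfig,
                 config: ScarfConfig | None = None, X_val=None):
        self.X = _as_array(X_pretrain)
        self.X_val = None if X_val is None else _as_array(X_val)
        self.encoder_config = encoder_config
        self.config = config or ScarfConfig()
        if self.X.shape[1] != encoder_config.input_dim:
            raise ValueError("encoder input_dim != data feature count")

    def fit(self) -> PretrainResult:
        cfg = self.config
        encoder = build_encoder(self.encoder_config)
        projector = build_head(HeadConfig(
            "scarf_projector", in_dim=self.encoder_config.embedding_dim,
            out_dim=cfg.projection_dim, hidden_dim=256,
            seed=cfg.seed + 1))
        bounds = compute_bounds(self.X)
        rng = np.random.default_rng([cfg.seed, 101])
        opt = Adam([encoder, projector], lr=cfg.learning_rate)
        history, val_history = [], []
        for epoch in range(cfg.epochs):
            losses = []
            for idx in _batches(self.X.shape[0], cfg.batch_size, rng):
                xb = self.X[idx]
                xc = scarf_corrupt_batch(xb, bounds, cfg.corruption_fraction, rng)
                z1, enc_c1 = encoder.forward(xb, training=True)
                q1, proj_c1 = projector.forward(z1, training=True)
                z2, enc_c2 = encoder.forward(xc, training=True)
                q2, proj_c2 = projector.forward(z2, training=True)
                loss, dq1, dq2 = _info_nce_with_grads(q1, q2, cfg.temperature)
                _check_finite(loss, self.method)
                opt.zero_grad()
                encoder.backward(projector.backward(dq1, proj_c1), enc_c1)
                encoder.backward(projector.backward(dq2, proj_c2), enc_c2)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if self.X_val is not None:
                val_history.append(self._val_loss(encoder, projector, bounds, epoch))
        return PretrainResult(encoder, history, val_history, cfg, self.method)

    def _val_loss(self, encoder, projector, bounds, epoch) -> float:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 777])
        losses = []
        for idx in _batches(self.X_val.shape[0], cfg.batch_size,
                            np.random.default_rng([cfg.seed, 778])):
            xb = self.X_val[idx]
            xc = scarf_corrupt_batch(xb, bounds, cfg.corruption_fraction, rng)
            q1 = projector(encoder(xb))
            q2 = projector(encoder(xc))
            losses.append(info_nce_loss(q1, q2, cfg.temperature))
        return float(np.mean(losses)) if losses else float("nan")


class VimePretraining:
    """Denoising pre-training: mask features, swap in marginal draws, and
    train the encoder jointly with a feature decoder (reconstruct original
    values) and a mask decoder (recover which features were swapped).

    The marginal reference for corruption is the pre-training matrix itself;
    fine-tuning and test samples never feed the corruption distribution.
    """

    method = "vime"

    def __init__(self, X_pretrain, encoder_config: EncoderConfig,
                 config: VimeConfig | None = None, X_val=None):
        self.X = _as_array(X_pretrain)
        self.X_val = None if X_val is None else _as_array(X_val)
        self.encoder_config = encoder_config
        self.config = config or VimeConfig()
        if self.X.shape[1] != encoder_config.input_dim:
            raise ValueError("encoder input_dim != data feature count")

    def _build_heads(self):
        ec = self.encoder_config
        common = dict(in_dim=ec.embedding_dim, out_dim=ec.input_dim,
                      hidden_dim=ec.hidden_dim, n_layers=ec.n_layers,
                      use_batchnorm=ec.use_batchnorm)
        fdec = build_head(HeadConfig("vime_feature_decoder",
                                     seed=self.config.seed + 1, **common))
        mdec = build_head(HeadConfig("vime_mask_decoder",
                                     seed=self.config.seed + 2, **common))
        return fdec, mdec

    def fit(self) -> PretrainResult:
        cfg = self.config
        encoder = build_encoder(self.encoder_config)
        fdec, mdec = self._build_heads()
        rng = np.random.default_rng([cfg.seed, 202])
        opt = Adam([encoder, fdec, mdec], lr=cfg.learning_rate)
        d = self.X.shape[1]
        history, val_history = [], []
        for epoch in range(cfg.epochs):
            losses = []
            for idx in _batches(self.X.shape[0], cfg.batch_size, rng):
                xb = self.X[idx]
                m = sample_mask(d, cfg.mask_rate, rng, n=xb.shape[0])
                xc = vime_corrupt_batch(xb, self.X, m, rng)
                z, enc_c = encoder.forward(xc, training=True)
                x_hat, f_c = fdec.forward(z, training=True)
                logits, m_c = mdec.forward(z, training=True)
                m_hat = 1.0 / (1.0 + np.exp(-logits))
                _, _, loss = vime_losses(xb, m, x_hat,
                                         np.clip(m_hat, 1e-7, 1 - 1e-7),
                                         cfg.alpha)
                _check_finite(loss, self.method)
                n_b = xb.shape[0]
                d_xhat = cfg.alpha * 2.0 * (x_hat - xb) / (n_b * d)
                d_logits = (m_hat - m) / n_b
                opt.zero_grad()
                dz = fdec.backward(d_xhat, f_c) + mdec.backward(d_logits, m_c)
                encoder.backward(dz, enc_c)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if self.X_val is not None:
                val_history.append(
                    self._val_loss(encoder, fdec, mdec, epoch))
        return PretrainResult(encoder, history, val_history, cfg, self.method)

    def _val_loss(self, encoder, fdec, mdec, epoch) -> float:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 777])
        d = self.X.shape[1]
        losses = []
        for idx in _batches(self.X_val.shape[0], cfg.batch_size,
                            np.random.default_rng([cfg.seed, 778])):
            xb = self.X_val[idx]
            m = sample_mask(d, cfg.mask_rate, rng, n=xb.shape[0])
            xc = vime_corrupt_batch(xb, self.X, m, rng)
            z = encoder(xc)
            x_hat = fdec(z)
            m_hat = 1.0 / (1.0 + np.exp(-mdec(z)))
            _, _, loss = vime_losses(xb, m, x_hat,
                                     np.clip(m_hat, 1e-7, 1 - 1e-7), cfg.alpha)
            losses.append(loss)
        return float(np.mean(losses)) if losses else float("nan")


class ByolPretraining:
    """Teacher–student pre-training with an EMA target network.

    The online branch (encoder → projector → predictor, parameters θ) sees
    the original sample; the target branch (encoder → projector, parameters
    ξ) sees the mask-and-swap corrupted sample and is behind a stop-gradient:
    the loss 2 − 2·cos(q_θ, z̃_ξ) is minimized with respect to θ only, while
    ξ follows θ by the exponential moving average ξ ← λξ + (1−λ)θ after every
    step.  Only the online encoder is returned.
    """

    method = "byol"

    def __init__(self, X_pretrain, encoder_config: EncoderConfig,
                 config: ByolConfig | None = None, X_val=None):
        self.X = _as_array(X_pretrain)
        self.X_val = None if X_val is None else _as_array(X_val)
        self.encoder_config = encoder_config
        self.config = config or ByolConfig()
        if self.X.shape[1] != encoder_config.input_dim:
            raise ValueError("encoder input_dim != data feature count")

    def _build_networks(self):
        ec, cfg = self.encoder_config, self.config
        online_enc = build_encoder(ec)
        head = dict(in_dim=ec.embedding_dim, out_dim=cfg.projection_dim,
                    hidden_dim=cfg.projection_hidden_dim)
        online_proj = build_head(HeadConfig("byol_projector",
                                            seed=cfg.seed + 1, **head))
        predictor = build_head(HeadConfig(
            "byol_predictor", in_dim=cfg.projection_dim,
            out_dim=cfg.projection_dim, hidden_dim=cfg.projection_hidden_dim,
            seed=cfg.seed + 2))
        target_enc = build_encoder(ec)
        target_proj = build_head(HeadConfig("byol_projector",
                                            seed=cfg.seed + 1, **head))
        copy_parameters(online_enc, target_enc)
        copy_parameters(online_proj, target_proj)
        return online_enc, online_proj, predictor, target_enc, target_proj

    def fit(self) -> PretrainResult:
        cfg = self.config
        enc, proj, pred, t_enc, t_proj = self._build_networks()
        rng = np.random.default_rng([cfg.seed, 303])
        opt = Adam([enc, proj, pred], lr=cfg.learning_rate)
        d = self.X.shape[1]
        history, val_history = [], []
        for epoch in range(cfg.epochs):
            losses = []
            for idx in _batches(self.X.shape[0], cfg.batch_size, rng):
                xb = self.X[idx]
                m = sample_mask(d, cfg.mask_rate, rng, n=xb.shape[0])
                xc = vime_corrupt_batch(xb, self.X, m, rng)
                loss = self._step(opt, enc, proj, pred, t_enc, t_proj, xb, xc)
                if cfg.symmetrize:
                    loss = 0.5 * loss + 0.5 * self._step(
                        opt, enc, proj, pred, t_enc, t_proj, xc, xb)
                _check_finite(loss, self.method)
                ema_update(t_enc, enc, cfg.target_decay)
                ema_update(t_proj, proj, cfg.target_decay)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if self.X_val is not None:
                val_history.append(
                    self._val_loss(enc, proj, pred, t_enc, t_proj, epoch))
        return PretrainResult(enc, history, val_history, cfg, self.method)

    @staticmethod
    def _step(opt, enc, proj, pred, t_enc, t_proj, x_online, x_target) -> float:
        z, enc_c = enc.forward(x_online, training=True)
        g, proj_c = proj.forward(z, training=True)
        p, pred_c = pred.forward(g, training=True)
        # target branch: forward only (inference mode: its running batch-norm
        # statistics follow the online branch via the EMA, never the forward
        # pass, so a decay of 1 freezes the target completely); stop-gradient
        # holds by construction
        t = t_proj(t_enc(x_target))
        loss, dp = _byol_with_grads(p, t)
        opt.zero_grad()
        enc.backward(proj.backward(pred.backward(dp, pred_c), proj_c), enc_c)
        opt.step()
        return loss

    def _val_loss(self, enc, proj, pred, t_enc, t_proj, epoch) -> float:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 777])
        d = self.X.shape[1]
        losses = []
        for idx in _batches(self.X_val.shape[0], cfg.batch_size,
                            np.random.default_rng([cfg.seed, 778])):
            xb = self.X_val[idx]
            m = sample_mask(d, cfg.mask_rate, rng, n=xb.shape[0])
            xc = vime_corrupt_batch(xb, self.X, m, rng)
            p = pred(proj(enc(xb)))
            t = t_proj(t_enc(xc))
            losses.append(byol_loss(p, t))
        return float(np.mean(losses)) if losses else float("nan")
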