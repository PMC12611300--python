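"""Minimal dense-network core with manual backpropagation.

Everything in this package that trains — the self-supervised pretext tasks and
the supervised fine-tuning — runs on the layers defined here: fully-connected
layers, batch normalization and ReLU, composed into :class:`Sequential` stacks
and optimized with Adam.  The forward pass is functional (it returns an
explicit cache), so one network can be run on several inputs per step (e.g.
the original and the corrupted view of a batch) and back-propagated through
each pass independently.

Parameters are plain numpy arrays exposed by name, which makes the exponential
moving average of a target network, freeze verification and checkpointing
trivial to implement and test.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "ReLU",
    "Sequential",
    "Adam",
    "EncoderConfig",
    "HeadConfig",
    "build_encoder",
    "build_head",
    "copy_parameters",
    "parameters_equal",
    "save_checkpoint",
    "load_checkpoint",
]


class Layer:
    """Base layer: named parameter/gradient/state dictionaries."""

    def parameters(self) -> dict:
        return {}

    def gradients(self) -> dict:
        return {}

    def state(self) -> dict:
        """Non-trainable arrays (e.g. batch-norm running statistics)."""
        return {}

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray, cache):  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``x @ W + b`` with He (fan-in) initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        if in_dim < 1 or out_dim < 1:
            raise ValueError(f"invalid Dense dims ({in_dim}, {out_dim})")
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        return x @ self.W + self.b, x

    def backward(self, dout, cache):
        x = cache
        self.dW += x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class BatchNorm(Layer):
    """Batch normalization over the sample axis.

    Training mode uses batch statistics and updates exponential running
    statistics; inference mode uses the running statistics only, so a frozen
    network is bit-stable.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        out = self.gamma * xhat + self.beta
        return out, (xhat, inv_sd, training and x.shape[0] > 1)

    def backward(self, dout, cache):
        xhat, inv_sd, used_batch_stats = cache
        n = dout.shape[0]
        self.dgamma += (dout * xhat).sum(axis=0)
        self.dbeta += dout.sum(axis=0)
        dxhat = dout * self.gamma
        if used_batch_stats:
            return (inv_sd / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        return dxhat * inv_sd


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, 0.0)
        return out, x > 0
    def backward(self, dout, cache):
        return dout * cache


class Sequential(Layer):
    """Ordered layer stack with prefixed parameter names."""

    def __init__(self, layers: list):
        self.layers = list(layers)

    def _named(self, getter) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in getter(layer).items():
                out[f"{i}.{layer.__class__.__name__}.{name}"] = arr
        return out

    def parameters(self):
        return self._named(lambda l: l.parameters())

    def gradients(self):
        return self._named(lambda l: l.gradients())

    def state(self):
        return self._named(lambda l: l.state())

    def forward(self, x, training=False):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, training)
            caches.append(c)
        return x, caches

    def backward(self, dout, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dout = layer.backward(dout, c)
        return dout

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass discarding the cache (inference convenience)."""
        return self.forward(x, training)[0]


class Adam:
    """Adam over an explicit (parameter, gradient) set.

    The parameter selection defines what trains: frozen fine-tuning simply
    constructs the optimizer over the head's parameters only, so no optimizer
    state ever exists for encoder parameters.
    """

    def __init__(self, modules: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.modules = list(modules)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._pairs = []
        for mod in self.modules:
            params, grads = mod.parameters(), mod.gradients()
            for name in params:
                self._pairs.append((params[name], grads[name]))
        self._m = [np.zeros_like(p) for p, _ in self._pairs]
        self._v = [np.zeros_like(p) for p, _ in self._pairs]

    def zero_grad(self):
        for _, g in self._pairs:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for (p, g), m, v in zip(self._pairs, self._m, self._v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Declarative configs and builders
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Architecture of the encoder ``e``: ``n_layers`` dense layers of width
    ``hidden_dim`` (the final layer of width ``embedding_dim``), each followed
    by optional batch normalization and ReLU."""

    input_dim: int
    n_layers: int = 4
    hidden_dim: int = 256
    embedding_dim: int = 256
    use_batchnorm: bool = True
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for d in (self.input_dim, self.hidden_dim, self.embedding_dim):
            if d < 1:
                raise ValueError("all dimensions must be >= 1")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")


HEAD_KINDS = (
    "scarf_projector",
    "byol_projector",
    "byol_predictor",
    "vime_feature_decoder",
    "vime_mask_decoder",
    "classifier",
)


@dataclass
class HeadConfig:
    """Auxiliary head used during pre-training or fine-tuning.

    ``in_dim`` is the embedding dimension for every kind; ``out_dim`` is the
    data dimension for the VIME decoders, the class count for the classifier,
    and the projection dimension otherwise.
    """

    kind: str
    in_dim: int
    out_dim: int
    hidden_dim: int = 0  # kind-dependent default applied in build_head
    n_layers: int = 4    # used by the VIME decoders (mirror the encoder)
    use_batchnorm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {self.kind!r}")
        if self.in_dim < 1 or self.out_dim < 1:
            raise ValueError("head dims must be >= 1")


def build_encoder(config: EncoderConfig) -> Sequential:
    """Build the encoder network from its config (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    widths = [config.hidden_dim] * (config.n_layers - 1) + [config.embedding_dim]
    layers: list = []
    d = config.input_dim
    for w in widths:
        layers.append(Dense(d, w, rng))
        if config.use_batchnorm:
            layers.append(BatchNorm(w))
        layers.append(ReLU())
        d = w
    enc = Sequential(layers)
    enc.config = config
    return enc


def build_head(config: HeadConfig) -> Sequential:
    rng = np.random.default_rng(config.seed)
    k = config.kind
    if k == "classifier":
        layers = [Dense(config.in_dim, config.out_dim, rng)]
    elif k == "scarf_projector":
        hidden = config.hidden_dim or 256
        layers = [Dense(config.in_dim, hidden, rng), ReLU(),
                  Dense(hidden, config.out_dim, rng)]
    elif k in ("byol_projector", "byol_predictor"):
        hidden = config.hidden_dim or 4096
        layers = [Dense(config.in_dim, hidden, rng), BatchNorm(hidden), ReLU(),
                  Dense(hidden, config.out_dim, rng)]
    else:  # vime decoders mirror the encoder stack, linear output layer
        hidden = config.hidden_dim or config.in_dim
        layers = []
        d = config.in_dim
        for _ in range(max(config.n_layers - 1, 0)):
            layers.append(Dense(d, hidden, rng))
            if config.use_batchnorm:
                layers.append(BatchNorm(hidden))
            layers.append(ReLU())
            d = hidden
        layers.append(Dense(d, config.out_dim, rng))
    head = Sequential(layers)
    head.config = config
    return head


# ---------------------------------------------------------------------------
# Parameter plumbing: copy, compare, EMA, checkpoints
# ---------------------------------------------------------------------------

def _all_arrays(net: Sequential) -> dict:
    return {**net.parameters(), **net.state()}


def _check_architecture(a: Sequential, b: Sequential) -> None:
    pa, pb = _all_arrays(a), _all_arrays(b)
    if pa.keys() != pb.keys():
        raise ValueError("architecture mismatch: different layer structure")
    for name in pa:
        if pa[name].shape != pb[name].shape:
            raise ValueError(f"architecture mismatch at {name}: "
                             f"{pa[name].shape} vs {pb[name].shape}")


def copy_parameters(src: Sequential, dst: Sequential) -> None:
    """Elementwise copy of all parameters and state from src into dst."""
    _check_architecture(src, dst)
    sa, da = _all_arrays(src), _all_arrays(dst)
    for name in sa:
        da[name][...] = sa[name]


def parameters_equal(a: Sequential, b: Sequential, tol: float = 0.0) -> bool:
    """True iff every parameter and state array agrees within ``tol``."""
    _check_architecture(a, b)
    pa, pb = _all_arrays(a), _all_arrays(b)
    return all(np.max(np.abs(pa[n] - pb[n]), initial=0.0) <= tol for n in pa)


def snapshot_parameters(net: Sequential) -> dict:
    return {name: arr.copy() for name, arr in _all_arrays(net).items()}


def restore_parameters(net: Sequential, snap: dict) -> None:
    arrays = _all_arrays(net)
    for name, arr in snap.items():
        arrays[name][...] = arr


def ema_update(target: Sequential, online: Sequential, decay: float) -> None:
    """Exponential-moving-average update of the target network.

    Each target array moves to ``decay * target + (1 - decay) * online``;
    the online network is untouched.  Running batch-norm statistics follow
    the same rule so the target stays a coherent network.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError("decay must be in [0, 1]")
    _check_architecture(target, online)
    ta, oa = _all_arrays(target), _all_arrays(online)
    for name in ta:
        ta[name][...] = decay * ta[name] + (1.0 - decay) * oa[name]


def save_checkpoint(path, net: Sequential) -> None:
    """Write config + named parameter/state arrays to a single .npz archive."""
    cfg = getattr(net, "config", None)
    meta = json.dumps({
        "config_class": type(cfg).__name__ if cfg is not None else None,
        "config": asdict(cfg) if cfg is not None else None,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **_all_arrays(net))


def load_checkpoint(path) -> Sequential:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["config_class"] == "EncoderConfig":
        net = build_encoder(EncoderConfig(**meta["config"]))
    elif meta["config_class"] == "HeadConfig":
        net = build_head(HeadConfig(**meta["config"]))
    else:
        raise ValueError("checkpoint has no recognizable config")
    target = _all_arrays(net)
    for name, arr in arrays.items():
        target[name][...] = arr
    return net


def parameter_count(net: Sequential) -> int:
    return sum(arr.size for arr in net.parameters().values())
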