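"""Label-efficiency benchmarking: accuracy curves, AUPC gain, data savings,
and the pre-training-set-size sweep.

The central object is the :class:`AccuracyCurve` — mean/sd test accuracy over
repeats, indexed by the labeled proportion ``p`` made available during
fine-tuning.  Curves for a pre-trained method and for the non-pre-trained
baseline are compared by:

* the **gain** ``g(m1, m2)``: the difference of the areas under the two
  accuracy curves (AUPC) restricted to p ∈ [0.02, 0.3], the regime of
  realistically small labeled sets; ``g > 0`` means m1 is better on average;
* **data savings**: one minus the smallest proportion at which the
  pre-trained mean curve reaches the baseline's maximum mean accuracy.

Repeats are averaged per proportion first; the integral is taken on the mean
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .finetune import FineTune, FineTuneConfig, FineTuneResult, baseline_train
from .nn import EncoderConfig, Sequential
from .pretraining import (
    ByolConfig,
    ByolPretraining,
    ScarfConfig,
    ScarfPretraining,
    VimeConfig,
    VimePretraining,
)
from .synthetic import subsample_labeled

__all__ = [
    "AccuracyCurve",
    "GainResult",
    "SavingsResult",
    "BenchmarkData",
    "default_proportion_grid",
    "default_size_grid",
    "run_curve",
    "aupc",
    "gain",
    "data_savings",
    "pretrain_size_sweep",
    "make_pretrainer",
]

GAIN_RANGE = (0.02, 0.30)

PRETRAINERS = {
    "scarf": (ScarfPretraining, ScarfConfig),
    "vime": (VimePretraining, VimeConfig),
    "byol": (ByolPretraining, ByolConfig),
}


def default_proportion_grid(step: float = 0.01) -> np.ndarray:
    """Labeled-proportion grid 0.02 .. 1.0 (99 points at the full step 0.01)."""
    return np.round(np.arange(0.02, 1.0 + step / 2, step), 6)


def default_size_grid() -> np.ndarray:
    """Pre-training-proportion grid: 0.01..0.05 step 0.01, then 0.05..1
    step 0.05 (24 unique points)."""
    fine = np.arange(0.01, 0.05 + 0.005, 0.01)
    coarse = np.arange(0.05, 1.0 + 0.025, 0.05)
    return np.unique(np.round(np.concatenate([fine, coarse]), 6))


@dataclass
class AccuracyCurve:
    """Mean/sd test accuracy per labeled proportion, for one method."""

    proportions: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n_repeats: int
    method: str

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=float)
        self.sd_accuracy = np.asarray(self.sd_accuracy, dtype=float)
        if self.proportions.ndim != 1 or np.any(np.diff(self.proportions) <= 0):
            raise ValueError("proportion grid must be strictly increasing")
        if not (self.proportions.shape == self.mean_accuracy.shape
                == self.sd_accuracy.shape):
            raise ValueError("curve arrays must share one shape")
        if np.any(self.sd_accuracy < 0):
            raise ValueError("sd must be >= 0")
        if np.any((self.mean_accuracy < 0) | (self.mean_accuracy > 1)):
            raise ValueError("mean accuracy must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "p": self.proportions,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "n_repeats": self.n_repeats,
            "method": self.method,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AccuracyCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["p"].to_numpy(), df["mean_accuracy"].to_numpy(),
                   df["sd_accuracy"].to_numpy(),
                   int(df["n_repeats"].iloc[0]), str(df["method"].iloc[0]))


@dataclass
class GainResult:
    """AUPC difference g(m1, m2) over the integration range."""

    g: float
    range: tuple
    m1: str
    m2: str

    def __repr__(self):
        return (f"GainResult(g={self.g:.6f}, range={self.range}, "
                f"m1={self.m1!r}, m2={self.m2!r})")


@dataclass
class SavingsResult:
    """Labeled-data savings of a pre-trained curve over the baseline."""

    p_star: float
    savings: float
    reached: bool
    baseline_max: float


@dataclass
class BenchmarkData:
    """The matrices one benchmark scenario fine-tunes and evaluates on."""

    X_finetune: np.ndarray
    y_finetune: np.ndarray
    X_finetune_val: np.ndarray
    y_finetune_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    n_classes: int

    def __post_init__(self):
        for attr in ("X_finetune", "X_finetune_val", "X_test"):
            setattr(self, attr,
                    np.asarray(getattr(getattr(self, attr), "values",
                                       getattr(self, attr)), dtype=float))
        for attr in ("y_finetune", "y_finetune_val", "y_test"):
            setattr(self, attr, np.asarray(getattr(self, attr)))


def _derived_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def run_curve(method: str, data: BenchmarkData,
              encoder: Sequential | None = None,
              encoder_config: EncoderConfig | None = None,
              mode: str = "unfrozen",
              grid: np.ndarray | None = None,
              n_repeats: int = 5,
              base_seed: int = 0,
              finetune_config: FineTuneConfig | None = None,
              collect_rows: list | None = None) -> AccuracyCurve:
    """Fine-tune ``n_repeats`` models at each labeled proportion of the grid.

    For the ``baseline`` method a fresh encoder is initialized per run
    (``encoder_config`` required); otherwise the supplied pre-trained
    ``encoder`` is the starting point.  Each (p, repeat) run gets a distinct
    derived seed driving the labeled subsample, the head initialization, and
    the training shuffles.
    """
    if method != "baseline" and encoder is None:
        raise ValueError(f"method {method!r} requires a pre-trained encoder "
                         f"checkpoint; none was provided")
    if method == "baseline" and encoder_config is None:
        raise ValueError("baseline runs require encoder_config")
    grid = default_proportion_grid() if grid is None else np.asarray(grid, float)
    template = finetune_config or FineTuneConfig()
    n_ft = data.X_finetune.shape[0]
    positions = np.arange(n_ft)
    means, sds = [], []
    for pi, p in enumerate(grid):
        accs = []
        for r in range(n_repeats):
            seed = _derived_seed(base_seed, pi, r)
            sub = subsample_labeled(positions, data.y_finetune, float(p), seed)
            cfg = replace(template, mode=mode, p=float(p), seed=seed)
            if method == "baseline":
                res = baseline_train(
                    encoder_config, data.n_classes,
                    data.X_finetune[sub], data.y_finetune[sub],
                    data.X_finetune_val, data.y_finetune_val,
                    data.X_test, data.y_test, cfg)
            else:
                res = FineTune(
                    encoder, data.n_classes,
                    data.X_finetune[sub], data.y_finetune[sub],
                    data.X_finetune_val, data.y_finetune_val,
                    data.X_test, data.y_test, cfg, method=method).fit()
            accs.append(res.test_accuracy)
            if collect_rows is not None:
                collect_rows.append(res.to_row() | {"method": method})
        means.append(float(np.mean(accs)))
        sds.append(float(np.std(accs)))
    return AccuracyCurve(grid, means, sds, n_repeats, method)


def aupc(curve: AccuracyCurve, range_: tuple = GAIN_RANGE) -> float:
    """Trapezoidal area under the mean accuracy curve on [a, b]."""
    a, b = range_
    mask = (curve.proportions >= a - 1e-12) & (curve.proportions <= b + 1e-12)
    if mask.sum() < 2:
        raise ValueError(f"need at least two grid points inside [{a}, {b}]")
    return float(np.trapezoid(curve.mean_accuracy[mask],
                              curve.proportions[mask]))


def _interp_onto(curve: AccuracyCurve, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, curve.proportions, curve.mean_accuracy)


def gain(m1: AccuracyCurve, m2: AccuracyCurve,
         range_: tuple = GAIN_RANGE) -> GainResult:
    """g(m1, m2) = AUPC(m1) − AUPC(m2) on the integration range.

    Curves on mismatched grids are first linearly interpolated onto the
    union of their grid points inside the range (the integral presumes a
    common support); antisymmetric by construction.
    """
    a, b = range_
    for c in (m1, m2):
        if c.proportions[0] > a + 1e-12 or c.proportions[-1] < b - 1e-12:
            raise ValueError(f"curve {c.method!r} does not cover [{a}, {b}]")
    common = np.union1d(m1.proportions, m2.proportions)
    common = common[(common >= a - 1e-12) & (common <= b + 1e-12)]
    y1 = _interp_onto(m1, common)
    y2 = _interp_onto(m2, common)
    g = float(np.trapezoid(y1 - y2, common))
    return GainResult(g, (a, b), m1.method, m2.method)


def data_savings(pretrained: AccuracyCurve,
                 baseline: AccuracyCurve) -> SavingsResult:
    """Smallest proportion at which the pre-trained mean curve reaches the
    baseline's maximum mean accuracy; savings = 1 − that proportion."""
    baseline_max = float(baseline.mean_accuracy.max())
    hit = np.flatnonzero(pretrained.mean_accuracy >= baseline_max - 1e-12)
    if hit.size == 0:
        return SavingsResult(p_star=float("nan"), savings=0.0,
                             reached=False, baseline_max=baseline_max)
    p_star = float(pretrained.proportions[hit[0]])
    return SavingsResult(p_star=p_star, savings=1.0 - p_star,
                         reached=True, baseline_max=baseline_max)


def make_pretrainer(method: str, X_pretrain, encoder_config: EncoderConfig,
                    config=None, X_val=None):
    """Instantiate the pre-training model object for a method name."""
    if method not in PRETRAINERS:
        raise ValueError(f"unknown pre-training method {method!r}; "
                         f"choose from {sorted(PRETRAINERS)}")
    cls, cfg_cls = PRETRAINERS[method]
    return cls(X_pretrain, encoder_config, config or cfg_cls(), X_val=X_val)


def pretrain_size_sweep(method: str, X_pretrain, y_pretrain,
                        data: BenchmarkData, encoder_config: EncoderConfig,
                        pretrain_config=None,
                        q_grid: np.ndarray | None = None,
                        p: float = 0.1, n_repeats: int = 5,
                        base_seed: int = 0,
                        finetune_config: FineTuneConfig | None = None) -> pd.DataFrame:
    """Accuracy at fixed fine-tuning proportion ``p`` as a function of the
    pre-training-set fraction ``q``.

    For each q, a stratified q-fraction of the pre-training split is used for
    pre-training, then ``n_repeats`` unfrozen fine-tuning runs at proportion
    ``p``.  A baseline row (q = 0, no pre-training) is included.
    """
    q_grid = default_size_grid() if q_grid is None else np.asarray(q_grid, float)
    X_pretrain = np.asarray(getattr(X_pretrain, "values", X_pretrain), float)
    y_pretrain = np.asarray(y_pretrain)
    positions = np.arange(X_pretrain.shape[0])
    min_batch = (pretrain_config.batch_size if pretrain_config is not None
                 else 2)
    rows = []

    base_curve = run_curve("baseline", data, encoder_config=encoder_config,
                           grid=np.array([p]), n_repeats=n_repeats,
                           base_seed=base_seed, finetune_config=finetune_config)
    rows.append({"q": 0.0, "n_pretrain": 0, "method": "baseline",
                 "mean_accuracy": base_curve.mean_accuracy[0],
                 "sd_accuracy": base_curve.sd_accuracy[0]})

    for qi, q in enumerate(q_grid):
        sub = subsample_labeled(positions, y_pretrain, float(q),
                                _derived_seed(base_seed, 7000, qi))
        if sub.shape[0] < 2:
            raise ValueError(
                f"q={q} leaves {sub.shape[0]} pre-training samples; too few "
                f"to form a batch")
        pre = make_pretrainer(method, X_pretrain[sub], encoder_config,
                              pretrain_config)
        result = pre.fit()
        curve = run_curve(method, data, encoder=result.encoder,
                          grid=np.array([p]), n_repeats=n_repeats,
                          base_seed=_derived_seed(base_seed, 8000, qi),
                          finetune_config=finetune_config)
        rows.append({"q": float(q), "n_pretrain": int(sub.shape[0]),
                     "method": method,
                     "mean_accuracy": curve.mean_accuracy[0],
                     "sd_accuracy": curve.sd_accuracy[0]})
    return pd.DataFrame(rows)


def plot_curves(curves: list, path, title: str = "Label efficiency") -> None:
    """Optional curve plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(c.proportions, c.mean_accuracy, label=c.method)
        ax.fill_between(c.proportions,
                        c.mean_accuracy - c.sd_accuracy,
                        c.mean_accuracy + c.sd_accuracy, alpha=0.2)
    ax.set_xlabel("labeled proportion p")
    ax.set_ylabel("test accuracy")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
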