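"""A small residual-network classifier for univariate time series.

The network takes a length-T series (reshaped to a T x 1 single-channel
plane, so the convolutions run k x 1 kernels), stacks chi residual blocks
(chi in [2, 10], chosen from the training-set distribution), applies global
average pooling and ends in a dense softmax head trained with cross-entropy.
Each residual block is the community time-series variant: three
convolution -> batch-norm -> ReLU stages with kernel lengths 8/5/3, summed
with a shortcut path that carries the block input (projected by a 1x1
convolution only when channel counts differ).

Training inputs may be additively perturbed with scaled Gaussian noise drawn
from the training matrix's moments before normalization; the same perturbed
signal feeds both the convolutional path and the shortcut, which is what
turns the identity connection into a perturbation connection.

Everything is seed-deterministic: parameter initialization, batch shuffling
and (through :class:`~shapaal.perturbation.PerturbationConfig`) the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._nn import (
    Adam,
    SGD,
    BatchNorm1d,
    Conv1d,
    Dense,
    GlobalAveragePool,
    ReLU,
    cross_entropy,
    softmax,
)
from .data_io import NormalizationStats, TimeSeriesDataset
from .errors import ConfigError, ContractError, TrainingDivergenceError
from .perturbation import PerturbationConfig, perturb, sample_perturbation

DEPTH_BOUNDS = (2, 10)
DEFAULT_KERNELS = (8, 5, 3)


def compute_batch_size(n_train: int) -> int:
    """Batch-size rule: 2 for small training sets (n <= 10), otherwise
    min(ceil(n/10), 16)."""
    if n_train < 1:
        raise ContractError("n_train must be >= 1")
    if n_train <= 10:
        return 2
    return min(math.ceil(n_train / 10), 16)


def estimate_depth(train: TimeSeriesDataset, bounds=DEPTH_BOUNDS) -> int:
    """Pick the number of residual blocks from a training-set complexity score.

    This is a deliberately simple, documented proxy for distribution-aware
    elastic depth estimation: score = C * log(number of distinct instances
    after exact deduplication), mapped affinely from the small-sample regime
    (C=2, 20 instances) up to (C=3, 200 instances) onto [2, 10] and clamped.
    It is deterministic, invariant to exact duplication of rows, and
    monotone non-decreasing in the score. An explicit ``n_blocks`` in the
    model config overrides it.
    """
    lo, hi = bounds
    distinct = np.unique(train.series, axis=0).shape[0]
    c = max(train.n_classes, 1)
    score = c * math.log(max(distinct, 1))
    s_lo = 2 * math.log(20)
    s_hi = 3 * math.log(200)
    frac = (score - s_lo) / (s_hi - s_lo)
    depth = int(round(lo + frac * (hi - lo)))
    return max(lo, min(hi, depth))


@dataclass
class ResNetConfig:
    """Hyperparameters of the classifier.

    ``n_blocks=None`` asks :func:`estimate_depth` to pick chi from the data.
    ``batch_size=None`` applies the batch-size rule. The learning rate is
    fixed (no schedule).
    """

    n_blocks: Optional[int] = None
    batch_size: Optional[int] = None
    learning_rate: float = 1e-3
    epochs: int = 500
    filters_per_block: int = 64
    kernels: tuple = DEFAULT_KERNELS
    optimizer: str = "adam"  # "adam" | "sgd"
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks is not None and not (DEPTH_BOUNDS[0] <= self.n_blocks <= DEPTH_BOUNDS[1]):
            raise ConfigError(f"n_blocks must lie in {DEPTH_BOUNDS}")
        if self.batch_size is not None and self.batch_size < 1:
            raise ConfigError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


class _ResidualBlock:
    def __init__(self, c_in, c_out, kernels, t, rng):
        ks = [min(k, t) for k in kernels]
        self.conv1, self.bn1 = Conv1d(c_in, c_out, ks[0], rng), BatchNorm1d(c_out)
        self.conv2, self.bn2 = Conv1d(c_out, c_out, ks[1], rng), BatchNorm1d(c_out)
        self.conv3, self.bn3 = Conv1d(c_out, c_out, ks[2], rng), BatchNorm1d(c_out)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        if c_in != c_out:
            self.short_conv, self.short_bn = Conv1d(c_in, c_out, 1, rng), BatchNorm1d(c_out)
        else:
            self.short_conv = self.short_bn = None

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.short_conv is not None:
            out += [self.short_conv, self.short_bn]
        return out

    def forward(self, x, train):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)
        h = self.bn3.forward(self.conv3.forward(h, train), train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(h + s, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh, ds = d, d
        dh = self.conv3.backward(self.bn3.backward(dh))
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        if self.short_conv is not None:
            ds = self.short_conv.backward(self.short_bn.backward(ds))
        return dh + ds


class _Network:
    def __init__(self, config: ResNetConfig, input_length: int, n_classes: int):
        rng = np.random.default_rng(config.seed)
        chi = config.n_blocks
        f = config.filters_per_block
        self.blocks = []
        c_in = 1
        for _ in range(chi):
            self.blocks.append(_ResidualBlock(c_in, f, config.kernels, input_length, rng))
            c_in = f
        self.gap = GlobalAveragePool()
        self.head = Dense(f, n_classes, rng)

    def layers(self):
        out = []
        for b in self.blocks:
            out += b.layers()
        out.append(self.head)
        return out

    def parameters(self):
        params, grads = [], []
        for layer in self.layers():
            params += layer.params
            grads += layer.grads
        return params, grads

    def forward(self, x, train):
        h = x
        for b in self.blocks:
            h = b.forward(h, train)
        return self.head.forward(self.gap.forward(h, train), train)

    def backward(self, dlogits):
        d = self.gap.backward(self.head.backward(dlogits))
        for b in reversed(self.blocks):
            d = b.backward(d)
        return d

    def snapshot(self):
        params, _ = self.parameters()
        state = [p.copy() for p in params]
        running = []
        for layer in self.layers():
            if isinstance(layer, BatchNorm1d):
                running.append((layer.running_mean.copy(), layer.running_var.copy()))
        return state, running

    def restore(self, snap):
        state, running = snap
        params, _ = self.parameters()
        for p, s in zip(params, state):
            p[...] = s
        it = iter(running)
        for layer in self.layers():
            if isinstance(layer, BatchNorm1d):
                rm, rv = next(it)
                layer.running_mean[...] = rm
                layer.running_var[...] = rv


@dataclass
class TrainedModel:
    """A (possibly unfitted) residual-network classifier with its config,
    normalization statistics and training trace."""

    network: _Network
    config: ResNetConfig
    input_length: int
    n_classes: int
    label_set: tuple = ()
    norm_stats: Optional[NormalizationStats] = None
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})
    variant_tag: str = "M"
    fitted: bool = False

    def parameter_count(self) -> int:
        params, _ = self.network.parameters()
        return int(sum(p.size for p in params))

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.input_length:
            raise ContractError(
                f"input length {x.shape[1]} != model's training length {self.input_length}"
            )
        return x

    def forward_probs(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        return softmax(self.network.forward(x[:, None, :], train))

    def input_gradient(self, x: np.ndarray, class_idx: np.ndarray) -> np.ndarray:
        """d(logit of class_idx)/d(input), evaluated in inference mode.

        Used by the gradient-based per-sample attribution path.
        """
        x = self._check_input(x)
        class_idx = np.asarray(class_idx, dtype=np.int64)
        logits = self.network.forward(x[:, None, :], False)
        dlogits = np.zeros_like(logits)
        dlogits[np.arange(len(class_idx)), class_idx] = 1.0
        dx = self.network.backward(dlogits)
        return dx[:, 0, :]


def build_model(config: ResNetConfig, input_length: int, n_classes: int) -> TrainedModel:
    """Construct an unfitted classifier; initialization is seeded."""
    if n_classes < 2:
        raise ConfigError("classification needs at least 2 classes")
    if input_length < 2:
        raise ConfigError("input length must be at least 2")
    cfg = config
    if cfg.n_blocks is None:
        raise ConfigError("n_blocks unset; call estimate_depth or set it explicitly")
    net = _Network(cfg, input_length, n_classes)
    return TrainedModel(network=net, config=cfg, input_length=input_length, n_classes=n_classes)


def fit(
    model: TrainedModel,
    train: TimeSeriesDataset,
    perturb_cfg: Optional[PerturbationConfig] = None,
    norm_stats: Optional[NormalizationStats] = None,
    clean_series: Optional[np.ndarray] = None,
) -> TrainedModel:
    """Minimize cross-entropy by seeded mini-batch gradient descent.

    ``train`` must already be z-normalized, after optional perturbation —
    perturb first, normalize second is the supported order. With the default
    ``per_instance_once`` policy the caller perturbs once up front (which
    keeps alpha = 0 runs bit-identical to unperturbed ones, since x + 0 is
    x). With ``per_instance_per_epoch`` fresh noise is drawn each epoch on
    the raw inputs, which must then be supplied via ``clean_series`` along
    with ``norm_stats``.
    """
    x = train.series
    y = train.encoded_labels
    if x.shape[1] != model.input_length:
        raise ContractError("training length does not match the model")
    cfg = model.config
    batch_size = cfg.batch_size if cfg.batch_size is not None else compute_batch_size(train.n)
    params, grads = model.network.parameters()
    if cfg.optimizer == "adam":
        opt = Adam(params, grads, lr=cfg.learning_rate)
    else:
        opt = SGD(params, grads, lr=cfg.learning_rate)

    shuffle_rng = np.random.default_rng((cfg.seed, 0x5AFE))
    per_epoch = perturb_cfg is not None and perturb_cfg.resample_policy == "per_instance_per_epoch"
    if per_epoch and (clean_series is None or norm_stats is None):
        raise ContractError(
            "per_instance_per_epoch resampling needs clean_series and norm_stats"
        )

    best_loss, best_snap = np.inf, None
    for epoch in range(cfg.epochs):
        xe = x
        if per_epoch:
            epoch_cfg = PerturbationConfig(
                alpha=perturb_cfg.alpha,
                mu=perturb_cfg.mu,
                sigma2=perturb_cfg.sigma2,
                seed=int(np.random.default_rng((perturb_cfg.seed, epoch)).integers(2**31)),
                resample_policy=perturb_cfg.resample_policy,
            )
            draw = sample_perturbation(epoch_cfg, clean_series.shape)
            xe = (perturb(clean_series, draw) - norm_stats.mean) / norm_stats.std
        order = shuffle_rng.permutation(train.n)
        losses, hits, seen = [], 0, 0
        for start in range(0, train.n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = xe[idx][:, None, :], y[idx]
            logits = model.network.forward(xb, True)
            probs = softmax(logits)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}", epoch=epoch
                )
            losses.append(loss * len(idx))
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += len(idx)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.network.backward(dlogits)
            opt.step()
        epoch_loss = float(np.sum(losses) / seen)
        model.history["loss"].append(epoch_loss)
        model.history["accuracy"].append(hits / seen)
        if cfg.restore_best and epoch_loss < best_loss:
            best_loss = epoch_loss
            best_snap = model.network.snapshot()

    if cfg.restore_best and best_snap is not None:
        model.network.restore(best_snap)
    model.label_set = train.label_set
    if norm_stats is not None:
        model.norm_stats = norm_stats
    model.fitted = True
    return model


def predict(model: TrainedModel, data: TimeSeriesDataset):
    """Class probabilities and decoded argmax labels for normalized data."""
    if not model.fitted:
        raise ContractError("model is not fitted")
    if data.t != model.input_length:
        raise ContractError(
            f"series length {data.t} != model's training length {model.input_length}"
        )
    probs = model.forward_probs(data.series, train=False)
    table = np.asarray(model.label_set, dtype=np.int64)
    labels = table[probs.argmax(axis=1)]
    return probs, labels


def clone_unfitted(model: TrainedModel, seed: Optional[int] = None) -> TrainedModel:
    """Fresh re-initialized model with the same architecture (no warm start)."""
    cfg = model.config if seed is None else replace(model.config, seed=seed)
    return build_model(cfg, model.input_length, model.n_classes)
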