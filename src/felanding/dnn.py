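"""Fully connected tanh network for landing-height-pair classification.

The reference architecture is 600 inputs, ten hidden layers of 1,200 tanh
units and a 2-unit output read through a softmax; training is mini-batch
stochastic gradient descent (momentum optional) on the cross-entropy loss,
batch size 25, epoch limit 3,000, on an 80/20 random trial split.  Because
depth-10 tanh stacks saturate under naive initialization, weights start
Xavier-uniform and inputs are standardized per column with training-set
statistics (both recorded with the network).  The forward pass can cache
every layer's pre-activations and activations, which is what the layer-wise
relevance propagation module consumes.

Everything is plain NumPy and fully determined by (data, configs, seeds);
tests and the scaled-down study runs use a 600-64-64-2 variant of the same
code path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, SignalError, TrainingDivergedError
from .signal_prep import PairDataset


@dataclass(frozen=True)
class NetworkConfig:
    """Layer plan of the fully connected classifier."""

    n_inputs: int = 600
    hidden_layers: int = 10
    hidden_units: int = 1200
    n_outputs: int = 2
    init_seed: int = 0

    def __post_init__(self):
        for name in ("n_inputs", "hidden_layers", "hidden_units", "n_outputs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *([self.hidden_units] * self.hidden_layers), self.n_outputs)

    def parameter_count(self) -> tuple[int, int]:
        """(number of weights, number of biases) of the fully connected stack."""
        sizes = self.layer_sizes
        weights = sum(a * b for a, b in zip(sizes, sizes[1:]))
        biases = sum(sizes[1:])
        return weights, biases


def scaled_down_config(n_inputs: int = 600, hidden_units: int = 64,
                       hidden_layers: int = 2, init_seed: int = 0) -> NetworkConfig:
    """Desk-scale variant (600-64-64-2 by default) of the same architecture."""
    return NetworkConfig(n_inputs=n_inputs, hidden_layers=hidden_layers,
                         hidden_units=hidden_units, n_outputs=2, init_seed=init_seed)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 25
    epochs: int = 3000
    train_fraction: float = 0.80
    shuffle_seed: int = 0
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-3  # L2 penalty; tanh stacks overfit small cohorts without it
    augment_sd: float = 0.3  # sd of Gaussian jitter on standardized training inputs
    patience: int | None = None  # early stopping disabled by default

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.batch_size <= 0:
            raise ConfigurationError("batch_size must be positive")
        if self.epochs <= 0:
            raise ConfigurationError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


@dataclass
class ForwardCache:
    """Per-layer pre-activations z and activations u for one batch.

    ``activations[0]`` is the (standardized) input; ``activations[l]`` is
    tanh(z_l) for hidden layers and the raw pre-softmax scores at the top.
    """

    pre_activations: list[np.ndarray]
    activations: list[np.ndarray]


@dataclass
class TrainedNetwork:
    """Layer weights/biases plus input-scaling parameters and provenance."""

    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    train_log: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray, cache: bool = False,
                standardized: bool = False):
        """Class scores (pre-softmax) for rows of ``X``; optionally the full
        layer cache needed by relevance propagation.

        Raises :class:`SignalError` naming the layer if non-finite values
        appear during propagation.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.n_inputs:
            raise ConfigurationError(
                f"input has {X.shape[1]} features, expected {self.config.n_inputs}")
        if not np.all(np.isfinite(X)):
            raise SignalError("non-finite input to forward pass")
        u = X if standardized else (X - self.x_mean) / self.x_sd
        zs, us = [], [u]
        n_layers = len(self.weights)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = u @ w + b
            if not np.all(np.isfinite(z)):
                raise SignalError(f"non-finite pre-activation at layer {l + 1}")
            u = np.tanh(z) if l < n_layers - 1 else z
            zs.append(z)
            us.append(u)
        scores = us[-1]
        if cache:
            return scores, ForwardCache(pre_activations=zs, activations=us)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class indices; ties break to the lower class index."""
        scores = self.forward(X)
        return np.argmax(scores, axis=1)  # argmax returns the first (lowest) tie

    def save(self, path) -> None:
        bundle = {
            "config": self.config.__dict__,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "train_log": {k: v for k, v in self.train_log.items() if k != "loss"},
            "loss": [float(v) for v in self.train_log.get("loss", [])],
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            bundle = json.load(fh)
        log = dict(bundle.get("train_log", {}))
        log["loss"] = bundle.get("loss", [])
        return cls(
            config=NetworkConfig(**bundle["config"]),
            weights=[np.array(w) for w in bundle["weights"]],
            biases=[np.array(b) for b in bundle["biases"]],
            x_mean=np.array(bundle["x_mean"]),
            x_sd=np.array(bundle["x_sd"]),
            train_log=log,
        )


def initialize_network(config: NetworkConfig) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Xavier-uniform weights (tanh-friendly at depth), zero biases."""
    rng = np.random.default_rng(config.init_seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def split_dataset(data: PairDataset, cfg: TrainConfig,
                  max_redraws: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test row indices: a pure function of the shuffle seed.

    At the default 1,120-row pair this is an 896/224 split.  If a class ends
    up absent from either side the split is re-drawn with an advanced seed
    (warned, documented policy), up to ``max_redraws`` times.
    """
    n = data.matrix.shape[0]
    n_train = int(round(cfg.train_fraction * n))
    if not 0 < n_train < n:
        raise ConfigurationError("train_fraction leaves an empty train or test set")
    for attempt in range(max_redraws):
        rng = np.random.default_rng(cfg.shuffle_seed + attempt)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        ok = all(len(np.unique(data.labels[idx])) == 2 for idx in (train_idx, test_idx))
        if ok:
            if attempt:
                warnings.warn(f"split re-drawn {attempt} time(s) to get both classes on both sides")
            return np.sort(train_idx), np.sort(test_idx)
    raise ConfigurationError("could not draw a split with both classes on both sides")


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def train(data: PairDataset, ncfg: NetworkConfig, tcfg: TrainConfig,
          train_idx: np.ndarray | None = None,
          test_idx: np.ndarray | None = None) -> TrainedNetwork:
    """Mini-batch SGD (momentum) on softmax cross-entropy.

    Inputs are standardized per column with training-set statistics (stored on
    the returned network); training runs for at most ``tcfg.epochs`` epochs,
    optionally stopping early when the loss has not improved for
    ``tcfg.patience`` epochs.  Fully deterministic given the configs and data.
    """
    if train_idx is None or test_idx is None:
        train_idx, test_idx = split_dataset(data, tcfg)
    X = data.matrix[train_idx]
    y = data.labels[train_idx].astype(int)
    if tcfg.batch_size > len(train_idx):
        raise ConfigurationError("batch_size exceeds the training-set size")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Xs = (X - x_mean) / x_sd

    weights, biases = initialize_network(ncfg)
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    net = TrainedNetwork(config=ncfg, weights=weights, biases=biases,
                         x_mean=x_mean, x_sd=x_sd)

    rng = np.random.default_rng(tcfg.shuffle_seed + 7919)  # batch-order stream
    n = len(y)
    onehot = np.eye(ncfg.n_outputs)[y]
    losses: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            rows = order[start:start + tcfg.batch_size]
            xb, tb = Xs[rows], onehot[rows]
            if tcfg.augment_sd > 0:
                xb = xb + tcfg.augment_sd * rng.standard_normal(xb.shape)
            scores, cache = net.forward(xb, cache=True, standardized=True)
            probs = _softmax(scores)
            eps = 1e-12
            batch_loss = -np.mean(np.sum(tb * np.log(probs + eps), axis=1))
            epoch_loss += batch_loss * len(rows)
            # backprop
            delta = (probs - tb) / len(rows)
            for l in range(len(weights) - 1, -1, -1):
                u_prev = cache.activations[l]
                gw = u_prev.T @ delta + tcfg.weight_decay * weights[l]
                gb = delta.sum(axis=0)
                if l > 0:
                    delta = (delta @ weights[l].T) * (1.0 - cache.activations[l] ** 2)
                vel_w[l] = tcfg.momentum * vel_w[l] - tcfg.learning_rate * gw
                vel_b[l] = tcfg.momentum * vel_b[l] - tcfg.learning_rate * gb
                weights[l] += vel_w[l]
                biases[l] += vel_b[l]
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(epoch)
        losses.append(epoch_loss)
        if tcfg.patience is not None:
            if epoch_loss < best - 1e-12:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= tcfg.patience:
                    break
    net.train_log = {
        "loss": losses,
        "epochs_run": len(losses),
        "init_seed": ncfg.init_seed,
        "shuffle_seed": tcfg.shuffle_seed,
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
        "pair_id": data.pair_id,
    }
    return net


def predict(net: TrainedNetwork, X: np.ndarray,
            labels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray | None]:
    """Predicted classes for each row, plus the correctness mask when true
    labels are supplied (consumed by relevance aggregation and by the
    classifier metrics)."""
    pred = net.predict(X)
    if labels is None:
        return pred, None
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != pred.shape[0]:
        raise ConfigurationError("labels length must match the number of rows")
    return pred, pred == labels
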