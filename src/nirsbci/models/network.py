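"""Build and train the fully connected and convolutional classifiers."""

from __future__ import annotations

import numpy as np

from ..core_io import CLASSES, TrialSet
from .nn import (
    Conv1dSame,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    Network,
    ReLU,
    train_network,
)
from .specs import ANNSpec, CNNSpec, TrainConfig, cnn_shape_propagation


def _encode_labels(labels) -> tuple[np.ndarray, tuple[str, ...]]:
    order = {c: i for i, c in enumerate(CLASSES)}
    classes = tuple(sorted(set(labels), key=lambda l: (order.get(l, len(order)), l)))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels]), classes


class NeuralClassifier:
    """Trained network plus label vocabulary and expected input shape."""

    def __init__(self, net: Network, classes: tuple[str, ...],
                 input_shape: tuple[int, ...], loss_history: list[float]):
        self.net = net
        self.classes_ = classes
        self.input_shape = input_shape
        self.loss_history = loss_history

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match the training "
                f"shape {self.input_shape}"
            )
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._check(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.array([self.classes_[i] for i in
                         self.predict_proba(x).argmax(axis=1)])


def build_ann(spec: ANNSpec, n_features: int, seed: int = 0) -> Network:
    """Fully connected net: hidden ReLU layers then a linear softmax head."""
    rng = np.random.default_rng(seed)
    layers = []
    prev = n_features
    for width in spec.hidden_layers:
        layers += [Dense(prev, width, rng), ReLU()]
        prev = width
    layers.append(Dense(prev, spec.output_classes, rng))
    return Network(layers)


def train_ann(features: np.ndarray, labels, spec: ANNSpec,
              config: TrainConfig) -> NeuralClassifier:
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be (n_trials, n_features)")
    y_idx, classes = _encode_labels(labels)
    net = build_ann(spec, x.shape[1], seed=config.seed)
    history = train_network(net, x, y_idx, config)
    return NeuralClassifier(net, classes, x.shape[1:], history)


def build_cnn(spec: CNNSpec, input_shape: tuple[int, int], seed: int = 0
              ) -> Network:
    """Convolutional blocks (conv/ReLU, max-pool, dropout) then FC head.

    The flattened width entering the first fully connected layer is taken
    from the spec's shape propagation; an input on which the propagation
    collapses raises :class:`ArchitectureError` with the per-layer table.
    """
    rows = cnn_shape_propagation(spec, input_shape)  # raises if degenerate
    rng = np.random.default_rng(seed)
    m, c = input_shape
    layers: list = []
    for n_filt in spec.conv_filters:
        layers += [Conv1dSame(c, n_filt, spec.kernel_size, rng), ReLU(),
                   MaxPool1d(spec.pool_size), Dropout(spec.dropout_rate)]
        c = n_filt
        m //= spec.pool_size
    layers.append(Flatten())
    prev = m * c
    for width in spec.fc_widths:
        layers += [Dense(prev, width, rng), ReLU()]
        prev = width
    layers.append(Dense(prev, spec.output_classes, rng))
    net = Network(layers)
    net.shape_propagation = rows
    return net


def train_cnn(trials: TrialSet | np.ndarray, labels, spec: CNNSpec,
              config: TrainConfig) -> NeuralClassifier:
    x = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials, float)
    if x.ndim != 3:
        raise ValueError("trials must be (n_trials, time, channels)")
    y_idx, classes = _encode_labels(labels)
    net = build_cnn(spec, x.shape[1:], seed=config.seed)  # ArchitectureError on bad shape
    history = train_network(net, x, y_idx, config)
    return NeuralClassifier(net, classes, x.shape[1:], history)
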