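"""Declarative model structures and training hyperparameters.

The named ANN/CNN structures and the hyperparameter value sets mirror the
configurations evaluated in this pipeline's reference experiments: ANNs
with one or two fully connected hidden layers, CNNs with one or three
convolutional blocks (kernel 3, max-pool 2, dropout 0.5) feeding
256 -> 128 -> 3 fully connected layers.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..exceptions import ArchitectureError

#: Named fully connected structures (hidden-layer widths).
ANN_STRUCTURES: dict[str, tuple[int, ...]] = {
    "ANN1-a": (128,),
    "ANN1-b": (256,),
    "ANN1-c": (512,),
    "ANN2-a": (256, 128),
    "ANN2-b": (512, 256),
    "ANN2-c": (512, 128),
}

#: Named convolutional structures (filters per convolutional layer).
CNN_STRUCTURES: dict[str, tuple[int, ...]] = {
    "CNN1-a": (32,),
    "CNN1-b": (64,),
    "CNN2-a": (32, 32, 32),
    "CNN2-b": (64, 64, 64),
}

#: The printed Adam beta2 of 0.1 cripples second-moment smoothing and is a
#: likely typo; the default below is the standard 0.999, with this constant
#: available to restore the printed value (e.g. via the CLI --paper-adam).
PAPER_ADAM_BETA2 = 0.1


@dataclass(frozen=True)
class SVMSpec:
    c_regularization: float = 1.0
    n_components: int = 20

    def __post_init__(self):
        if self.c_regularization <= 0:
            raise ValueError("C must be > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass(frozen=True)
class ANNSpec:
    hidden_layers: tuple[int, ...] = (256, 128)
    activation: str = "relu"
    output_classes: int = 3

    def __post_init__(self):
        object.__setattr__(self, "hidden_layers", tuple(int(w) for w in self.hidden_layers))
        if any(w < 1 for w in self.hidden_layers) or not self.hidden_layers:
            raise ValueError("all hidden-layer widths must be positive")
        if self.activation != "relu":
            raise ValueError("only 'relu' hidden activation is supported")
        if self.output_classes < 2:
            raise ValueError("need at least two output classes")

    @classmethod
    def named(cls, name: str) -> "ANNSpec":
        return cls(hidden_layers=ANN_STRUCTURES[name])


@dataclass(frozen=True)
class CNNSpec:
    conv_filters: tuple[int, ...] = (32,)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.5
    fc_widths: tuple[int, ...] = (256, 128)
    output_classes: int = 3

    def __post_init__(self):
        object.__setattr__(self, "conv_filters", tuple(int(f) for f in self.conv_filters))
        object.__setattr__(self, "fc_widths", tuple(int(w) for w in self.fc_widths))
        if not self.conv_filters or any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be non-empty positive ints")
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ValueError("kernel_size and pool_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def named(cls, name: str) -> "CNNSpec":
        return cls(conv_filters=CNN_STRUCTURES[name])


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")


def cnn_shape_propagation(
    spec: CNNSpec, input_shape: tuple[int, int]
) -> list[tuple[str, tuple[int, ...], tuple[int, ...]]]:
    """Per-layer (name, input size, output size) for a (time, channel) input.

    Convolutions are length-preserving (zero 'same' padding, stride 1);
    max-pooling floor-divides the temporal length, dropping any orphan
    final element (257 -> 128 with kernel 2).
    """
    m, c = input_shape
    rows: list[tuple[str, tuple[int, ...], tuple[int, ...]]] = []
    for i, n_filt in enumerate(spec.conv_filters, start=1):
        rows.append((f"Convolutional layer {i}", (m, c), (m, n_filt)))
        c = n_filt
        m_out = m // spec.pool_size
        if m_out < 1:
            raise ArchitectureError(
                f"temporal length collapses to {m_out} at max-pooling {i}; "
                f"propagation so far: {rows}"
            )
        rows.append((f"Max-pooling {i}", (m, c), (m_out, c)))
        m = m_out
        rows.append((f"Dropout {i}", (m, c), (m, c)))
    flat = m * c
    prev = flat
    for i, w in enumerate(spec.fc_widths, start=1):
        rows.append((f"Fully connected layer {i}", (prev,), (w,)))
        prev = w
    rows.append(("Output layer", (prev,), (spec.output_classes,)))
    return rows
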