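"""Feature-space visualization and convolutional-filter channel attribution.

``pca_scatter`` projects any per-trial representation (raw flattened
signal, conventional feature vectors, or first-layer feature maps) onto
its top two variance components for plotting.

``filter_channel_attribution`` inspects the first convolutional layer of a
trained CNN: each filter's weights are averaged over the kernel (time)
dimension to one weight per input channel, the argmax channel is selected,
and that channel's trace is pulled out of every trial — the channel the
filter has learned to emphasize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core_io import TrialSet
from .features import FeatureTable
from .models import NeuralClassifier
from .models.nn import Conv1dSame


def _as_matrix(inputs) -> np.ndarray:
    if isinstance(inputs, FeatureTable):
        return inputs.values
    if isinstance(inputs, TrialSet):
        return inputs.trials.reshape(inputs.n_trials, -1)  # row-major flatten
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    return x


def pca_scatter(inputs, labels) -> tuple[np.ndarray, tuple[str, ...]]:
    """Top-2 principal-component coordinates per sample, with labels."""
    x = _as_matrix(inputs)
    labels = tuple(labels)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match the number of samples")
    nondegenerate = int(np.sum(x.std(axis=0) > 0))
    if x.shape[1] < 2 or nondegenerate < 2:
        raise ValueError("need at least two non-degenerate dimensions")
    coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    return coords, labels


def first_layer_feature_maps(classifier: NeuralClassifier,
                             trials: TrialSet | np.ndarray) -> np.ndarray:
    """Post-ReLU output of the first convolutional layer, (n, M, F)."""
    conv = _first_conv(classifier)
    x = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials, float)
    return np.maximum(conv.forward(x, train=False, rng=None), 0.0)


@dataclass
class AttributionResult:
    filter_id: int
    channel_weights: np.ndarray  # one averaged weight per input channel
    selected_channel: int  # 0-based argmax column of the trial matrices
    per_sample_traces: np.ndarray  # (n_trials, M)


def _first_conv(classifier: NeuralClassifier) -> Conv1dSame:
    if not isinstance(classifier, NeuralClassifier):
        raise TypeError("attribution requires a trained neural classifier")
    first = classifier.net.layers[0]
    if not isinstance(first, Conv1dSame):
        raise TypeError("first layer is not a time-convolution layer")
    return first


def filter_channel_attribution(
    classifier: NeuralClassifier,
    trials: TrialSet | np.ndarray,
    use_abs: bool = False,
) -> list[AttributionResult]:
    """Averaged-column channel weights and selected traces per first-layer filter.

    ``use_abs`` averages absolute weights instead of signed ones — sign
    conventions can differ after training; the signed mean is the default.
    """
    conv = _first_conv(classifier)
    x = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials, float)
    if x.ndim != 3 or x.shape[2] != conv.c_in:
        raise ValueError(
            f"trials have {x.shape[2:]} channels; the network expects {conv.c_in}"
        )
    kernel = conv.kernel  # (kernel_size, channels, filters)
    weights = np.abs(kernel).mean(axis=0) if use_abs else kernel.mean(axis=0)
    results = []
    for f in range(conv.n_filters):
        w = weights[:, f]
        sel = int(np.argmax(w))
        results.append(AttributionResult(
            filter_id=f,
            channel_weights=w.copy(),
            selected_channel=sel,
            per_sample_traces=x[:, :, sel].copy(),
        ))
    return results


def rank_filters_by_contrast(
    results: list[AttributionResult], labels
) -> list[tuple[int, float]]:
    """Filters ranked by class-conditional amplitude contrast of their traces.

    Contrast is the largest difference between a task class's mean trace
    amplitude and the rest-class mean amplitude, per filter.
    """
    labels = np.asarray(labels)
    ranked = []
    for res in results:
        amp = res.per_sample_traces.mean(axis=1)
        rest = amp[labels == "rest"].mean() if np.any(labels == "rest") else 0.0
        contrast = max(
            (amp[labels == c].mean() - rest)
            for c in set(labels.tolist()) if c != "rest"
        ) if len(set(labels.tolist())) > 1 else 0.0
        ranked.append((res.filter_id, float(contrast)))
    ranked.sort(key=lambda t: -t[1])
    return ranked
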