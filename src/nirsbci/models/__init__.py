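"""Classifier families: PCA + linear SVM, fully connected ANNs, 1-D CNNs."""

from .specs import (
    ANN_STRUCTURES,
    CNN_STRUCTURES,
    PAPER_ADAM_BETA2,
    ANNSpec,
    CNNSpec,
    SVMSpec,
    TrainConfig,
    cnn_shape_propagation,
)
from .network import (
    NeuralClassifier,
    build_ann,
    build_cnn,
    train_ann,
    train_cnn,
)
from .svm import SVMClassifier, pca_fit, pca_transform, train_svm


def predict(classifier, inputs):
    """One label per input row; dropout is disabled at inference."""
    return classifier.predict(inputs)


__all__ = [
    "ANN_STRUCTURES",
    "CNN_STRUCTURES",
    "PAPER_ADAM_BETA2",
    "ANNSpec",
    "CNNSpec",
    "SVMSpec",
    "TrainConfig",
    "cnn_shape_propagation",
    "NeuralClassifier",
    "SVMClassifier",
    "build_ann",
    "build_cnn",
    "train_ann",
    "train_cnn",
    "train_svm",
    "pca_fit",
    "pca_transform",
    "predict",
]
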