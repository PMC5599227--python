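"""PCA dimensionality reduction and the linear soft-margin SVM.

The SVM minimizes ||w||^2/2 + C * sum(hinge errors) with a linear decision
function; the three-class problem is handled one-vs-rest.  Both stages are
backed by scikit-learn behind this module's interface.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .specs import SVMSpec


def pca_fit(x: np.ndarray, n_components: int) -> PCA:
    """Fit a mean-centred top-variance projection on training rows only.

    Requests exceeding min(n_samples, n_features) are reduced with a
    warning rather than raised.
    """
    x = np.asarray(x, dtype=float)
    max_rank = min(x.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds min(n_samples, n_features)"
            f"={max_rank}; reducing", stacklevel=2,
        )
        n_components = max_rank
    return PCA(n_components=n_components, svd_solver="full").fit(x)


def pca_transform(x: np.ndarray, fitted: PCA) -> np.ndarray:
    return fitted.transform(np.asarray(x, dtype=float))


class SVMClassifier:
    def __init__(self, model: LinearSVC, classes: tuple[str, ...]):
        self._model = model
        self.classes_ = classes

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._model.predict(np.asarray(x, dtype=float))

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self._model.decision_function(np.asarray(x, dtype=float))


def train_svm(features: np.ndarray, labels, spec: SVMSpec, seed: int = 0
              ) -> SVMClassifier:
    """Train a one-vs-rest linear SVM on (already PCA-reduced) features."""
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes to train an SVM")
    model = LinearSVC(
        C=spec.c_regularization,
        loss="squared_hinge",
        dual="auto",
        max_iter=20000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny toy sets
        model.fit(x, labels)
    return SVMClassifier(model, tuple(model.classes_.tolist()))
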