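"""k-fold cross validation, grid search, and the sample-size learning curve.

All fold-dependent statistics (feature min-max scaling, PCA, model
weights) are fitted strictly on training-fold rows; the held-out fold is
only ever transformed and scored.  Folds are stratified so the 2:1:1
rest/right/left prior of the block design holds per fold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ParameterError
from .features import FeatureTable, apply_minmax, fit_minmax
from .models import (
    ANNSpec,
    CNNSpec,
    SVMSpec,
    TrainConfig,
    pca_fit,
    pca_transform,
    train_ann,
    train_cnn,
    train_svm,
)


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def stratified_kfold(labels: Sequence[str], k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample a fold id in 0..k-1.

    Each class's (shuffled) indices are dealt round-robin, continuing the
    deal across classes, so per-class counts across folds differ by at
    most one and total fold sizes differ by at most one.  ``k == n``
    degenerates to a leave-one-out partition.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of samples n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = (offset + j) % k
        offset = (offset + idx.size) % k
    return fold_of


def fold_indices(fold_of: np.ndarray, fold: int) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, test_idx) for one fold id."""
    test = np.flatnonzero(fold_of == fold)
    train = np.flatnonzero(fold_of != fold)
    return train, test


# ---------------------------------------------------------------------------
# pipelines (estimator factories with leakage-safe fit)
# ---------------------------------------------------------------------------

class SVMPipeline:
    """min-max scaling -> PCA -> one-vs-rest linear SVM on feature vectors."""

    def __init__(self, spec: SVMSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def _as_table(self, x: np.ndarray) -> FeatureTable:
        x = np.asarray(x, dtype=float)
        return FeatureTable(values=x, names=tuple(f"f{i}" for i in range(x.shape[1])))

    def fit(self, x: np.ndarray, y):
        table = self._as_table(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.minmax_ = fit_minmax(table)
            scaled = apply_minmax(table, self.minmax_).values
            self.pca_ = pca_fit(scaled, self.spec.n_components)
        self.model_ = train_svm(pca_transform(scaled, self.pca_), y,
                                self.spec, seed=self.seed)
        return self

    def _transform(self, x: np.ndarray) -> np.ndarray:
        scaled = apply_minmax(self._as_table(x), self.minmax_).values
        return pca_transform(scaled, self.pca_)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model_.predict(self._transform(x))


class ANNPipeline:
    """min-max scaling -> fully connected network on feature vectors."""

    def __init__(self, spec: ANNSpec, config: TrainConfig):
        self.spec = spec
        self.config = config

    def fit(self, x: np.ndarray, y):
        table = FeatureTable(values=np.asarray(x, float),
                             names=tuple(f"f{i}" for i in range(x.shape[1])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.minmax_ = fit_minmax(table)
            scaled = apply_minmax(table, self.minmax_).values
        self.model_ = train_ann(scaled, y, self.spec, self.config)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        table = FeatureTable(values=np.asarray(x, float),
                             names=tuple(f"f{i}" for i in range(x.shape[1])))
        return self.model_.predict(apply_minmax(table, self.minmax_).values)


class CNNPipeline:
    """1-D CNN directly on trial matrices (already scaled at recording level)."""

    def __init__(self, spec: CNNSpec, config: TrainConfig):
        self.spec = spec
        self.config = config

    def fit(self, x: np.ndarray, y):
        self.model_ = train_cnn(x, y, self.spec, self.config)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model_.predict(x)


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    k: int
    seed: int
    spec_id: str = ""
    chosen_hyperparameters: dict = field(default_factory=dict)
    failed_folds: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "k": self.k,
            "seed": self.seed,
            "spec_id": self.spec_id,
            "chosen_hyperparameters": self.chosen_hyperparameters,
            "failed_folds": list(self.failed_folds),
        }


def cross_validate(
    make_pipeline: Callable[[], object],
    x: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    seed: int = 0,
    spec_id: str = "",
    hyperparameters: dict | None = None,
) -> CVReport:
    """k-fold accuracy of a freshly constructed pipeline per fold.

    A fold whose training raises is recorded in ``failed_folds`` with a
    NaN accuracy; the mean is taken over the successful folds.
    """
    y = np.asarray(y)
    fold_of = stratified_kfold(y, k, seed)
    accs: list[float] = []
    failed: list[int] = []
    for fold in range(k):
        train_idx, test_idx = fold_indices(fold_of, fold)
        try:
            est = make_pipeline()
            est.fit(x[train_idx], y[train_idx])
            pred = est.predict(x[test_idx])
            accs.append(float(np.mean(pred == y[test_idx])))
        except Exception:
            accs.append(float("nan"))
            failed.append(fold)
    ok = [a for a in accs if np.isfinite(a)]
    mean = float(np.mean(ok)) if ok else float("nan")
    return CVReport(
        fold_accuracies=tuple(accs),
        mean_accuracy=mean,
        k=k,
        seed=seed,
        spec_id=spec_id,
        chosen_hyperparameters=dict(hyperparameters or {}),
        failed_folds=tuple(failed),
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter value sets; the epoch/batch/lr sets are the values
    that appear across the per-subject tuning tables, the SVM grids are
    package defaults."""

    epochs_grid: tuple[int, ...] = (20, 50, 100)
    batch_grid: tuple[int, ...] = (16, 32, 64)
    lr_grid: tuple[float, ...] = (0.0001, 0.0005, 0.001)
    svm_c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    pca_components_grid: tuple[int, ...] = (2, 5, 10, 20, 50, 100, 200)

    def __post_init__(self):
        for name in ("epochs_grid", "batch_grid", "lr_grid",
                     "svm_c_grid", "pca_components_grid"):
            if not getattr(self, name):
                raise ParameterError(f"{name} must be non-empty")


@dataclass
class GridSearchResult:
    best_hyperparameters: dict
    best_report: CVReport
    reports: tuple[CVReport, ...]


def grid_search(
    spec: SVMSpec | ANNSpec | CNNSpec,
    grid: GridSpec,
    x: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    seed: int = 0,
    base_config: TrainConfig | None = None,
) -> GridSearchResult:
    """Exhaustive k-fold evaluation of every grid point; argmax mean accuracy.

    Grid points are visited in tie-break priority order — (fewer epochs,
    smaller batch, lower learning rate) for the networks, (fewer PCA
    components, smaller C) for the SVM — and ties keep the earlier point.
    """
    base_config = base_config or TrainConfig()
    points: list[dict] = []
    if isinstance(spec, SVMSpec):
        for n_comp, c in itertools.product(
            sorted(grid.pca_components_grid), sorted(grid.svm_c_grid)
        ):
            points.append({"n_components": n_comp, "c_regularization": c})
    else:
        for epochs, batch, lr in itertools.product(
            sorted(grid.epochs_grid), sorted(grid.batch_grid), sorted(grid.lr_grid)
        ):
            points.append({"epochs": epochs, "batch_size": batch,
                           "learning_rate": lr})
    if not points:
        raise ParameterError("empty hyperparameter grid")

    reports: list[CVReport] = []
    best: CVReport | None = None
    for params in points:
        if isinstance(spec, SVMSpec):
            pt_spec = SVMSpec(**params)
            factory = lambda s=pt_spec: SVMPipeline(s, seed=seed)
            spec_id = f"svm(p={params['n_components']},C={params['c_regularization']})"
        else:
            cfg = TrainConfig(
                epochs=params["epochs"], batch_size=params["batch_size"],
                learning_rate=params["learning_rate"],
                adam_beta1=base_config.adam_beta1,
                adam_beta2=base_config.adam_beta2,
                adam_eps=base_config.adam_eps, seed=seed,
            )
            if isinstance(spec, ANNSpec):
                factory = lambda s=spec, c=cfg: ANNPipeline(s, c)
                spec_id = f"ann{spec.hidden_layers}{tuple(params.values())}"
            else:
                factory = lambda s=spec, c=cfg: CNNPipeline(s, c)
                spec_id = f"cnn{spec.conv_filters}{tuple(params.values())}"
        report = cross_validate(factory, x, np.asarray(y), k=k, seed=seed,
                                spec_id=spec_id, hyperparameters=params)
        reports.append(report)
        if best is None or (np.isfinite(report.mean_accuracy)
                            and report.mean_accuracy > best.mean_accuracy):
            best = report
    return GridSearchResult(
        best_hyperparameters=dict(best.chosen_hyperparameters),
        best_report=best,
        reports=tuple(reports),
    )


# ---------------------------------------------------------------------------
# learning curve
# ---------------------------------------------------------------------------

def learning_curve(
    make_pipeline: Callable[[], object],
    x: np.ndarray,
    y: Sequence[str],
    sizes: Sequence[int],
    k: int = 10,
    seed: int = 0,
    repeats: int = 3,
) -> dict[int, float]:
    """Mean k-fold accuracy per stratified subsample size, averaged over repeats.

    Subsamples preserve the full-data class ratio.  Sizes too small for a
    stratified k-fold are skipped with a warning.
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    y = np.asarray(y)
    n = y.shape[0]
    classes = sorted(set(y.tolist()))
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for size in sizes:
        if size > n:
            raise ParameterError(f"size {size} exceeds n={n}")
        per_class = {c: max(1, int(round(size * np.mean(y == c)))) for c in classes}
        if size < k or min(per_class.values()) < 1:
            warnings.warn(f"size {size} too small for stratified {k}-fold; skipped")
            continue
        accs = []
        for rep in range(repeats):
            if size == n:
                sub = np.arange(n)  # full data: reduces to plain cross_validate
            else:
                sub = np.concatenate([
                    rng.choice(np.flatnonzero(y == c), size=per_class[c],
                               replace=False)
                    for c in classes
                ])
            fold_seed = seed if rep == 0 else int(rng.integers(2 ** 31))
            report = cross_validate(make_pipeline, x[sub], y[sub], k=k,
                                    seed=fold_seed)
            accs.append(report.mean_accuracy)
        out[int(size)] = float(np.mean(accs))
    return out
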