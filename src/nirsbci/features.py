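"""Conventional time-domain features and the per-trial feature table.

Six statistics per trace — mean, variance, kurtosis, skewness, peak,
slope — computed for the HbO and HbR trace of every channel give a
6 x 2 x N_channels vector per trial (408 dimensions for 34 channels).

Moment conventions: variance, kurtosis and skewness use the population
divisor N and kurtosis is non-excess (a Gaussian scores 3).  Peak is the
maximum of the signed trace; slope is the ordinary-least-squares slope of
the trace against sample index (per-sample units — time rescaling only
rescales the feature and is absorbed by min-max normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core_io import TrialSet
from .exceptions import DegenerateInputError

FEATURE_ORDER = ("mean", "variance", "kurtosis", "skewness", "peak", "slope")
CHROMOPHORES = ("hbo", "hbr")


class StatFeatures(NamedTuple):
    mean: float
    variance: float
    kurtosis: float
    skewness: float
    peak: float
    slope: float


def stat_features(x: np.ndarray) -> StatFeatures:
    """The six per-trace statistics (see module docstring for conventions)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    n = x.size
    mu = x.sum() / n
    dev = x - mu
    var = (dev ** 2).sum() / n
    if var == 0:
        raise DegenerateInputError(
            "kurtosis and skewness are undefined for a constant trace"
        )
    kurt = (dev ** 4).sum() / n / var ** 2
    skew = (dev ** 3).sum() / n / var ** 1.5
    peak = x.max()
    idx = np.arange(n, dtype=float)
    slope = ((idx - idx.mean()) * dev).sum() / ((idx - idx.mean()) ** 2).sum()
    return StatFeatures(mu, var, kurt, skew, peak, slope)


def _stat_features_block(block: np.ndarray) -> np.ndarray:
    """Vectorized stat_features over columns of an (n, c) block -> (6, c)."""
    n = block.shape[0]
    mu = block.mean(axis=0)
    dev = block - mu
    var = (dev ** 2).mean(axis=0)
    if np.any(var == 0):
        bad = int(np.flatnonzero(var == 0)[0])
        raise DegenerateInputError(f"constant trace in column {bad}")
    kurt = (dev ** 4).mean(axis=0) / var ** 2
    skew = (dev ** 3).mean(axis=0) / var ** 1.5
    peak = block.max(axis=0)
    idx = np.arange(n, dtype=float)
    ic = idx - idx.mean()
    slope = (ic[:, None] * dev).sum(axis=0) / (ic ** 2).sum()
    return np.stack([mu, var, kurt, skew, peak, slope])


@dataclass
class FeatureTable:
    """Per-trial feature matrix with parallel column names and labels."""

    values: np.ndarray  # (n_trials, n_features)
    names: tuple[str, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n_trials, len(names))")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length must match the number of trials")


def feature_names(n_channels: int) -> tuple[str, ...]:
    """Canonical (feature x chromophore x channel) name ordering."""
    return tuple(
        f"{feat}_{chrom}_ch{k}"
        for feat in FEATURE_ORDER
        for chrom in CHROMOPHORES
        for k in range(1, n_channels + 1)
    )


def extract_feature_table(trials: TrialSet) -> FeatureTable:
    """One 6 x 2 x N_channels feature vector per trial.

    Trial columns are interpreted as the HbO channel block followed by the
    HbR channel block, matching :func:`nirsbci.core_io.segment_trials`.
    """
    n_trials, m, n_cols = trials.trials.shape
    if n_cols % 2:
        raise ValueError("trial matrices must have an even channel count (HbO|HbR)")
    n_ch = n_cols // 2
    names = feature_names(n_ch)
    values = np.empty((n_trials, len(names)))
    for i in range(n_trials):
        try:
            feats = _stat_features_block(trials.trials[i])  # (6, 2*n_ch)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"trial {i}: {exc}") from exc
        # block columns are already [hbo ch1..chN, hbr ch1..chN]; the
        # canonical ordering is feature-major over that same column order
        values[i] = feats.reshape(-1)
    return FeatureTable(values=values, names=names, labels=trials.labels)


@dataclass
class MinMaxStats:
    """Per-column training minima/maxima for (0,1) scaling."""

    col_min: np.ndarray
    col_max: np.ndarray


def fit_minmax(table: FeatureTable) -> MinMaxStats:
    """Fit per-feature min/max on (training) rows only."""
    col_min = table.values.min(axis=0)
    col_max = table.values.max(axis=0)
    if np.any(col_max == col_min):
        warnings.warn(
            "constant feature column(s) map to 0.5 under min-max scaling",
            stacklevel=2,
        )
    return MinMaxStats(col_min=col_min, col_max=col_max)


def apply_minmax(table: FeatureTable, fitted: MinMaxStats) -> FeatureTable:
    """Scale to [0,1] with the fitted statistics; out-of-range values clip."""
    span = fitted.col_max - fitted.col_min
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (table.values - fitted.col_min) / span
    scaled = np.where(span == 0, 0.5, scaled)
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureTable(values=scaled, names=table.names, labels=table.labels)
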