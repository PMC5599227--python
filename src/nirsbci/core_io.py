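"""Data model, delimited-text readers/writers, and trial segmentation.

File dialect
------------
Records are stored as UTF-8 comma-separated matrices, one row per time
sample, with a header row naming the channels:

* hemodynamic records: ``hbo_ch1, ..., hbo_chN, hbr_ch1, ..., hbr_chN``
* optical-density records: ``od_ch<k>_<wavelength>nm`` ordered channel-major
  (all wavelengths of channel 1, then channel 2, ...).

A JSON sidecar with the same stem and ``.json`` extension carries the
sampling rate and channel layout (and wavelengths for optical-density
files).  Time is row-major: ``seconds = row / fs_hz`` with 0-based rows,
and segments are half-open intervals ``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import BoundsError, InputFormatError

#: Class labels, in the fixed order used throughout the package.
CLASSES = ("rest", "right", "left")

_HEMISPHERES = ("C3", "C4")


def _round_half_away(x: float) -> int:
    """Round half away from zero (10 * 25.7 = 257 exactly, so unambiguous here)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel ids with their hemisphere assignment.

    The default 34-channel montage maps channels 1-17 over the right motor
    area (C4) and 18-34 over the left motor area (C3).
    """

    channel_ids: tuple[int, ...]
    hemisphere_of: dict[int, str]
    source_detector_distance_cm: float = 3.0

    def __post_init__(self):
        ids = tuple(int(c) for c in self.channel_ids)
        object.__setattr__(self, "channel_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        if set(self.hemisphere_of) != set(ids):
            raise ValueError("every channel must be mapped to exactly one hemisphere")
        for ch, hemi in self.hemisphere_of.items():
            if hemi not in _HEMISPHERES:
                raise ValueError(f"unknown hemisphere {hemi!r} for channel {ch}")
        if self.source_detector_distance_cm <= 0:
            raise ValueError("source-detector distance must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def channels_over(self, hemisphere: str) -> tuple[int, ...]:
        """Channel ids placed over the given hemisphere ('C3' or 'C4')."""
        return tuple(c for c in self.channel_ids if self.hemisphere_of[c] == hemisphere)


def default_layout(n_channels: int = 34) -> ChannelLayout:
    """Standard montage: first half of the channels over C4, second half over C3."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    ids = tuple(range(1, n_channels + 1))
    split = (n_channels + 1) // 2
    hemi = {c: ("C4" if c <= split else "C3") for c in ids}
    return ChannelLayout(channel_ids=ids, hemisphere_of=hemi)


def _check_matrix(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D time x channel matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class HemodynamicRecord:
    """Continuous concentration-change matrices (time x channel) for HbO and HbR."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs_hz: float
    layout: ChannelLayout

    def __post_init__(self):
        self.hbo = _check_matrix("hbo", self.hbo)
        self.hbr = _check_matrix("hbr", self.hbr)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shapes")
        if self.hbo.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"matrix has {self.hbo.shape[1]} channels but layout has "
                f"{self.layout.n_channels}"
            )
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class OpticalDensityRecord:
    """Per-wavelength optical-density changes, columns ordered channel-major."""

    od: np.ndarray
    wavelengths_nm: tuple[float, ...]
    fs_hz: float
    layout: ChannelLayout

    def __post_init__(self):
        self.od = _check_matrix("od", self.od)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if len(self.wavelengths_nm) < 2:
            raise ValueError("need at least two wavelengths")
        if any(w <= 0 for w in self.wavelengths_nm):
            raise ValueError("wavelengths must be positive")
        expected = self.layout.n_channels * len(self.wavelengths_nm)
        if self.od.shape[1] != expected:
            raise ValueError(
                f"od has {self.od.shape[1]} columns, expected "
                f"{expected} (channels x wavelengths)"
            )
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    def as_cube(self) -> np.ndarray:
        """Return the OD matrix reshaped to (time, channel, wavelength)."""
        n_wl = len(self.wavelengths_nm)
        return self.od.reshape(self.od.shape[0], self.layout.n_channels, n_wl)


@dataclass
class TrialSet:
    """Segmented task blocks: trial matrices M x 2N ([HbO block | HbR block])."""

    trials: np.ndarray
    labels: tuple[str, ...]
    fs_hz: float
    block_duration_s: float = 10.0

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = tuple(str(l) for l in self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be a 3-D array (trial, time, channel)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("len(trials) must equal len(labels)")
        for lab in self.labels:
            if lab not in CLASSES:
                raise ValueError(f"unknown label {lab!r}; expected one of {CLASSES}")
        if not self.fs_hz > 0 or not self.block_duration_s > 0:
            raise ValueError("fs_hz and block_duration_s must be positive")
        if self.trials.shape[0] > 0:
            m_expected = _round_half_away(self.block_duration_s * self.fs_hz)
            if self.trials.shape[1] != m_expected:
                raise ValueError(
                    f"trials have {self.trials.shape[1]} rows, expected "
                    f"round(duration x fs) = {m_expected}"
                )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.trials.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {c: sum(1 for l in self.labels if l == c) for c in CLASSES}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _layout_to_json(layout: ChannelLayout) -> dict:
    return {
        "channel_ids": list(layout.channel_ids),
        "hemisphere_of": {str(k): v for k, v in layout.hemisphere_of.items()},
        "source_detector_distance_cm": layout.source_detector_distance_cm,
    }


def _layout_from_json(obj: dict) -> ChannelLayout:
    return ChannelLayout(
        channel_ids=tuple(int(c) for c in obj["channel_ids"]),
        hemisphere_of={int(k): v for k, v in obj["hemisphere_of"].items()},
        source_detector_distance_cm=float(
            obj.get("source_detector_distance_cm", 3.0)
        ),
    )


def write_record(
    record: HemodynamicRecord | OpticalDensityRecord, path: str | Path
) -> Path:
    """Write a record as CSV plus a JSON sidecar; returns the CSV path.

    Values are written at 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    path = Path(path)
    if record.layout.n_channels == 0:
        raise ValueError("record has no channels")
    sidecar = {"fs_hz": record.fs_hz, "layout": _layout_to_json(record.layout)}
    if isinstance(record, HemodynamicRecord):
        cols = [f"hbo_ch{c}" for c in record.layout.channel_ids] + [
            f"hbr_ch{c}" for c in record.layout.channel_ids
        ]
        data = np.hstack([record.hbo, record.hbr])
        sidecar["kind"] = "hemodynamic"
    elif isinstance(record, OpticalDensityRecord):
        cols = [
            f"od_ch{c}_{_fmt_wl(w)}nm"
            for c in record.layout.channel_ids
            for w in record.wavelengths_nm
        ]
        data = record.od
        sidecar["kind"] = "optical_density"
        sidecar["wavelengths_nm"] = list(record.wavelengths_nm)
    else:
        raise TypeError(f"unsupported record type {type(record).__name__}")
    df = pd.DataFrame(data, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _fmt_wl(w: float) -> str:
    return f"{w:g}"


def read_record(
    path: str | Path, kind: Literal["hemodynamic", "optical_density"] = "hemodynamic"
) -> HemodynamicRecord | OpticalDensityRecord:
    """Read a CSV record and its JSON sidecar back into a validated object.

    Column order is normalized to ascending channel id with the HbO block
    before the HbR block (or channel-major wavelength order for OD files).
    """
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not path.exists():
        raise InputFormatError(f"record file not found: {path}")
    if not sidecar_file.exists():
        raise InputFormatError(f"sidecar metadata not found: {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    layout = _layout_from_json(meta["layout"])
    fs_hz = float(meta["fs_hz"])

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise InputFormatError(f"{path}: missing or incomplete header row")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise InputFormatError(f"{path}: non-numeric cell in column {col!r}")
        if df[col].isna().any():
            raise InputFormatError(f"{path}: missing value in column {col!r}")

    if kind == "hemodynamic":
        wanted = [f"hbo_ch{c}" for c in layout.channel_ids] + [
            f"hbr_ch{c}" for c in layout.channel_ids
        ]
    elif kind == "optical_density":
        wls = tuple(float(w) for w in meta["wavelengths_nm"])
        wanted = [
            f"od_ch{c}_{_fmt_wl(w)}nm" for c in layout.channel_ids for w in wls
        ]
    else:
        raise ValueError(f"unknown record kind {kind!r}")

    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{path}: expected column {missing[0]!r} not found "
            f"(channel count mismatch with sidecar layout?)"
        )
    data = df[wanted].to_numpy(dtype=float)

    if kind == "hemodynamic":
        n = layout.n_channels
        return HemodynamicRecord(
            hbo=data[:, :n], hbr=data[:, n:], fs_hz=fs_hz, layout=layout
        )
    return OpticalDensityRecord(
        od=data, wavelengths_nm=wls, fs_hz=fs_hz, layout=layout
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_trials(
    record: HemodynamicRecord,
    onsets_s: Sequence[float],
    labels: Sequence[str],
    block_duration_s: float = 10.0,
) -> TrialSet:
    """Cut 10-s task blocks out of a continuous record.

    Each trial matrix has ``M = round(block_duration_s * fs_hz)`` rows and
    ``2N`` columns (the HbO channel block followed by the HbR channel
    block); labels are preserved in onset order.
    """
    if len(onsets_s) != len(labels):
        raise ValueError("onsets and labels must have the same length")
    m = _round_half_away(block_duration_s * record.fs_hz)
    n_ch = record.n_channels
    trials = np.empty((len(onsets_s), m, 2 * n_ch))
    for i, onset in enumerate(onsets_s):
        start = _round_half_away(float(onset) * record.fs_hz)
        if start < 0 or start + m > record.n_samples:
            raise BoundsError(
                f"block at onset {onset} s (rows {start}..{start + m}) overruns "
                f"the record ({record.n_samples} rows)"
            )
        trials[i, :, :n_ch] = record.hbo[start : start + m]
        trials[i, :, n_ch:] = record.hbr[start : start + m]
    return TrialSet(
        trials=trials,
        labels=tuple(labels),
        fs_hz=record.fs_hz,
        block_duration_s=block_duration_s,
    )
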