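"""Wavelet multiresolution analysis, band-limited reconstruction, scaling.

The continuous recording is decomposed with an orthonormal Daubechies
wavelet (default db5, 10 levels) into time-domain components

    S[n] = a_J[n] + sum_j d_j[n],

each component the inverse transform of a single level's coefficients with
all other levels zeroed.  Physiological noise is removed by keeping only
the detail levels whose nominal dyadic band (fs/2^{j+1}, fs/2^j) covers
the hemodynamic response — d8 + d9 at fs = 25.7 Hz, i.e. ~0.025-0.1 Hz —
and the filtered signal is then mapped into [0, 1].

The transform uses periodized boundary handling: analysis is periodic
correlation with the scaling/wavelet filters followed by dyadic
downsampling, synthesis is the transposed (hence, for orthonormal filters,
inverse) operator.  Odd-length stages are extended by repeating the final
sample, which preserves additive perfect reconstruction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np

from .exceptions import DecompositionDepthError, DegenerateInputError, ParameterError

# ---------------------------------------------------------------------------
# filter construction
# ---------------------------------------------------------------------------

def daubechies_filter(p: int) -> np.ndarray:
    """Orthonormal Daubechies scaling filter with ``p`` vanishing moments.

    Built by spectral factorization of the halfband polynomial: the
    binomial polynomial P(y) = sum_k C(p-1+k, k) y^k is rooted, each root
    is mapped to the z-plane via y = (2 - z - 1/z)/4, and the minimum-phase
    (inside-unit-circle) factors are kept.  Length 2p, sum sqrt(2).
    """
    if p < 1:
        raise ParameterError("order must be >= 1")
    if p == 1:
        return np.array([1.0, 1.0]) / sqrt(2.0)
    qp = np.array([comb(p - 1 + k, k) for k in range(p)], dtype=float)
    yroots = np.roots(qp[::-1])
    zroots = []
    for y in yroots:
        # y = (2 - z - 1/z)/4  <=>  z^2 + (4y - 2) z + 1 = 0
        r = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        zroots.append(r[np.argmin(np.abs(r))])
    h = np.real(np.poly([-1.0] * p + list(zroots)))
    h *= sqrt(2.0) / h.sum()
    # orient so energy is front-loaded (extremal-phase convention)
    if np.sum(h[:p] ** 2) < np.sum(h[p:] ** 2):
        h = h[::-1]
    return h


_DB_RE = re.compile(r"^db(\d+)$")


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (scaling filter h, wavelet filter g) for an orthogonal wavelet.

    Supported names: ``haar`` and ``db1`` ... ``db20``.  The quadrature
    mirror is g[m] = (-1)^m h[L-1-m].
    """
    name = name.lower()
    if name == "haar":
        h = daubechies_filter(1)
    else:
        m = _DB_RE.match(name)
        if not m or not 1 <= int(m.group(1)) <= 20:
            raise ParameterError(f"unknown or unsupported orthogonal wavelet {name!r}")
        h = daubechies_filter(int(m.group(1)))
    sign = (-1.0) ** np.arange(h.size)
    g = sign * h[::-1]
    return h, g


# ---------------------------------------------------------------------------
# periodized DWT machinery (time on axis 0; trailing axes carried along)
# ---------------------------------------------------------------------------

def _analysis_step(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """c[k] = sum_m f[m] x[(2k + m) mod n] for even n."""
    out = None
    for m, fm in enumerate(f):
        term = fm * np.roll(x, -m, axis=0)[::2]
        out = term if out is None else out + term
    return out


def _synthesis_step(ca: np.ndarray, cd: np.ndarray, h: np.ndarray, g: np.ndarray
                    ) -> np.ndarray:
    """Transpose of the analysis step: x[i] = sum_k ca[k] h[(i-2k)%n] + ..."""
    n = 2 * ca.shape[0]
    up_a = np.zeros((n,) + ca.shape[1:], dtype=float)
    up_d = np.zeros_like(up_a)
    up_a[::2] = ca
    up_d[::2] = cd
    out = np.zeros_like(up_a)
    for m in range(h.size):
        out += h[m] * np.roll(up_a, m, axis=0)
        out += g[m] * np.roll(up_d, m, axis=0)
    return out


def _wavedec(x: np.ndarray, h: np.ndarray, g: np.ndarray, levels: int
             ) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    """Decompose to (a_J, [d_1..d_J] coefficient arrays, input length per level)."""
    a = x
    details: list[np.ndarray] = []
    lens: list[int] = []
    for _ in range(levels):
        n = a.shape[0]
        lens.append(n)
        if n % 2:
            a = np.concatenate([a, a[-1:]], axis=0)
        details.append(_analysis_step(a, g))
        a = _analysis_step(a, h)
    return a, details, lens


def _inverse_from(coeff_a: np.ndarray | None,
                  coeff_details: dict[int, np.ndarray],
                  levels: int, lens: list[int],
                  h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Single inverse pass using only the provided coefficient arrays."""
    template_shape = next(iter(coeff_details.values())).shape[1:] if coeff_details \
        else coeff_a.shape[1:]
    n_top = (lens[-1] + 1) // 2
    x = coeff_a if coeff_a is not None else np.zeros((n_top,) + template_shape)
    for lev in range(levels, 0, -1):
        cd = coeff_details.get(lev)
        if cd is None:
            cd = np.zeros_like(x)
        x = _synthesis_step(x, cd, h, g)[: lens[lev - 1]]
    return x


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class WaveletConfig:
    mother: str = "db5"
    levels: int = 10
    keep_details: frozenset[int] = frozenset({8, 9})
    boundary_mode: str = "periodization"

    def __post_init__(self):
        self.keep_details = frozenset(int(k) for k in self.keep_details)
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        for k in self.keep_details:
            if not 1 <= k <= self.levels:
                raise ParameterError(
                    f"kept detail level {k} outside 1..{self.levels}"
                )
        if self.boundary_mode != "periodization":
            raise ParameterError(
                f"unsupported boundary mode {self.boundary_mode!r} "
                "(only 'periodization' is implemented)"
            )
        wavelet_filters(self.mother)  # validates the name


@dataclass
class MRADecomposition:
    """Additive per-level components: input = approximation + sum(details)."""

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]  # details[j-1] is level j

    @property
    def levels(self) -> int:
        return len(self.details)

    def detail(self, level: int) -> np.ndarray:
        if not 1 <= level <= self.levels:
            raise KeyError(f"detail level {level} not in 1..{self.levels}")
        return self.details[level - 1]


def _check_depth(n: int, levels: int) -> None:
    if n < 2 ** levels:
        raise DecompositionDepthError(
            f"signal length {n} too short for a {levels}-level decomposition; "
            f"need at least {2 ** levels} samples"
        )


def mra_decompose(signal: np.ndarray, config: WaveletConfig | None = None
                  ) -> MRADecomposition:
    """Full multiresolution analysis of a signal (1-D, or 2-D time x channel).

    Each returned component has the length of the input, and the components
    sum back to the input to floating-point accuracy.
    """
    config = config or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    _check_depth(x.shape[0], config.levels)
    h, g = wavelet_filters(config.mother)
    ca, cds, lens = _wavedec(x, h, g, config.levels)
    approx = _inverse_from(ca, {}, config.levels, lens, h, g)
    details = tuple(
        _inverse_from(None, {lev: cds[lev - 1]}, config.levels, lens, h, g)
        for lev in range(1, config.levels + 1)
    )
    return MRADecomposition(approximation=approx, details=details)


def band_reconstruct(decomp: MRADecomposition,
                     keep_details: set[int] | frozenset[int],
                     include_approximation: bool = False) -> np.ndarray:
    """Element-wise sum of the selected detail components (optionally + a_J)."""
    out = np.zeros_like(decomp.approximation)
    for lev in sorted(set(keep_details)):
        out = out + decomp.detail(lev)  # .detail raises KeyError if absent
    if include_approximation:
        out = out + decomp.approximation
    return out


def band_filter(signal: np.ndarray, config: WaveletConfig | None = None
                ) -> np.ndarray:
    """Decompose and reconstruct the kept detail band in one inverse pass.

    Equivalent to ``band_reconstruct(mra_decompose(x, cfg), cfg.keep_details)``
    but avoids materializing every component.
    """
    config = config or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    _check_depth(x.shape[0], config.levels)
    h, g = wavelet_filters(config.mother)
    _, cds, lens = _wavedec(x, h, g, config.levels)
    kept = {lev: cds[lev - 1] for lev in config.keep_details}
    if not kept:
        return np.zeros_like(x)
    return _inverse_from(None, kept, config.levels, lens, h, g)


def band_edges(fs_hz: float, level: int) -> tuple[float, float]:
    """Nominal dyadic band (fs/2^{level+1}, fs/2^level) of detail level d_level."""
    if level < 1:
        raise ParameterError("level must be >= 1")
    if fs_hz <= 0:
        raise ParameterError("fs_hz must be positive")
    return fs_hz / 2 ** (level + 1), fs_hz / 2 ** level


def normalize_unit_interval(signal: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean-subtract then scale/shift so each trace spans exactly [0, 1].

    (Subtracting the mean and min-max mapping commute into a single affine
    map; the result has min 0 and max 1 and preserves ordering.)
    """
    x = np.asarray(signal, dtype=float)
    centred = x - x.mean(axis=axis, keepdims=True)
    lo = centred.min(axis=axis, keepdims=True)
    hi = centred.max(axis=axis, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        raise DegenerateInputError("constant trace cannot be scaled to (0, 1)")
    return (centred - lo) / span


def denoise_record(record, config: WaveletConfig | None = None,
                   normalize: bool = True):
    """Band-filter every channel of a hemodynamic record, then rescale.

    Filtering runs on the full continuous recording (a 10-level dyadic
    decomposition needs >= 1024 samples, which single 10-s blocks cannot
    supply); segmentation into trials should happen afterwards.
    """
    from .core_io import HemodynamicRecord

    config = config or WaveletConfig()
    hbo = band_filter(record.hbo, config)
    hbr = band_filter(record.hbr, config)
    if normalize:
        hbo = normalize_unit_interval(hbo, axis=0)
        hbr = normalize_unit_interval(hbr, axis=0)
    return HemodynamicRecord(hbo=hbo, hbr=hbr, fs_hz=record.fs_hz,
                             layout=record.layout)
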