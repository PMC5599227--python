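"""Synthetic fNIRS session generator.

Produces continuous recordings with the statistical structure the pipeline
assumes: block-design motor tasks whose activated-hemisphere channels carry
a boxcar convolved with a canonical hemodynamic response (HbO up, HbR
down, contralateral — right-hand tasks activate C3 channels, left-hand
C4), superposed with sinusoidal physiological noise at the cardiac
(0.8 Hz), respiratory (0.2 Hz), Mayer-wave (0.1 Hz) and very-low-frequency
(0.03 Hz) bands plus white noise.  All randomness (component phases, white
noise) is drawn from a single seeded generator.

A forward Beer-Lambert stage converts simulated concentration changes into
per-wavelength optical densities so the inverse conversion can be
round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .core_io import (
    ChannelLayout,
    HemodynamicRecord,
    OpticalDensityRecord,
    default_layout,
)
from .exceptions import ParameterError
from .mbll import MBLLCoefficients


@dataclass(frozen=True)
class HRFParams:
    """Difference-of-gamma hemodynamic response kernel parameters.

    Defaults place the kernel peak at 6 s with a 16-s undershoot.  The
    dispersions and undershoot ratio are calibrated so that the response
    evoked by a 10-s block peaks inside the block (activation concentrated
    in the 5-10 s window) and dips back near baseline during the following
    block instead of spilling its bulk into it.
    """

    peak_time_s: float = 6.0
    undershoot_time_s: float = 16.0
    peak_dispersion_s: float = 0.5
    undershoot_dispersion_s: float = 1.8
    undershoot_ratio: float = 0.6
    amplitude_hbo: float = 1.0
    amplitude_hbr: float = -1.0 / 3.0  # typical neurovascular coupling polarity

    def __post_init__(self):
        if self.peak_time_s <= 0 or self.undershoot_time_s <= self.peak_time_s:
            raise ParameterError("need 0 < peak_time_s < undershoot_time_s")
        if self.peak_dispersion_s <= 0 or self.undershoot_dispersion_s <= 0:
            raise ParameterError("dispersions must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ParameterError("undershoot_ratio must be in [0, 1)")
        if self.amplitude_hbo < 0:
            raise ParameterError("amplitude_hbo must be >= 0")
        if self.amplitude_hbr > 0:
            raise ParameterError("amplitude_hbr must be <= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model.

    ``components`` are sinusoids (name, frequency Hz, amplitude) with
    seeded uniform random phase per channel.  ``drift_sigma`` sets the
    stationary standard deviation of an AR(1) low-frequency drift (corner
    frequency ``drift_corner_hz``) that — unlike the sinusoids, whose
    periods are commensurate with the 10-s block grid — varies from block
    to block and therefore genuinely interferes with classification.
    ``white_sigma`` is broadband Gaussian noise.
    """

    components: tuple[tuple[str, float, float], ...] = (
        ("cardiac", 0.8, 0.5),
        ("respiration", 0.2, 0.5),
        ("mayer", 0.1, 0.3),
        ("vlf", 0.03, 0.3),
    )
    white_sigma: float = 0.5
    drift_sigma: float = 2.0
    drift_corner_hz: float = 0.05

    def __post_init__(self):
        for name, freq, amp in self.components:
            if freq <= 0:
                raise ParameterError(f"{name}: frequency must be positive")
            if amp < 0:
                raise ParameterError(f"{name}: amplitude must be >= 0")
        if self.white_sigma < 0 or self.drift_sigma < 0:
            raise ParameterError("noise sigmas must be >= 0")
        if self.drift_corner_hz <= 0:
            raise ParameterError("drift_corner_hz must be positive")


#: Task label -> hemisphere whose channels carry the full response.
DEFAULT_LATERALIZATION = {"right": "C3", "left": "C4"}


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 34
    fs_hz: float = 25.7
    session_plan: tuple[str, ...] = ("rest", "right", "rest", "left")
    n_sessions: int = 5
    n_experiments: int = 10
    block_duration_s: float = 10.0
    hrf: HRFParams = field(default_factory=HRFParams)
    lateralization: tuple[tuple[str, str], ...] = (("right", "C3"), ("left", "C4"))
    ipsilateral_fraction: float = 0.2
    effect_size: float = 1.0
    #: s.d. of the multiplicative per-block response amplitude (truncated at 0);
    #: trial-to-trial hemodynamic variability
    response_jitter: float = 0.4
    #: per-channel response gain drawn uniformly from this range (spatially
    #: heterogeneous activation strength across the montage)
    channel_gain_range: tuple[float, float] = (0.3, 1.0)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")
        for name, freq, _ in self.noise.components:
            if freq >= self.fs_hz / 2:
                raise ParameterError(
                    f"noise component {name} at {freq} Hz is not below fs/2"
                )
        for lab in self.session_plan:
            if lab not in ("rest", "right", "left"):
                raise ParameterError(f"unknown block label {lab!r}")
        if self.effect_size < 0 or not 0 <= self.ipsilateral_fraction <= 1:
            raise ParameterError("effect_size >= 0 and 0 <= ipsilateral_fraction <= 1")
        if self.response_jitter < 0:
            raise ParameterError("response_jitter must be >= 0")
        lo, hi = self.channel_gain_range
        if not 0 <= lo <= hi:
            raise ParameterError("channel_gain_range must satisfy 0 <= lo <= hi")


def canonical_hrf(fs_hz: float, hrf: HRFParams | None = None) -> np.ndarray:
    """Unit-peak difference-of-gamma kernel sampled at ``fs_hz``.

    The kernel covers twice the undershoot time, peaks (to within one
    sample) at ``peak_time_s`` and has a non-negative main lobe.
    """
    hrf = hrf or HRFParams()
    if fs_hz <= 0:
        raise ParameterError("fs_hz must be positive")
    if hrf.peak_time_s * fs_hz < 2:
        raise ParameterError(
            f"sampling rate {fs_hz} Hz too low to resolve a "
            f"{hrf.peak_time_s}-s peak"
        )
    duration = 2.0 * hrf.undershoot_time_s
    t = np.arange(int(round(duration * fs_hz)) + 1) / fs_hz

    def build(peak_mode: float) -> np.ndarray:
        # gamma pdf with scale s and shape a peaks at (a - 1) * s
        main = gamma_dist.pdf(
            t, a=peak_mode / hrf.peak_dispersion_s + 1.0,
            scale=hrf.peak_dispersion_s,
        )
        under = gamma_dist.pdf(
            t, a=hrf.undershoot_time_s / hrf.undershoot_dispersion_s + 1.0,
            scale=hrf.undershoot_dispersion_s,
        )
        k = main / main.max() - hrf.undershoot_ratio * under / under.max()
        return k / k.max()

    # the undershoot subtraction drags the combined argmax slightly earlier
    # than the main lobe's mode; a couple of fixed-point corrections pin the
    # kernel peak to peak_time_s
    mode = hrf.peak_time_s
    kernel = build(mode)
    for _ in range(3):
        shift = hrf.peak_time_s - t[int(np.argmax(kernel))]
        if abs(shift) <= 0.5 / fs_hz:
            break
        mode += shift
        kernel = build(mode)
    return kernel


def _block_schedule(config: SimulationConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    """Back-to-back block onsets (s) and labels for the full design."""
    labels = tuple(
        config.session_plan[i]
        for _ in range(config.n_experiments)
        for _ in range(config.n_sessions)
        for i in range(len(config.session_plan))
    )
    onsets = np.arange(len(labels)) * config.block_duration_s
    return onsets, labels


def simulate_session(
    config: SimulationConfig | None = None,
    layout: ChannelLayout | None = None,
) -> tuple[HemodynamicRecord, np.ndarray, tuple[str, ...]]:
    """Generate one continuous recording; returns (record, onsets_s, labels)."""
    config = config or SimulationConfig()
    layout = layout or default_layout(config.n_channels)
    if layout.n_channels != config.n_channels:
        raise ParameterError("layout channel count does not match config")
    rng = np.random.default_rng(config.seed)

    onsets, labels = _block_schedule(config)
    m = int(round(config.block_duration_s * config.fs_hz))
    n_t = m * len(labels)
    t = np.arange(n_t) / config.fs_hz
    lateral = dict(config.lateralization)

    # --- evoked response: per-task boxcar convolved with the HRF kernel;
    # each task block gets a jittered multiplicative amplitude
    kernel = canonical_hrf(config.fs_hz, config.hrf)
    # scale so that a single isolated block evokes a unit-peak response
    kernel = kernel / np.convolve(np.ones(m), kernel).max()
    response = {}  # task -> (n_t,) unit-amplitude response time course
    for task in ("right", "left"):
        boxcar = np.zeros(n_t)
        for onset, lab in zip(onsets, labels):
            if lab == task:
                start = int(round(onset * config.fs_hz))
                amp = 1.0
                if config.response_jitter > 0:
                    amp = max(
                        0.0, 1.0 + config.response_jitter * rng.standard_normal()
                    )
                boxcar[start : start + m] = amp
        response[task] = np.convolve(boxcar, kernel)[:n_t]

    hemi = np.array([layout.hemisphere_of[c] for c in layout.channel_ids])
    lo, hi = config.channel_gain_range
    channel_gain = rng.uniform(lo, hi, size=config.n_channels)
    hbo = np.zeros((n_t, config.n_channels))
    hbr = np.zeros((n_t, config.n_channels))
    for task in ("right", "left"):
        gain = np.where(
            hemi == lateral[task], 1.0, config.ipsilateral_fraction
        ) * config.effect_size * channel_gain
        hbo += config.hrf.amplitude_hbo * np.outer(response[task], gain)
        hbr += config.hrf.amplitude_hbr * np.outer(response[task], gain)

    # --- physiological + drift + white noise, independent per chromophore channel
    for mat in (hbo, hbr):
        for _, freq, amp in config.noise.components:
            if amp > 0:
                phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
                mat += amp * np.sin(
                    2.0 * np.pi * freq * t[:, None] + phases[None, :]
                )
        if config.noise.drift_sigma > 0:
            rho = np.exp(-2.0 * np.pi * config.noise.drift_corner_hz / config.fs_hz)
            innovations = rng.standard_normal(mat.shape) * (
                config.noise.drift_sigma * np.sqrt(1.0 - rho ** 2)
            )
            mat += lfilter([1.0], [1.0, -rho], innovations, axis=0)
        if config.noise.white_sigma > 0:
            mat += config.noise.white_sigma * rng.standard_normal(mat.shape)

    record = HemodynamicRecord(hbo=hbo, hbr=hbr, fs_hz=config.fs_hz, layout=layout)
    return record, onsets, labels


def forward_mbll(
    record: HemodynamicRecord, coeffs: MBLLCoefficients
) -> OpticalDensityRecord:
    """Forward Beer-Lambert: dOD(lambda) = d*DPF*(eps_HbO*dHbO + eps_HbR*dHbR)."""
    a = coeffs.pathlength_matrix()  # (n_wl, 2)
    conc = np.stack([record.hbo, record.hbr], axis=-1)  # (t, ch, 2)
    cube = np.einsum("wc,tkc->tkw", a, conc)  # (t, ch, n_wl)
    od = cube.reshape(record.n_samples, -1)
    return OpticalDensityRecord(
        od=od,
        wavelengths_nm=coeffs.wavelengths_nm,
        fs_hz=record.fs_hz,
        layout=record.layout,
    )
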