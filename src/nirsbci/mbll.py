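"""Modified Beer-Lambert law: optical-density changes -> chromophore changes.

For each channel and time point the forward model is

    dOD(lambda) = d * DPF(lambda) * (eps(lambda, HbO) * dHbO
                                     + eps(lambda, HbR) * dHbR)

and the inverse solves for (dHbO, dHbR).  With exactly two wavelengths the
2x2 system is inverted directly; with three or more it is solved in the
least-squares sense.  Extinction coefficients and DPF are configuration,
not ground truth: the shipped defaults are approximate literature values
for 780/805/830 nm and can be overridden (e.g. from a YAML file).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import HemodynamicRecord, OpticalDensityRecord
from .exceptions import IllConditionedError

#: Approximate molar extinction coefficients in 1/(mM*cm), {wavelength: (HbO, HbR)}.
#: Compiled from standard in-vivo spectroscopy tables; override as needed.
DEFAULT_EXTINCTION = {
    780.0: (0.735, 1.075),
    805.0: (0.860, 0.840),
    830.0: (1.058, 0.781),
}

DEFAULT_DPF = 6.0


@dataclass
class MBLLCoefficients:
    """Wavelength-resolved extinction matrix plus pathlength geometry."""

    wavelengths_nm: tuple[float, ...]
    extinction: np.ndarray  # (n_wavelengths, 2) columns [HbO, HbR], 1/(mM*cm)
    d_cm: float = 3.0
    dpf: np.ndarray | float = DEFAULT_DPF

    def __post_init__(self):
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (len(self.wavelengths_nm), 2):
            raise ValueError("extinction must be (n_wavelengths, 2)")
        if not np.all(np.isfinite(self.extinction)):
            raise ValueError("extinction coefficients must be finite")
        if np.linalg.matrix_rank(self.extinction) < 2:
            raise ValueError("extinction rows are collinear; system not invertible")
        if self.d_cm <= 0:
            raise ValueError("d_cm must be positive")
        dpf = np.broadcast_to(
            np.asarray(self.dpf, dtype=float), (len(self.wavelengths_nm),)
        ).copy()
        if np.any(dpf <= 0):
            raise ValueError("dpf must be positive")
        self.dpf = dpf

    def pathlength_matrix(self) -> np.ndarray:
        """Effective (n_wavelengths, 2) system matrix d * DPF * extinction."""
        return self.d_cm * self.dpf[:, None] * self.extinction


def default_coefficients(
    wavelengths_nm: tuple[float, ...] = (780.0, 805.0, 830.0),
    d_cm: float = 3.0,
    dpf: float = DEFAULT_DPF,
) -> MBLLCoefficients:
    try:
        ext = np.array([DEFAULT_EXTINCTION[float(w)] for w in wavelengths_nm])
    except KeyError as exc:
        raise ValueError(
            f"no default extinction for wavelength {exc.args[0]} nm; "
            "provide explicit coefficients"
        ) from None
    return MBLLCoefficients(
        wavelengths_nm=tuple(wavelengths_nm), extinction=ext, d_cm=d_cm, dpf=dpf
    )


def od_to_concentration(
    od: OpticalDensityRecord,
    coeffs: MBLLCoefficients,
    cond_threshold: float = 1e8,
) -> HemodynamicRecord:
    """Invert the Beer-Lambert system per channel and time point.

    Exactly two wavelengths use the direct 2x2 solve; three or more use the
    normal-equations least-squares solution.  Raises
    :class:`IllConditionedError` when the system matrix condition number
    exceeds ``cond_threshold``.
    """
    if tuple(od.wavelengths_nm) != tuple(coeffs.wavelengths_nm):
        raise ValueError(
            f"record wavelengths {od.wavelengths_nm} do not match "
            f"coefficient wavelengths {coeffs.wavelengths_nm}"
        )
    a = coeffs.pathlength_matrix()  # (n_wl, 2)
    cond = np.linalg.cond(a)
    if cond > cond_threshold:
        raise IllConditionedError(
            f"MBLL system condition number {cond:.3g} exceeds {cond_threshold:.3g}"
        )
    cube = od.as_cube()  # (time, channel, n_wl)
    if a.shape[0] == 2:
        inv = np.linalg.inv(a)
        conc = np.einsum("cw,tkw->tkc", inv, cube)
    else:
        pinv = np.linalg.pinv(a)
        conc = np.einsum("cw,tkw->tkc", pinv, cube)
    return HemodynamicRecord(
        hbo=conc[..., 0], hbr=conc[..., 1], fs_hz=od.fs_hz, layout=od.layout
    )
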