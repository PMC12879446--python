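"""Modified Beer-Lambert hemoglobin spectroscopy.

The modified Beer-Lambert law relates the differential absorption measured
at each LED wavelength to chromophore concentration changes:

    dA(lambda, t, p) = sum_i eps_i(lambda) * L(lambda) * dc_i(t, p)

where ``eps_i`` are molar extinction coefficients of oxy-/deoxyhemoglobin,
``L`` the wavelength-dependent differential pathlength factor, and ``dc``
the concentration contrasts relative to baseline. With more wavelengths
than chromophores the inversion is the least-squares (pseudoinverse)
solution.

The shipped extinction/pathlength defaults follow the scale of standard
tabulated hemoglobin spectra compilations (extinction in 1/(uM*cm),
pathlength in cm) and are configuration-replaceable; 530 nm sits near an
isosbestic point, 590 nm is deoxy-dominant, and 625 nm lies in the weakly
absorbing red band with the longest photon path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpectroscopyError

__all__ = [
    "SpectroscopyModel",
    "default_spectroscopy_model",
    "forward_absorption",
    "invert_spectroscopy",
]

#: molar extinction per chromophore, 1/(uM*cm), keyed by wavelength (nm)
DEFAULT_EXTINCTION_UM_CM = {
    530.0: (0.039036, 0.039036),  # (HbO2, HbR)
    590.0: (0.013640, 0.037020),
    625.0: (0.001506, 0.005888),
}

#: differential pathlength factor (effective photon path, cm)
DEFAULT_PATHLENGTH_CM = {530.0: 0.5, 590.0: 0.7, 625.0: 1.3}


@dataclass
class SpectroscopyModel:
    """Extinction/pathlength system over a fixed wavelength set.

    ``extinction`` has shape (n_wavelengths, n_chromophores) with chromophore
    order (HbO2, HbR); ``pathlength_cm`` has shape (n_wavelengths,).
    """

    wavelengths_nm: tuple[float, ...]
    extinction: np.ndarray
    pathlength_cm: np.ndarray
    chromophores: tuple[str, ...] = ("HbO2", "HbR")

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.pathlength_cm = np.asarray(self.pathlength_cm, dtype=float)
        n_wl = len(self.wavelengths_nm)
        if self.extinction.shape != (n_wl, len(self.chromophores)):
            raise SpectroscopyError(
                f"extinction shape {self.extinction.shape} does not match "
                f"{n_wl} wavelengths x {len(self.chromophores)} chromophores"
            )
        if self.pathlength_cm.shape != (n_wl,):
            raise SpectroscopyError("one pathlength factor per wavelength required")
        if np.any(self.extinction <= 0) or np.any(self.pathlength_cm <= 0):
            raise SpectroscopyError("extinction and pathlength entries must be positive")

    @property
    def system_matrix(self) -> np.ndarray:
        """(n_wavelengths, n_chromophores) matrix E = extinction * pathlength."""
        return self.extinction * self.pathlength_cm[:, None]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.system_matrix))


def default_spectroscopy_model(
    wavelengths_nm: tuple[float, ...] = (530.0, 590.0, 625.0),
) -> SpectroscopyModel:
    """Model with the shipped extinction/pathlength constants."""
    try:
        ext = np.array([DEFAULT_EXTINCTION_UM_CM[float(w)] for w in wavelengths_nm])
        dpf = np.array([DEFAULT_PATHLENGTH_CM[float(w)] for w in wavelengths_nm])
    except KeyError as err:
        raise SpectroscopyError(
            f"no shipped constants for wavelength {err.args[0]} nm; "
            "supply a SpectroscopyModel explicitly"
        ) from None
    return SpectroscopyModel(tuple(float(w) for w in wavelengths_nm), ext, dpf)


def forward_absorption(hbo2: np.ndarray, hbr: np.ndarray, model: SpectroscopyModel) -> np.ndarray:
    """Differential absorption from concentration contrasts.

    ``hbo2``/``hbr`` may have any matching shape; the result gains a leading
    wavelength axis: out[l] = E[l, 0]*hbo2 + E[l, 1]*hbr.
    """
    hbo2 = np.asarray(hbo2, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo2.shape != hbr.shape:
        raise SpectroscopyError("hbo2 and hbr must share a shape")
    E = model.system_matrix
    stacked = np.stack([hbo2, hbr])  # (2, ...)
    return np.tensordot(E, stacked, axes=(1, 0))


def invert_spectroscopy(
    dabs: np.ndarray, model: SpectroscopyModel, cond_limit: float = 1e8
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares inversion of the Beer-Lambert system.

    Parameters
    ----------
    dabs
        Differential absorption with the wavelength axis leading,
        shape (n_wavelengths, ...).
    model
        Extinction/pathlength system; requires >= 2 wavelengths and a full
        column rank system matrix.

    Returns
    -------
    (hbo2, hbr) arrays of shape ``dabs.shape[1:]``, in the concentration
    units implied by the extinction coefficients (uM for the defaults).
    Sign convention: increased absorption maps to positive concentration
    change for a positively absorbing chromophore.
    """
    dabs = np.asarray(dabs, dtype=float)
    E = model.system_matrix
    if dabs.shape[0] != E.shape[0]:
        raise SpectroscopyError(
            f"dabs leading axis {dabs.shape[0]} does not match "
            f"{E.shape[0]} model wavelengths"
        )
    if E.shape[0] < E.shape[1]:
        raise SpectroscopyError("need at least as many wavelengths as chromophores")
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > cond_limit:
        raise SpectroscopyError(
            f"extinction*pathlength system is rank deficient (condition number {cond:.3g})"
        )
    pinv = np.linalg.pinv(E)  # (2, n_wl)
    dc = np.tensordot(pinv, dabs, axes=(1, 0))
    return dc[0], dc[1]
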