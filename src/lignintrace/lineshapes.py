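"""Area-normalized NMR lineshape profiles.

All profiles integrate to 1 over the real line so that a peak is fully
specified by (center, FWHM, area); the pseudo-Voigt uses the common
same-FWHM convention ``eta * Lorentzian + (1 - eta) * Gaussian``, matching
the parametrization used by the deconvolution fit model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GAUSS_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LineShape:
    """A lineshape family: ``gaussian``, ``lorentzian`` or ``pseudo_voigt``."""

    kind: str = "gaussian"
    fwhm_ppm: float = 2.0
    eta: float = 0.0  # Lorentzian fraction, pseudo_voigt only

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown lineshape kind {self.kind!r}")
        if not self.fwhm_ppm > 0:
            raise ValueError("fwhm_ppm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def profile(self, x: np.ndarray, center: float) -> np.ndarray:
        if self.kind == "gaussian":
            return gaussian(x, center, self.fwhm_ppm)
        if self.kind == "lorentzian":
            return lorentzian(x, center, self.fwhm_ppm)
        return pseudo_voigt(x, center, self.fwhm_ppm, self.eta)


def gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _GAUSS_SIGMA_PER_FWHM
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return (gamma / np.pi) / ((x - center) ** 2 + gamma**2)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    return eta * lorentzian(x, center, fwhm) + (1.0 - eta) * gaussian(x, center, fwhm)


def profile_2d(
    f1: np.ndarray, f2: np.ndarray, c1: float, c2: float, shape: LineShape
) -> np.ndarray:
    """Separable 2D peak profile (outer product of 1D profiles), volume 1."""
    return np.outer(shape.profile(f1, c1), shape.profile(f2, c2))
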