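"""Cone spectral sensitivities from a shiftable photopigment nomogram.

The only parameter distinguishing cone classes in this package is the
wavelength of peak sensitivity, lambda-max.  Sensitivities are produced by a
nomogram: a fixed template absorbance spectrum translated rigidly in
log-wavelength so that its peak lands on the requested lambda-max.  The
template itself is the Govardovskii A1 visual-pigment absorbance (alpha plus
beta band), frozen at the reference lambda-max of 558.9 nm (the typical
human L cone).  Freezing the template and shifting in log-wavelength makes
the family exactly shift-invariant, which is all the downstream algorithm
needs: realistic, unimodal, lambda-max-parameterized curves whose overlap
grows as peaks approach.

Sensitivities are quantal-unit throughout and peak-normalized; a fixed
pre-receptoral (lens + macular pigment) transmittance is applied by default
and can be disabled for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenes import DEFAULT_WAVELENGTHS

__all__ = [
    "SpectralSensitivity",
    "cone_fundamental",
    "standard_set",
    "pre_receptoral_transmittance",
    "REFERENCE_LAMBDA_MAX",
    "LAMBDA_MAX_RANGE",
]

#: lambda-max at which the pigment template is frozen (typical human L cone).
REFERENCE_LAMBDA_MAX = 558.9

#: validity window for the shifted template (documented contract).
LAMBDA_MAX_RANGE = (400.0, 620.0)

# Govardovskii A1 alpha-band coefficients
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _template_absorbance(wavelengths: np.ndarray) -> np.ndarray:
    """A1 pigment absorbance (alpha + beta band) at the reference peak."""
    lam = np.asarray(wavelengths, dtype=float)
    lm = REFERENCE_LAMBDA_MAX
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    x = lm / lam
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    a_beta = 0.26
    lm_beta = 189.0 + 0.315 * lm
    b_beta = -40.5 + 0.195 * lm
    beta = a_beta * np.exp(-(((lam - lm_beta) / b_beta) ** 2))
    return alpha + beta


def pre_receptoral_transmittance(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed lens + macular pigment transmittance on ``wavelengths``.

    A smooth synthetic stand-in for ocular media filtering: lens optical
    density decays exponentially from ~1.6 at 400 nm; macular pigment adds a
    Gaussian density bump (0.35 peak) near 460 nm.  Transmittance is
    ``10**-(density)``.
    """
    lam = np.asarray(wavelengths, dtype=float)
    lens = 1.6 * np.exp(-(lam - 400.0) / 60.0)
    macular = 0.35 * np.exp(-(((lam - 458.0) / 50.0) ** 2))
    return 10.0 ** -(lens + macular)


@dataclass
class SpectralSensitivity:
    """Peak-normalized quantal sensitivity of one cone class.

    ``sensitivity`` includes pre-receptoral filtering (when enabled);
    ``absorbance`` is the unfiltered, peak-normalized pigment template, whose
    argmax sits within one grid step of ``lambda_max``.
    """

    wavelengths: np.ndarray
    sensitivity: np.ndarray
    lambda_max: float
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        if self.sensitivity.shape != self.wavelengths.shape:
            raise ValueError("sensitivity and wavelength grids differ in length")

    @property
    def peak_wavelength(self) -> float:
        """Grid wavelength at which the filtered sensitivity peaks."""
        return float(self.wavelengths[int(np.argmax(self.sensitivity))])


def cone_fundamental(
    lambda_max: float,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    filtered: bool = True,
) -> SpectralSensitivity:
    """Spectral sensitivity of a cone with peak absorbance at ``lambda_max``.

    The frozen template is evaluated at ``lam * (ref / lambda_max)`` — a
    rigid shift in log-wavelength — then multiplied by the fixed
    pre-receptoral transmittance (unless ``filtered=False``) and renormalized
    to unit peak.
    """
    lo, hi = LAMBDA_MAX_RANGE
    if not lo <= lambda_max <= hi:
        raise ValueError(
            f"lambda_max {lambda_max} nm outside template validity window "
            f"[{lo}, {hi}] nm"
        )
    lam = np.asarray(wavelengths, dtype=float)
    absorbance = _template_absorbance(lam * (REFERENCE_LAMBDA_MAX / lambda_max))
    absorbance = absorbance / absorbance.max()
    sens = absorbance * pre_receptoral_transmittance(lam) if filtered else absorbance.copy()
    sens = sens / sens.max()
    return SpectralSensitivity(
        wavelengths=lam, sensitivity=sens, lambda_max=float(lambda_max), absorbance=absorbance
    )


def standard_set(
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS, filtered: bool = True
) -> dict[str, SpectralSensitivity]:
    """L, M, S fundamentals for a typical human fovea.

    Peak wavelengths 558.9, 530 and 420.7 nm respectively.
    """
    peaks = {"L": 558.9, "M": 530.0, "S": 420.7}
    return {
        name: cone_fundamental(lm, wavelengths, filtered=filtered)
        for name, lm in peaks.items()
    }
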