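"""Photoreceptor spectral sensitivity and quantum catch.

Sensitivities are generated from the standard A1 visual-pigment
absorbance template (alpha band plus beta band, parameterised solely by
λmax) when measured curves are not available; measured spectra can be
supplied as CSV instead.  The quantum catch of a surface is the integral
over wavelength of illuminant × reflectance × receptor sensitivity,
normalised to the catch of an ideal 100% reflector under the same
illuminant so that scaling of the illuminant cancels.  The average of
the two double-cone members' normalised catches models the luminance
channel of fishes whose double cones feed achromatic vision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_GRID = np.arange(300.0, 750.0 + 1e-9, 1.0)


@dataclass
class Spectrum:
    """A nonnegative function of wavelength on an ascending nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D and the same length")
        if len(self.wavelengths) < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be nonnegative")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto `grid`; zero outside support."""
        return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)

    @classmethod
    def flat(cls, value: float, grid: np.ndarray = DEFAULT_GRID) -> "Spectrum":
        return cls(grid.copy(), np.full_like(grid, float(value)))

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "value": self.values}).to_csv(path, index=False)


@dataclass
class PhotoreceptorSensitivity:
    label: str
    lambda_max_nm: float
    sensitivity: Spectrum

    def __post_init__(self) -> None:
        peak_idx = int(np.argmax(self.sensitivity.values))
        nearest = int(np.argmin(np.abs(self.sensitivity.wavelengths - self.lambda_max_nm)))
        # the beta band shifts the discrete summit by one grid step for
        # UV/violet pigments (λmax ≲ 390 nm); allow that single-step skew
        if abs(peak_idx - nearest) > 1:
            raise ValueError("sensitivity peak is not at the grid point nearest λmax")
        if not np.isclose(self.sensitivity.values[peak_idx], 1.0):
            raise ValueError("sensitivity must be normalised to peak 1")


def a1_template(lambda_max_nm: float, wavelengths: np.ndarray) -> np.ndarray:
    """A1 visual-pigment absorbance (alpha + beta band), un-normalised.

    Standard rhodopsin/porphyropsin template: the alpha band is a
    sum-of-exponentials function of x = λmax/λ with a λmax-dependent
    steepness of the long-wave limb; the beta band is a Gaussian whose
    position and width scale linearly with λmax.
    """
    lm = float(lambda_max_nm)
    wl = np.asarray(wavelengths, dtype=float)
    x = lm / wl
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lm
    b_beta = -40.5 + 0.195 * lm
    beta = 0.26 * np.exp(-(((wl - lm_beta) / b_beta) ** 2))
    return alpha + beta


def pigment_template(lambda_max_nm: float,
                     grid: np.ndarray = DEFAULT_GRID,
                     label: str | None = None) -> PhotoreceptorSensitivity:
    """Peak-normalised A1 template sensitivity on `grid`.

    λmax must lie in 350–600 nm (the template's validated range for
    teleost visual pigments) and inside the grid.
    """
    if not 350.0 <= lambda_max_nm <= 600.0:
        raise ValueError(f"λmax {lambda_max_nm} nm outside the supported range 350-600 nm")
    grid = np.asarray(grid, dtype=float)
    if grid[0] > lambda_max_nm or grid[-1] < lambda_max_nm:
        raise ValueError("grid does not cover λmax")
    vals = a1_template(lambda_max_nm, grid)
    vals = vals / vals.max()
    return PhotoreceptorSensitivity(
        label=label or f"lmax{lambda_max_nm:g}",
        lambda_max_nm=lambda_max_nm,
        sensitivity=Spectrum(grid.copy(), vals),
    )


@dataclass
class QuantumCatchResult:
    receptor_label: str
    catch: float
    normalised_catch: float  # percent of the ideal-white catch


def _common_grid(*spectra: Spectrum) -> np.ndarray:
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have disjoint wavelength supports")
    step = min(float(np.min(np.diff(s.wavelengths))) for s in spectra)
    return np.arange(lo, hi + step / 2, step)


def quantum_catch(reflectance: Spectrum, illuminant: Spectrum,
                  receptor: PhotoreceptorSensitivity) -> QuantumCatchResult:
    """Quantum catch Q = ∫ R(λ) I(λ) S(λ) dλ (trapezoidal).

    normalised_catch is 100 × Q / Q_white where Q_white uses a unit
    reflector, so the ideal white surface scores 100 by construction.
    """
    grid = _common_grid(reflectance, illuminant, receptor.sensitivity)
    r = reflectance.resample(grid)
    i = illuminant.resample(grid)
    s = receptor.sensitivity.resample(grid)
    catch = float(np.trapezoid(r * i * s, grid))
    white = float(np.trapezoid(i * s, grid))
    if white == 0:
        raise ValueError("illuminant delivers no light within the receptor's sensitivity")
    return QuantumCatchResult(receptor.label, catch, 100.0 * catch / white)


def double_cone_output(reflectance: Spectrum, illuminant: Spectrum,
                       members: Sequence[PhotoreceptorSensitivity]) -> float:
    """Luminance signal: mean normalised catch of the two double-cone members."""
    if len(members) != 2:
        raise ValueError("a double cone has exactly two members")
    catches = [quantum_catch(reflectance, illuminant, m).normalised_catch
               for m in members]
    return float(np.mean(catches))


def relative_gap(q_a: float, q_b: float) -> float:
    """Relative luminance difference |Qa − Qb| / mean(Qa, Qb)."""
    mean = (q_a + q_b) / 2.0
    if mean == 0:
        raise ValueError("both luminance signals are zero")
    return abs(q_a - q_b) / mean


def isoluminance_gap(colour_a: Spectrum, colour_b: Spectrum, illuminant: Spectrum,
                     members: Sequence[PhotoreceptorSensitivity]) -> float:
    """Relative double-cone luminance difference between two colours.

    Near-zero values mean the pair is isoluminant to the double-cone
    channel and discrimination must rely on chromatic cues.
    """
    q_a = double_cone_output(colour_a, illuminant, members)
    q_b = double_cone_output(colour_b, illuminant, members)
    return relative_gap(q_a, q_b)
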