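"""Pump-laser photoexcitation and heating dosimetry.

Closed-form arithmetic tying pump-pulse geometry and chromophore optics to
excitation metrics: Gaussian-beam fluences and power densities, the
upper-bound photons-per-chromophore metric sigma*F/(h*nu), and the
heating-based estimate DeltaT * C_P / (c * N_A * h*nu) with the temperature
jump read from the principal SVD component of difference solution-scattering
curves against a calibration.

All unit conversions are centralized here; physical constants are CODATA
(via scipy) and 1 kcal = 4184 J.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.constants import Avogadro, c as SPEED_OF_LIGHT, h as PLANCK

__all__ = [
    "BeamProfile",
    "Photophysics",
    "HeatingSeries",
    "FWHM_PER_E2_RADIUS",
    "photon_energy",
    "cross_section",
    "gaussian_fluences",
    "photons_per_molecule_from_fluence",
    "photons_per_molecule_from_heating",
    "concentration_rescale",
    "svd_heating",
]

J_PER_KCAL = 4184.0
#: FWHM = (1/e^2 radius) * sqrt(2 ln 2) for a Gaussian beam
FWHM_PER_E2_RADIUS = float(np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_e2_diameter(fwhm: float) -> float:
    """1/e^2 diameter from FWHM (any consistent length unit)."""
    return 2.0 * (fwhm / 2.0) / FWHM_PER_E2_RADIUS * 2.0


def e2_to_fwhm_diameter(e2_diameter: float) -> float:
    return (e2_diameter / 2.0) * FWHM_PER_E2_RADIUS


@dataclasses.dataclass
class BeamProfile:
    """Pump-pulse geometry and energy.

    pulse_energy : J;  fwhm_diameter, e2_diameter : cm (either suffices, the
    other is derived);  pulse_duration : s;  wavelength : m.
    """

    pulse_energy: float
    pulse_duration: float
    wavelength: float
    fwhm_diameter: float | None = None
    e2_diameter: float | None = None

    def __post_init__(self) -> None:
        for name in ("pulse_energy", "pulse_duration", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fwhm_diameter is None and self.e2_diameter is None:
            raise ValueError("supply fwhm_diameter or e2_diameter")
        if self.fwhm_diameter is not None and self.e2_diameter is not None:
            derived = e2_to_fwhm_diameter(self.e2_diameter)
            if abs(derived - self.fwhm_diameter) > 0.05 * self.fwhm_diameter:
                warnings.warn(
                    "FWHM and 1/e2 widths are inconsistent beyond 5%; "
                    "both retained as given", stacklevel=2,
                )
        elif self.fwhm_diameter is not None:
            self.e2_diameter = fwhm_to_e2_diameter(self.fwhm_diameter)
        else:
            self.fwhm_diameter = e2_to_fwhm_diameter(self.e2_diameter)


@dataclasses.dataclass
class Photophysics:
    """Chromophore optics and solution calorimetry.

    epsilon : molar extinction coefficient (M^-1 cm^-1);
    concentration : mol L^-1;  heat_capacity : J cm^-3 K^-1.
    """

    epsilon: float
    concentration: float
    heat_capacity: float

    def __post_init__(self) -> None:
        for name in ("epsilon", "concentration", "heat_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def photon_energy(wavelength: float) -> tuple[float, float]:
    """(E in J, molar E in kcal/mol) of a photon of the given wavelength (m)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    e_joule = PLANCK * SPEED_OF_LIGHT / wavelength
    e_kcal_mol = e_joule * Avogadro / J_PER_KCAL
    return e_joule, e_kcal_mol


def cross_section(epsilon: float) -> float:
    """Absorption cross-section (cm^2) from a molar extinction coefficient:
    sigma = 1000 ln(10) epsilon / N_A."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    return 1000.0 * np.log(10.0) * epsilon / Avogadro


@dataclasses.dataclass
class GaussianFluences:
    """Fluences in J cm^-2, power densities in W cm^-2."""

    peak: float
    fwhm_average: float
    peak_power: float
    fwhm_average_power: float


def gaussian_fluences(beam: BeamProfile) -> GaussianFluences:
    """Idealized Gaussian-beam fluences.

    peak = 2 E / (pi w^2) with w the 1/e^2 radius; the FWHM average uses the
    fact that exactly half the pulse energy falls inside the FWHM disc of a
    2-D Gaussian: (E/2) / (pi (FWHM/2)^2).
    """
    w = beam.e2_diameter / 2.0
    peak = 2.0 * beam.pulse_energy / (np.pi * w * w)
    r_fwhm = beam.fwhm_diameter / 2.0
    fwhm_avg = 0.5 * beam.pulse_energy / (np.pi * r_fwhm * r_fwhm)
    return GaussianFluences(
        peak=peak,
        fwhm_average=fwhm_avg,
        peak_power=peak / beam.pulse_duration,
        fwhm_average_power=fwhm_avg / beam.pulse_duration,
    )


def photons_per_molecule_from_fluence(fluence: float, epsilon: float,
                                      wavelength: float) -> float:
    """Upper-bound excitation metric sigma F / (h nu) (dimensionless).

    ``fluence`` in J cm^-2; an upper bound because excited-state absorption,
    stimulated emission and scattering losses are ignored.
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    e_photon, _ = photon_energy(wavelength)
    return cross_section(epsilon) * fluence / e_photon


def photons_per_molecule_from_heating(delta_t: float, phys: Photophysics,
                                      wavelength: float) -> float:
    """Absorbed photons per molecule = DeltaT C_P / (c N_A h nu).

    ``delta_t`` in K; concentration is converted from mol L^-1 to mol cm^-3
    so the heat capacity (J cm^-3 K^-1) applies directly.
    """
    e_photon, _ = photon_energy(wavelength)
    conc_cm3 = phys.concentration * 1e-3
    return delta_t * phys.heat_capacity / (conc_cm3 * Avogadro * e_photon)


def concentration_rescale(photons: float, c_from: float, c_to: float) -> float:
    """Inverse-linear rescaling of a per-molecule heating estimate between
    sample concentrations (same heat goes to more molecules)."""
    if c_from <= 0 or c_to <= 0:
        raise ValueError("concentrations must be positive")
    return photons * c_from / c_to


@dataclasses.dataclass
class HeatingSeries:
    """Difference scattering curves (q-samples x measurements) with the pump
    fluence of each measurement and an (amplitude, DeltaT) calibration."""

    curves: np.ndarray
    fluences: np.ndarray
    calibration: np.ndarray

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        self.fluences = np.asarray(self.fluences, dtype=float)
        self.calibration = np.asarray(self.calibration, dtype=float)
        if self.curves.ndim != 2:
            raise ValueError("curves must be a 2-D matrix")
        if self.curves.shape[1] != len(self.fluences):
            raise ValueError("one fluence per measurement column required")
        if self.calibration.ndim != 2 or self.calibration.shape[0] < 2:
            raise ValueError("calibration needs >= 2 (amplitude, DeltaT) pairs")


@dataclasses.dataclass
class HeatingResult:
    amplitudes: np.ndarray
    delta_t: np.ndarray
    slope: float  # K per (mJ cm^-2), through-origin fit
    r_squared: float
    extrapolated: np.ndarray  # True where amplitude left the calibration span


def svd_heating(series: HeatingSeries) -> HeatingResult:
    """Per-measurement temperature jumps from the principal SVD component.

    The first left-singular vector is the heating basis (sign fixed so its
    mean is positive); each measurement's amplitude is its projection onto
    that basis, converted to DeltaT by piecewise-linear interpolation of the
    calibration pairs.  A straight line through the origin is fitted to
    DeltaT versus fluence.
    """
    u, s, vt = np.linalg.svd(series.curves, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("scattering matrix has rank 0")
    basis = u[:, 0]
    sign = 1.0 if basis.mean() >= 0 else -1.0
    amplitudes = sign * s[0] * vt[0, :]
    cal = series.calibration[np.argsort(series.calibration[:, 0])]
    lo, hi = cal[0, 0], cal[-1, 0]
    extrapolated = (amplitudes < lo) | (amplitudes > hi)
    if extrapolated.any():
        warnings.warn("SVD amplitudes outside the calibration span; "
                      "linear extrapolation applied", stacklevel=2)
    # np.interp clamps; extend linearly beyond the span instead
    delta_t = np.interp(amplitudes, cal[:, 0], cal[:, 1])
    below, above = amplitudes < lo, amplitudes > hi
    if below.any():
        m = (cal[1, 1] - cal[0, 1]) / (cal[1, 0] - cal[0, 0])
        delta_t[below] = cal[0, 1] + m * (amplitudes[below] - lo)
    if above.any():
        m = (cal[-1, 1] - cal[-2, 1]) / (cal[-1, 0] - cal[-2, 0])
        delta_t[above] = cal[-1, 1] + m * (amplitudes[above] - hi)
    f = series.fluences
    denom = float(f @ f)
    slope = float(f @ delta_t) / denom if denom > 0 else 0.0
    resid = delta_t - slope * f
    ss_tot = float(delta_t @ delta_t)
    r_squared = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return HeatingResult(amplitudes, delta_t, slope, r_squared, extrapolated)
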