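"""Physical constants and spin-physics primitives for pulsed dipolar EPR.

Unit conventions used throughout the package:

* time in microseconds (µs)
* angular frequencies in rad/µs
* distances in nanometers (nm)
* magnetic field in tesla (T)
* temperature in kelvin (K)
* spin concentration in millimolar (mM), converted internally to nm⁻³

These choices make the electron dipolar constant come out as
``D ≈ 2π · 52.04 MHz·nm³ = 326.98 rad µs⁻¹ nm³``, so that distances of a few
nanometers map onto oscillation periods of a few microseconds — the natural
scales of a DEER experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CODATA2018",
    "ExperimentConditions",
    "thermal_polarization",
    "dipolar_constant",
    "dipolar_frequency",
    "concentration_to_density",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants, CODATA-2018 values, SI units.

    ``ge`` is the free-electron g value rounded to the 6 figures customarily
    used in EPR; species-specific g values may be passed to the functions
    below instead.
    """

    mu0: float = 1.25663706212e-6  # vacuum magnetic permeability, N A^-2
    muB: float = 9.2740100783e-24  # Bohr magneton, J/T
    ge: float = 2.00232            # free-electron g value
    hbar: float = 1.054571817e-34  # reduced Planck constant, J s
    kB: float = 1.380649e-23       # Boltzmann constant, J/K (exact)
    NA: float = 6.02214076e23      # Avogadro constant, mol^-1 (exact)


CODATA2018 = PhysicalConstants()


def thermal_polarization(field_B, temperature_T, g: float | None = None):
    """Thermal equilibrium polarization of a spin-1/2 ensemble.

    Parameters
    ----------
    field_B : float or array_like
        Magnetic field in tesla, >= 0.
    temperature_T : float or array_like
        Temperature in kelvin, > 0.
    g : float, optional
        Electron g value; defaults to the free-electron value.

    Returns
    -------
    float or ndarray
        ``tanh(g µB B / (2 kB T))``, the normalized population difference
        between the two Zeeman levels, in [0, 1).
    """
    c = CODATA2018
    g = c.ge if g is None else g
    B = np.asarray(field_B, dtype=float)
    T = np.asarray(temperature_T, dtype=float)
    if np.any(B < 0):
        raise ValueError("magnetic field must be non-negative")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    eps = np.tanh(g * c.muB * B / (2.0 * c.kB * T))
    return float(eps) if eps.ndim == 0 else eps


def dipolar_constant(g: float | None = None) -> float:
    """Electron–electron dipolar constant D in rad µs⁻¹ nm³.

    ``D = (µ0/4π) µB² g² / ħ``;  D / 2π ≈ 52.04 MHz·nm³ for free electrons.
    """
    c = CODATA2018
    g = c.ge if g is None else g
    d_si = c.mu0 / (4.0 * np.pi) * (c.muB * g) ** 2 / c.hbar  # rad s^-1 m^3
    # rad s^-1 m^3 -> rad µs^-1 nm^3: 1e-6 (s->µs) * 1e27 (m^3->nm^3)
    return d_si * 1e21


def dipolar_frequency(r, cos_theta, g: float | None = None):
    """Secular dipolar coupling frequency ω(r, θ) in rad/µs.

    ``ω = D (1 − 3 cos²θ) / r³`` with r in nm and θ the angle between the
    inter-spin vector and the static field. Vanishes at the magic angle
    cosθ = 1/√3 and equals D/r³ for perpendicular orientation.
    """
    r = np.asarray(r, dtype=float)
    ct = np.asarray(cos_theta, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inter-spin distance must be positive")
    w = dipolar_constant(g) * (1.0 - 3.0 * ct**2) / r**3
    return float(w) if np.ndim(w) == 0 else w


def concentration_to_density(conc_cB) -> float:
    """Convert a concentration in mM to a number density in nm⁻³.

    1 mM = 1e-3 mol/L · NA / 1e24 nm³/L ≈ 6.022e-4 spins/nm³.
    """
    c = np.asarray(conc_cB, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    n = c * 1e-3 * CODATA2018.NA * 1e-24
    return float(n) if n.ndim == 0 else n


@dataclass(frozen=True)
class ExperimentConditions:
    """Settings that fix the polarization ε and the background decay rate.

    Attributes
    ----------
    field_B : float
        Static magnetic field, T.
    temperature_T : float
        Sample temperature, K (> 0).
    pump_efficiency_pB : float
        Fraction of B spins inverted by the pump pulse, in [0, 1].
    conc_cB : float
        Concentration of pumped (B) spins, mM (>= 0).
    """

    field_B: float
    temperature_T: float
    pump_efficiency_pB: float = 1.0
    conc_cB: float = 0.0

    def __post_init__(self) -> None:
        if self.field_B < 0:
            raise ValueError("field_B must be non-negative")
        if self.temperature_T <= 0:
            raise ValueError("temperature_T must be positive")
        if not 0.0 <= self.pump_efficiency_pB <= 1.0:
            raise ValueError("pump_efficiency_pB must lie in [0, 1]")
        if self.conc_cB < 0:
            raise ValueError("conc_cB must be non-negative")

    @property
    def epsilon(self) -> float:
        """Thermal spin polarization under these conditions."""
        return thermal_polarization(self.field_B, self.temperature_T)
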