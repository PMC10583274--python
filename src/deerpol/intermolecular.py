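"""Closed-form intermolecular (background) DEER signal at finite polarization.

For an A spin surrounded by a uniform random 3-D distribution of B spins,
the ensemble-averaged product of pair signals evaluates to

    V_inter(t) = exp(−k |t|) · exp(i α ε k t),

an exponential decay carrying a phase that grows linearly with the pump
position t and is proportional to the spin polarization ε. The decay rate is

    k = (8π² / 9√3) · pB · n_B · D,

with n_B the B-spin number density and D the dipolar constant, and
α ≈ 0.13213 is a universal dimensionless constant. This module provides the
closed form and its corollaries: extremum time of the out-of-phase channel,
its amplitude, and the Lorentzian Fourier lineshape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import concentration_to_density, dipolar_constant

__all__ = [
    "ALPHA",
    "BackgroundParams",
    "decay_rate",
    "background_signal",
    "t_oop",
    "oop_amplitude",
    "background_spectrum",
]

#: Dimensionless phase-slope constant of the polarized background.
#: The printed numeric value is authoritative; it is independently validated
#: by the Monte Carlo spin-bath oracle in :mod:`deerpol.montecarlo`.
ALPHA = 0.13213

_K_PREFACTOR = 8.0 * np.pi**2 / (9.0 * np.sqrt(3.0))


@dataclass(frozen=True)
class BackgroundParams:
    """Parameters of the closed-form intermolecular signal.

    Attributes
    ----------
    k : float
        Decay rate constant, µs⁻¹ (>= 0).
    epsilon : float
        Spin polarization in [0, 1].
    qB : float
        Phenomenological multiplier on the phase slope (theory: 1).
    alpha : float
        Universal phase constant, fixed at 0.13213.
    """

    k: float
    epsilon: float = 0.0
    qB: float = 1.0
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.qB < 0:
            raise ValueError("qB must be non-negative")


def decay_rate(pB: float, conc_cB: float, g: float | None = None) -> float:
    """Background decay rate k in µs⁻¹.

    ``k = (8π²/9√3) · pB · n_B · D`` with the B-spin number density n_B in
    nm⁻³ and D in rad µs⁻¹ nm³. Numerically, pB · (cB/mM) · (k/µs⁻¹)⁻¹ ≈ 1.
    """
    if not 0.0 <= pB <= 1.0:
        raise ValueError("pB must lie in [0, 1]")
    n = concentration_to_density(conc_cB)
    return _K_PREFACTOR * pB * n * dipolar_constant(g)


def background_signal(t, params: BackgroundParams):
    """Closed-form intermolecular signal exp(−k|t|)·exp(i α ε qB k t).

    Hermitian in t (real part even, imaginary part odd); the magnitude
    exp(−k|t|) is independent of ε and qB, which enter the phase only.
    """
    t = np.asarray(t, dtype=float)
    v = np.exp(-params.k * np.abs(t)) * np.exp(
        1j * params.alpha * params.epsilon * params.qB * params.k * t
    )
    return complex(v) if v.ndim == 0 else v


def t_oop(params: BackgroundParams) -> float:
    """Time of the out-of-phase extremum of the background, µs.

    ``t_OOP = (1/k) · arctan(αεqB) / (αεqB)``, with the ε → 0 limit 1/k.
    Since αεqB <= α ≈ 0.132, t_OOP ≈ 1/k always holds to better than 1 %.
    """
    if params.k <= 0:
        raise ValueError("k must be positive")
    x = params.alpha * params.epsilon * params.qB
    if x < 1e-12:
        return 1.0 / params.k
    return float(np.arctan(x) / x / params.k)


def oop_amplitude(epsilon: float, exact: bool = False) -> float:
    """Out-of-phase amplitude of the background at its extremum.

    With ``exact=False`` (default) returns the leading approximation
    ``e⁻¹ · α · ε ≈ 0.0486 ε``. With ``exact=True`` returns the exact
    extremum value ``exp(−arctan(αε)/(αε)) · αε / sqrt(1 + (αε)²)``, which
    equals Im V_inter(t_OOP) for qB = 1 to machine precision.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    x = ALPHA * epsilon
    if not exact:
        return float(np.exp(-1.0) * x)
    if x < 1e-12:
        return 0.0
    return float(np.exp(-np.arctan(x) / x) * x / np.sqrt(1.0 + x**2))


def background_spectrum(omega, params: BackgroundParams):
    """Fourier transform of the background: Lorentzian lineshape.

    ``FT(ω) = 2πk / (k² + (ω + αεqB k)²)``, centered at ω = −αεqB·k with
    full width at half maximum 2k. ω in rad/µs, result in µs.
    """
    if params.k <= 0:
        raise ValueError("k must be positive")
    omega = np.asarray(omega, dtype=float)
    shift = params.alpha * params.epsilon * params.qB * params.k
    s = 2.0 * np.pi * params.k / (params.k**2 + (omega + shift) ** 2)
    return float(s) if s.ndim == 0 else s
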