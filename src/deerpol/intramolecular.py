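"""Intramolecular (spin-pair) DEER signals at arbitrary spin polarization.

The elementary object is the two-spin signal

    V_AB(r, θ, t) = (1 − pB) + pB [cos(ωt) + i ε sin(ωt)],

whose orientation average over an isotropic powder has a closed form in
terms of Fresnel integrals of the dimensionless dipolar phase φ = D t / r³.
At polarization ε > 0 the powder signal acquires an out-of-phase (imaginary)
component; at ε = 0 it reduces to the familiar real DEER pair kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import fresnel

from .physics import dipolar_constant, dipolar_frequency

__all__ = [
    "GaussianDistanceDistribution",
    "DipolarPhase",
    "pair_signal",
    "fresnel_kernel",
    "powder_signal",
    "distribution_signal",
]

# below this |phi| the kernel is evaluated by its leading series
_PHI_SMALL = 1e-8


@dataclass(frozen=True)
class GaussianDistanceDistribution:
    """Gaussian inter-spin distance distribution P(r).

    Attributes
    ----------
    r0 : float
        Peak position, nm (> 0).
    w : float
        Standard deviation, nm (> 0).
    """

    r0: float
    w: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.w <= 0:
            raise ValueError("w must be positive")

    def pdf(self, r):
        r = np.asarray(r, dtype=float)
        return np.exp(-((r - self.r0) ** 2) / (2.0 * self.w**2)) / (
            self.w * np.sqrt(2.0 * np.pi)
        )

    def grid(self, n: int = 201, span: float = 6.0, r_min: float = 0.1):
        """Integration grid covering r0 ± span·w, truncated below r_min."""
        lo = max(r_min, self.r0 - span * self.w)
        hi = self.r0 + span * self.w
        return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class DipolarPhase:
    """Dimensionless dipolar phase φ = D t / r³ and its Fresnel argument.

    The Fresnel argument z = sqrt(6 φ / π) is real for φ >= 0 and imaginary
    for φ < 0; ``z_fresnel`` stores the real magnitude with the sign of φ
    carried separately by ``phi``.
    """

    phi: float

    @property
    def z_fresnel(self) -> complex:
        z = np.sqrt(6.0 * abs(self.phi) / np.pi)
        return complex(z) if self.phi >= 0 else 1j * z


def pair_signal(r, cos_theta, t, pB, epsilon):
    """Two-spin DEER signal for a single A–B pair at fixed orientation.

    Returns the complex echo amplitude
    ``(1 − pB) + pB [cos(ωt) + i ε sin(ωt)]`` with ω the secular dipolar
    frequency. Equals 1 exactly at t = 0 and for pB = 0.
    """
    if not 0.0 <= pB <= 1.0:
        raise ValueError("pB must lie in [0, 1]")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    w = dipolar_frequency(r, cos_theta)
    t = np.asarray(t, dtype=float)
    wt = w * t
    v = (1.0 - pB) + pB * (np.cos(wt) + 1j * epsilon * np.sin(wt))
    return complex(v) if v.ndim == 0 else v


def fresnel_kernel(phi):
    """Powder-average kernel components at dimensionless phase φ.

    Returns the pair ``(real_part, imag_kernel)`` with

        real_part   = [F_C(z) cos φ + F_S(z) sin φ] / z
        imag_kernel = [F_C(z) sin φ − F_S(z) cos φ] / z

    and z = sqrt(6 φ / π). For φ < 0 the Fresnel argument is imaginary and
    the identities F_C(ia) = i F_C(a), F_S(ia) = −i F_S(a) reduce both
    components to real values: the real part is even in φ, the imaginary
    kernel odd. The φ → 0 limit is (1, 0).
    """
    phi = np.asarray(phi, dtype=float)
    scalar = phi.ndim == 0
    p = np.abs(np.atleast_1d(phi))
    re = np.ones_like(p)
    im = np.zeros_like(p)
    big = p >= _PHI_SMALL
    pb = p[big]
    z = np.sqrt(6.0 * pb / np.pi)
    s, c = fresnel(z)
    re[big] = (c * np.cos(pb) + s * np.sin(pb)) / z
    im[big] = (c * np.sin(pb) - s * np.cos(pb)) / z
    # leading series: real = 1 - 2φ²/5 + O(φ⁴), imag = φ³/3 + O(φ⁵)
    ps = p[~big]
    re[~big] = 1.0 - 0.4 * ps**2
    im[~big] = ps**3 / 3.0
    sign = np.sign(np.atleast_1d(phi))
    sign[sign == 0] = 1.0
    im = im * sign
    if scalar:
        return float(re[0]), float(im[0])
    return re.reshape(np.shape(phi)), im.reshape(np.shape(phi))


def powder_signal(r, t, epsilon):
    """Orientation-averaged intramolecular signal for a single distance r.

    ``V(r, t) = real_part(φ) + i ε imag_kernel(φ)`` at φ = D t / r³.
    Hermitian in time: V(−t) = conj(V(t)).
    """
    if np.any(np.asarray(r) <= 0):
        raise ValueError("inter-spin distance must be positive")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    phi = dipolar_constant() * t / np.asarray(r, dtype=float) ** 3
    re, im = fresnel_kernel(phi)
    v = re + 1j * epsilon * np.asarray(im)
    return complex(v) if np.ndim(v) == 0 else v


def distribution_signal(dist, t, epsilon, qF: float = 1.0, mod_depth: float = 1.0,
                        n_r: int = 201):
    """Intramolecular signal averaged over a Gaussian distance distribution.

    Parameters
    ----------
    dist : GaussianDistanceDistribution
        Distance distribution P(r).
    t : array_like
        Pump-pulse positions, µs (signed).
    epsilon : float
        Spin polarization in [0, 1].
    qF : float
        Phenomenological multiplier on the out-of-phase term (theory: 1).
    mod_depth : float
        Modulation depth λ in [0, 1]; for an ideal pump pulse λ = pB.
    n_r : int
        Number of distance-quadrature nodes (trapezoid rule on r0 ± 6w).

    Returns
    -------
    complex or ndarray
        ``(1 − λ) + λ ∫ P(r) [real_part(φ) + i ε qF imag_kernel(φ)] dr``.
        The quadrature weights are renormalized over the truncated grid so
        that the signal is exactly 1 at t = 0.
    """
    if not isinstance(dist, GaussianDistanceDistribution):
        dist = GaussianDistanceDistribution(*dist)
    if not 0.0 <= mod_depth <= 1.0:
        raise ValueError("mod_depth must lie in [0, 1]")
    if qF < 0:
        raise ValueError("qF must be non-negative")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    r = dist.grid(n=n_r)
    wts = dist.pdf(r)
    trap = np.full(r.size, r[1] - r[0])
    trap[0] *= 0.5
    trap[-1] *= 0.5
    wts = wts * trap
    wts /= wts.sum()
    phi = dipolar_constant() * np.multiply.outer(1.0 / r**3, tt)
    re, im = fresnel_kernel(phi)
    v = (1.0 - mod_depth) + mod_depth * (wts @ re + 1j * epsilon * qF * (wts @ im))
    return complex(v[0]) if scalar else v
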