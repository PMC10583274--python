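"""Complex-valued least-squares fitting of polarized DEER traces.

The measured echo amplitude factorizes as

    V(t) = V0 · V_intra(t − t0) · V_inter(t − t0),

with the intermolecular factor exp(−k|t−t0|)·exp(i α ε qB k (t−t0)) and, for
biradicals, an intramolecular factor built from a Gaussian distance
distribution with an out-of-phase multiplier qF. Both channels of the
complex trace are fit simultaneously; the polarization ε is always a fixed
input computed from field and temperature, never a free parameter.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore); the
module-level :func:`fit_background` / :func:`fit_biradical` are thin
wrappers that accept a :class:`~deerpol.traces.DeerTrace` and return a
:class:`FitResult` with linearized 95 % confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .intermolecular import ALPHA, BackgroundParams, background_signal
from .intramolecular import GaussianDistanceDistribution, distribution_signal
from .physics import dipolar_constant
from .traces import DeerTrace

__all__ = [
    "BackgroundFitModel",
    "BiradicalFitModel",
    "FitResult",
    "BackgroundModel",
    "BiradicalModel",
    "forward_model",
    "fit_background",
    "fit_biradical",
    "phase_correct",
]


@dataclass
class BackgroundFitModel:
    """Parameters of the monoradical (background-only) trace model.

    ``V(t) = V0 · exp(−k|t−t0|) · exp(i α ε qB k (t−t0))``. ε is a fixed
    experimental input, not a fit parameter.
    """

    V0: float = 1.0
    k: float = 1.0
    t0: float = 0.0
    qB: float = 1.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.qB < 0:
            raise ValueError("qB must be non-negative")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass
class BiradicalFitModel(BackgroundFitModel):
    """Background model extended by the intramolecular pair signal.

    Adds a Gaussian distance distribution (r0, w), the out-of-phase
    multiplier qF, and the modulation depth λ (``mod_depth``).
    """

    r0: float = 3.7
    w: float = 0.2
    qF: float = 1.0
    mod_depth: float = 0.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.qF < 0:
            raise ValueError("qF must be non-negative")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")


def forward_model(model: BackgroundFitModel, t_grid) -> np.ndarray:
    """Evaluate the complex trace model on a time grid (µs)."""
    t = np.asarray(t_grid, dtype=float)
    tau = t - model.t0
    bg = background_signal(
        tau, BackgroundParams(k=model.k, epsilon=model.epsilon, qB=model.qB)
    )
    if isinstance(model, BiradicalFitModel):
        intra = distribution_signal(
            GaussianDistanceDistribution(model.r0, model.w),
            tau,
            model.epsilon,
            qF=model.qF,
            mod_depth=model.mod_depth,
        )
    else:
        intra = 1.0
    return model.V0 * intra * np.asarray(bg, dtype=complex)


@dataclass
class FitResult:
    """Point estimates with linearized 95 % confidence intervals.

    ``ci95`` holds per-parameter half-widths (inf for parameters the data
    carry no information on, which are also listed in ``unidentifiable``).
    ``residual_rms`` holds the root-mean-square residual of each channel.
    """

    estimates: dict
    ci95: dict
    residual_rms: dict
    n_points: int
    converged: bool
    unidentifiable: tuple = ()
    message: str = ""

    def model(self) -> BackgroundFitModel:
        """Rebuild the fitted model dataclass from the estimates."""
        cls = BiradicalFitModel if "r0" in self.estimates else BackgroundFitModel
        return cls(**self.estimates)

    def report(self) -> str:
        """Plain-text 'value(CI)' report in the style of figure captions."""
        lines = [f"n_points = {self.n_points}", f"converged = {self.converged}"]
        for name, val in self.estimates.items():
            ci = self.ci95.get(name)
            if ci is None:
                lines.append(f"{name} = {val:.6g} (fixed)")
            elif np.isinf(ci):
                lines.append(f"{name} = {val:.6g} (unidentifiable)")
            else:
                lines.append(f"{name} = {val:.6g} ({ci:.2g})")
        lines.append(
            "residual_rms = {re:.3g} (in-phase), {im:.3g} (out-of-phase)".format(
                **self.residual_rms
            )
        )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "ci95": dict(self.ci95),
            "residual_rms": dict(self.residual_rms),
            "n_points": self.n_points,
            "converged": self.converged,
            "unidentifiable": list(self.unidentifiable),
            "message": self.message,
        }


_COLNORM_TOL = 1e-9  # Jacobian column norm below this (relative) => no information


class BackgroundModel(BaseEstimator):
    """Least-squares estimator for the monoradical background trace.

    Parameters
    ----------
    epsilon : float
        Fixed spin polarization of the B spins (from field and temperature).
    init : BackgroundFitModel, optional
        Starting point; if None, heuristics are used (k from a log-linear
        fit to |V|, t0 from the |V| maximum, qB = 1).
    channel_weights : tuple of float
        Relative weights of the (in-phase, out-of-phase) residual channels.
    max_nfev : int
        Cap on model evaluations for the trust-region solver.

    Attributes
    ----------
    V0_, k_, t0_, qB_ : float
        Fitted parameters.
    result_ : FitResult
        Full fit report with 95 % confidence intervals.
    """

    _fit_param_names: Sequence[str] = ("V0", "k", "t0", "qB")
    _model_cls = BackgroundFitModel

    def __init__(self, epsilon: float = 0.0, init=None,
                 channel_weights=(1.0, 1.0), max_nfev: int = 5000):
        self.epsilon = epsilon
        self.init = init
        self.channel_weights = channel_weights
        self.max_nfev = max_nfev

    # -- initialization heuristics -------------------------------------
    def _initial_guess(self, t: np.ndarray, V: np.ndarray) -> dict:
        amp = np.abs(V)
        i0 = int(np.argmax(amp))
        t0 = float(t[i0])
        V0 = float(max(amp[i0], 1e-12))
        tau = np.abs(t - t0)
        good = amp > 0.05 * V0
        if good.sum() >= 2 and np.ptp(tau[good]) > 0:
            slope = np.polyfit(tau[good], np.log(amp[good]), 1)[0]
            k = float(max(-slope, 1e-3))
        else:
            k = 1.0
        return {"V0": V0, "k": k, "t0": t0, "qB": 1.0}

    def _bounds(self) -> tuple[list, list]:
        lo = [1e-12, 0.0, -np.inf, 0.0]
        hi = [np.inf, np.inf, np.inf, np.inf]
        return lo, hi

    def _theta_to_model(self, theta: np.ndarray) -> BackgroundFitModel:
        kw = dict(zip(self._fit_param_names, (float(x) for x in theta)))
        kw["epsilon"] = self.epsilon
        kw["V0"] = max(kw["V0"], 1e-12)
        return self._model_cls(**kw)

    # -- sklearn protocol ----------------------------------------------
    def fit(self, t, V=None):
        """Fit the model to a complex trace.

        ``t`` may be a DeerTrace (then V is ignored) or a 1-D time array
        with ``V`` the complex amplitudes (or an (n, 2) real array).
        """
        if isinstance(t, DeerTrace):
            V = t.V
            t = t.t
        t = np.asarray(t, dtype=float).ravel()
        V = np.asarray(V)
        if V.ndim == 2 and V.shape[1] == 2:
            V = V[:, 0] + 1j * V[:, 1]
        V = V.astype(complex).ravel()
        if t.size != V.size:
            raise ValueError("t and V must have equal length")
        if t.size < len(self._fit_param_names):
            raise ValueError("fewer data points than free parameters")
        if np.ptp(np.abs(V)) < 1e-14 and np.ptp(V.real) < 1e-14:
            raise ValueError("degenerate (constant) trace")

        if self.init is not None:
            guess = {name: getattr(self.init, name)
                     for name in self._fit_param_names}
        else:
            guess = self._initial_guess(t, V)
        theta0 = np.array([guess[name] for name in self._fit_param_names])
        lo, hi = self._bounds()
        theta0 = np.clip(theta0, lo, hi)

        w_re, w_im = self.channel_weights

        def residuals(theta):
            pred = forward_model(self._theta_to_model(theta), t)
            return np.concatenate(
                [w_re * (pred.real - V.real), w_im * (pred.imag - V.imag)]
            )

        res = optimize.least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf",
            max_nfev=self.max_nfev,
        )
        self._finalize(res, t, V)
        return self

    def _finalize(self, res, t: np.ndarray, V: np.ndarray) -> None:
        names = list(self._fit_param_names)
        theta = res.x
        J = res.jac
        colnorm = np.linalg.norm(J, axis=0)
        scale = max(colnorm.max(), 1.0)
        identifiable = colnorm > _COLNORM_TOL * scale
        n_res = J.shape[0]
        dof = max(n_res - int(identifiable.sum()), 1)
        ssr = float(2.0 * res.cost)
        s2 = ssr / dof
        ci = np.full(len(names), np.inf)
        if identifiable.any():
            Jg = J[:, identifiable]
            try:
                cov = s2 * np.linalg.pinv(Jg.T @ Jg)
                half = stats.t.ppf(0.975, dof) * np.sqrt(
                    np.maximum(np.diag(cov), 0.0)
                )
                ci[identifiable] = half
            except np.linalg.LinAlgError:  # pragma: no cover
                pass
        model = self._theta_to_model(theta)
        pred = forward_model(model, t)
        rms = {
            "re": float(np.sqrt(np.mean((pred.real - V.real) ** 2))),
            "im": float(np.sqrt(np.mean((pred.imag - V.imag) ** 2))),
        }
        unident = tuple(n for n, ok in zip(names, identifiable) if not ok)
        estimates = {n: float(v) for n, v in zip(names, theta)}
        estimates["epsilon"] = self.epsilon
        ci95 = {n: float(c) for n, c in zip(names, ci)}
        self.result_ = FitResult(
            estimates=estimates,
            ci95=ci95,
            residual_rms=rms,
            n_points=t.size,
            converged=bool(res.success),
            unidentifiable=unident,
            message=res.message,
        )
        self.model_ = model
        for name in names:
            setattr(self, name + "_", estimates[name])

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted model on a time grid."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return forward_model(self.model_, np.asarray(t, dtype=float))


class BiradicalModel(BackgroundModel):
    """Least-squares estimator for biradical traces.

    Simultaneously fits the background parameters and the intramolecular
    factor (Gaussian distance distribution r0, w; out-of-phase multiplier
    qF; modulation depth λ) on the complex trace.
    """

    _fit_param_names = ("V0", "k", "t0", "qB", "r0", "w", "qF", "mod_depth")
    _model_cls = BiradicalFitModel

    def _bounds(self):
        lo = [1e-12, 0.0, -np.inf, 0.0, 0.5, 1e-3, 0.0, 0.0]
        hi = [np.inf, np.inf, np.inf, np.inf, 20.0, 5.0, np.inf, 1.0]
        return lo, hi

    def _initial_guess(self, t: np.ndarray, V: np.ndarray) -> dict:
        guess = super()._initial_guess(t, V)
        V0 = guess["V0"]
        # divide out the decay estimate so the DFT sees the bare oscillation
        bg = V0 * np.exp(-guess["k"] * np.abs(t - guess["t0"]))
        x = V.real / np.maximum(bg, 1e-12 * V0)
        trend = self._smooth_trend(x)
        depth = float(np.clip(1.0 - trend.min(), 0.05, 0.95))
        r0 = self._r0_from_spectrum(t, x)
        guess.update({"r0": r0, "w": max(0.1 * r0, 0.05),
                      "qF": 1.0, "mod_depth": depth})
        return guess

    @staticmethod
    def _smooth_trend(x: np.ndarray) -> np.ndarray:
        win = min(2 * (x.size // 6) + 1, x.size - 1 - (x.size % 2))
        if win < 5:
            return np.full_like(x, x.mean())
        return savgol_filter(x, win, 3)

    @classmethod
    def _r0_from_spectrum(cls, t: np.ndarray, x: np.ndarray) -> float:
        """Distance guess from the dominant dipolar frequency (DFT peak).

        The slowly varying decay transient is removed with a smoothing
        filter; the perpendicular-orientation singularity then dominates
        the dipolar spectrum, so the peak frequency ν of the in-phase
        channel maps to r0 ≈ (D / 2πν)^(1/3).
        """
        dt = float(np.median(np.diff(t)))
        x = x - cls._smooth_trend(x)
        spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=4 * x.size))
        freq = np.fft.rfftfreq(4 * x.size, dt)  # cycles/µs
        spec[freq <= 0.15] = 0.0  # discard residual-decay leakage at DC
        if not spec.any():
            return 3.0
        nu = freq[int(np.argmax(spec))]
        r0 = (dipolar_constant() / (2.0 * np.pi * nu)) ** (1.0 / 3.0)
        return float(np.clip(r0, 1.0, 8.0))


def _coerce_trace(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, DeerTrace):
        return trace.t, trace.V
    t, V = trace
    return np.asarray(t, dtype=float), np.asarray(V, dtype=complex)


def fit_background(trace, epsilon: float, init: BackgroundFitModel | None = None,
                   **kwargs) -> FitResult:
    """Fit the monoradical background model to a complex trace.

    Warns when the trace is short or one-sided in t − t0, where qB (which
    multiplies the odd-in-t phase) is only weakly identified.
    """
    t, V = _coerce_trace(trace)
    t0_guess = init.t0 if init is not None else float(t[np.argmax(np.abs(V))])
    if t.size < 8 or not (t.min() < t0_guess < t.max()):
        warnings.warn(
            "trace should span >= 8 points on both sides of t0 for a "
            "well-identified qB",
            stacklevel=2,
        )
    est = BackgroundModel(epsilon=epsilon, init=init, **kwargs).fit(t, V)
    return est.result_


def fit_biradical(trace, epsilon: float, init: BiradicalFitModel | None = None,
                  **kwargs) -> FitResult:
    """Fit the biradical model (background × intramolecular) to a trace.

    Warns when the trace does not cover one full dipolar oscillation period
    of the (initial) r0, where r0 is weakly identified.
    """
    t, V = _coerce_trace(trace)
    r0_guess = init.r0 if init is not None else \
        BiradicalModel._r0_from_spectrum(t, np.asarray(V).real)
    period = 2.0 * np.pi * r0_guess**3 / dipolar_constant()
    if np.ptp(t) < period:
        warnings.warn(
            "trace covers less than one dipolar oscillation period; r0 is "
            "weakly identified",
            stacklevel=2,
        )
    est = BiradicalModel(epsilon=epsilon, init=init, **kwargs).fit(t, V)
    return est.result_


def phase_correct(trace: DeerTrace, t_ref: float = 0.0):
    """Zeroth-order phase a trace to the point nearest ``t_ref``.

    Rotates the complex trace so the imaginary part vanishes and the real
    part is positive at the reference point (default: zero time). Returns
    the rotated trace and the applied rotation angle in radians.
    """
    idx = int(np.argmin(np.abs(trace.t - t_ref)))
    v_ref = trace.V[idx]
    if abs(v_ref) < 1e-300:
        raise ValueError("zero amplitude at the phase reference point")
    applied = -float(np.angle(v_ref))
    V = trace.V * np.exp(1j * applied)
    meta = dict(trace.meta)
    meta["phase_applied_rad"] = applied
    return DeerTrace(t=trace.t.copy(), re=V.real, im=V.imag, meta=meta), applied
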