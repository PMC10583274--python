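# Methods

## Signal model

The measured four-pulse DEER echo amplitude is modeled as the product
`V(t) = V0 · V_intra(t − t0) · V_inter(t − t0)` of an overall amplitude, an
intramolecular factor from the spin pair on the labeled molecule, and an
intermolecular (background) factor from pumped spins on other molecules.
All components are complex: at spin polarization ε > 0 the echo acquires an
out-of-phase quadrature component. ε is treated as a known experimental
quantity, `ε = tanh(ge µB B / 2 kB T)`, computed from field and temperature
— never fitted — because it is fixed by the conditions of the measurement.

**Assumptions.** Spin-1/2 pairs in the weak-coupling (secular dipolar)
regime, i.e. the dipolar frequency is small against the A–B resonance
offset; isotropic orientation distribution (frozen glassy solution, no
orientation selection); dilute spins with couplings among pumped B spins
neglected; ideal rectangular pump inversion characterized by a single
efficiency pB. Exchange coupling, g/hyperfine anisotropy of the individual
signal, and excluded-volume background corrections are out of scope.

**Pair and powder signal.** The elementary signal is
`V_AB = (1 − pB) + pB[cos ωt + iε sin ωt]` with
`ω = D (1 − 3cos²θ)/r³`. Averaging over cosθ uniform in [0, 1] gives the
closed form in Fresnel integrals C, S of `z = sqrt(6φ/π)`, `φ = Dt/r³`:

    V(φ) = [C(z)cos φ + S(z)sin φ]/z  +  iε [C(z)sin φ − S(z)cos φ]/z.

For φ < 0 the identities C(ia) = iC(a), S(ia) = −iS(a) reduce both parts to
real expressions: the real part is even in φ, the imaginary kernel odd, so
the signal is Hermitian about zero time. Below |φ| = 1e-8 the kernel is
evaluated by its leading series (real ≈ 1 − 2φ²/5, imag ≈ φ³/3) to avoid
0/0 in the closed form.

**Background.** For a uniform random 3-D distribution of B spins at number
density nB, the configuration-averaged product of pair signals evaluates to
`V_inter = exp(−k|t|)·exp(iαεkt)` with `k = (8π²/9√3) pB nB D`. The
dimensionless constant α is stored as the numeric value 0.13213; its
symbolic form is not used, and the value is validated independently by the
Monte Carlo oracle (below). The out-of-phase channel is extremal at
`t_OOP = arctan(αε)/(αεk)` (≈ 1/k to better than 1 % since αε ≤ 0.133),
where the magnitude has decayed to e⁻¹ and the out-of-phase amplitude is
`exp(−arctan(αε)/αε)·αε/sqrt(1+(αε)²)`; the package reports the customary
leading approximation e⁻¹αε ≈ 0.0486 ε unless the exact form is requested.
The Fourier transform is the printed Lorentzian `2πk/(k² + (ω + αεk)²)`,
peaked at −αεk with FWHM 2k; note this normalization integrates to 2π²
rather than the 2π of a unit-normalized transform — peak position and
width, which are what the package checks, are unaffected.

## Fit models and estimation

Monoradical traces are fit with
`V0 · exp(−k|t−t0|) · exp(iαεqB k(t−t0))`; the phenomenological factor qB
scales the phase slope only (never the envelope) and equals 1 if the
theory is exact. Biradical traces multiply in the intramolecular factor
`(1 − λ) + λ ∫P(r)[Re(φ) + iεqF Im(φ)]dr` with a Gaussian `P(r)` (peak r0,
standard deviation w), an analogous out-of-phase factor qF, and a
modulation depth λ (equal to pB for an ideal pump; kept free because real
pulses invert imperfectly). The distance integral uses a 201-point
trapezoid rule on r ∈ [max(0.1 nm, r0 − 6w), r0 + 6w] with weights
renormalized over the truncated grid, so V(0) = 1 holds exactly.

Both quadrature channels are stacked with equal weight (no per-channel
noise model is assumed; optional weights are exposed) and minimized with a
trust-region-reflective least-squares solver under the physical bounds
(V0, k, qB, qF ≥ 0; λ ∈ [0, 1]). Starting values are derived from the data:
t0 from the amplitude maximum, k from a log-linear fit of |V|, r0 from the
dominant dipolar frequency of the in-phase channel after dividing out the
decay estimate and removing the residual transient with a Savitzky–Golay
trend, λ from the depth of that trend, qB = qF = 1. All heuristics can be
overridden via an explicit initial model.

**Confidence intervals** are linearized: with residual Jacobian J and
s² = SSR/dof, the per-parameter 95 % half-width is
`t(0.975, dof)·sqrt(diag(s²(JᵀJ)⁻¹))`. Jacobian columns with vanishing
norm (relative tolerance 1e-9) indicate parameters the data carry no
information on — qB when ε = 0, or (r0, w, qF) when λ = 0 — and are
reported as unidentifiable with infinite CI rather than silently inverted.
Parameter-recovery simulations (200 replicates, σ = 0.005–0.01, 80–120
points) show nominal coverage: the linearized SEs agree with the
dispersion of a 2000-draw noise-projection experiment to better than 1 %.

**Phasing** is zeroth-order only: the trace is rotated so the point nearest
the dipolar zero time is real and positive, and the applied angle is always
reported. The reference time is the echo refocusing point because the model
predicts a strictly real signal there regardless of ε.

## Monte Carlo spin-bath oracle

The closed-form background is validated by direct simulation: B spins are
placed uniformly at random in a ball of radius R around a central A spin
(count fixed at round(density·volume); the difference from Poisson counts
is O(1/N) and immaterial at N ≈ 1300), each with cosθ uniform in [−1, 1],
and the echo signal of one configuration is the product of pair signals.
No minimum distance is excluded around the A spin — the ideal dilute theory
integrates to r → 0 and the fast oscillations of close spins average out;
an optional exclusion radius is provided for sensitivity analysis. A master
seed spawns per-configuration substreams, making ensembles reproducible.
The ball radius must satisfy `D/R³ · max|t| < 0.01 rad` so truncation of
the bath is negligible; the default R = 80 nm at 1 mM holds ~1291 spins.

At the reference conditions (1 mM, pB = ε = 1), 2000 configurations
reproduce the closed form pointwise within 3 standard errors on t ∈ [0, 4]
µs and recover k within 5 % from the decay of the ensemble mean (points
with |mean| > 10× its standard error). The phase-slope estimate of α is
much noisier than the amplitude observables because the phase is small
(αk·t ≤ 0.066 rad on the fit window) while its per-point error grows with
the decaying amplitude, and errors are correlated across time points: its
relative spread is ≈26 % at 2000 configurations. The α-recovery check
therefore uses 100 000 configurations (spread ≈4 %), which keeps a 10 %
comparison against 0.13213 meaningful at desk scale (~1 min on one CPU).

## Synthetic traces

`synthesize_trace` evaluates a forward model on a time grid and adds i.i.d.
zero-mean Gaussian noise of equal standard deviation to both channels,
emulating quadrature detection with a common noise floor. Default study
conditions follow the regimes the model addresses: monoradical traces at
1 mM, pB = 1 (k ≈ 1 µs⁻¹), ε = 0.70 (6.42 T / 5 K) or 0.07 (1.21 T / 11 K),
80 points spanning [−1, 5] µs; biradical traces with r0 = 3.7 nm,
w = 0.2 nm, 0.5 mM total spin background. What synthetic data do not
contain: detector phase drift and gain imbalance, orientation selection,
nuclear modulation (ESEEM), baseline distortions, and any deviation of the
true background physics from the model (the experimental finding qB > 1
cannot arise in data generated from the model itself). Passing recovery
tests therefore demonstrate estimator correctness under the stated model,
not robustness to instrumental artifacts.

## Numerical choices

* Units: µs, rad/µs, nm, T, K, mM at the API surface; concentrations
  convert internally to nm⁻³ (1 mM = 6.022e-4 nm⁻³).
* Constants: CODATA-2018, hard-coded; g fixed to 2.00232 by default with a
  per-call override; D = 326.98 rad µs⁻¹ nm³ (D/2π = 52.04 MHz nm³).
* Sign conventions: phase factor +iαεkt, Fourier peak at −αεk, positive
  out-of-phase extremum at positive t for ε > 0.
* t_OOP uses the analytic ε → 0 limit 1/k below αεqB = 1e-12.
* Degenerate inputs raise ValueError (non-positive r, T, k; concentrations
  < 0; constant traces; zero amplitude at the phasing reference).

## Known limitations

The theory underpredicts the out-of-phase background seen in real
measurements (fitted qB of 2–4 at high polarization); the package models
this with the phenomenological qB but contains no physics for its origin
(candidate mechanisms such as B–B flip-flops are not implemented). Only
Gaussian distance distributions are supported — no Tikhonov/model-free
P(r). Vendor spectrometer formats are not read; traces must be converted
to delimited text first.
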