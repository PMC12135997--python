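# Methods

This note records the models, numerical choices and known limitations of
saskit, in the package's own words. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions and data model

Momentum transfer is `s = 4π sin θ / λ`, so a real-space repeat `d`
produces a Bragg peak at `s = 2π/d`. Units (nm⁻¹ vs Å⁻¹) are carried as
metadata and never converted silently — unit confusion is the classic SAS
bug, and an explicit CLI flag is the only way to change the declaration.
A `Curve` is the triple (s, I, σ) with σ = NaN where an uncertainty is
missing; such points are simply excluded from weighted fits rather than
given an invented weight. A `FrameSeries` is the SEC-SAXS matrix D
(m frames × n angles) on one bit-identical grid; the first frame's grid is
canonical and later frames must match it to 1e-9 relative.

The `.dat` dialect is deliberately permissive: leading non-numeric lines
are header, the first whitespace-separated line whose tokens are mostly
numeric starts the data, two-column rows are accepted with the
uncertainty flagged missing. Writing uses 14 significant digits so a
write→read round trip is the identity to better than 1e-12.

## Synthetic data

The generator is the ground-truth source for every downstream test. A
SEC-SAXS series is built as `D = C Sᵀ (+ noise)`: Gaussian elution
profiles in frame index (an exponentially modified Gaussian tail is
available via `skew_tau` where asymmetry matters), and component curves
taken from the mixture module's form factors, normalised to unit forward
scattering so the stated amplitudes are peak heights. Noise emulates
photon counting, `σ_ij = noise_scale · √max(D_ij, floor)`: weak frames
are relatively noisier, and the floor keeps least-squares weights finite
where D ≈ 0.

The default study condition is two spheres (R = 3 and 5 nm) eluting at
frames 45 and 56 with width 8 — a centre separation of ~1.4 σ, at which
the two Gaussians overlap by roughly half their area — and
`noise_scale = 0.01`, i.e. 1% relative noise at unit intensity. These
defaults are what the recovery suites and the acceptance script run on.

What the generator does **not** emulate: skewed/tailing real SEC peaks
(unless asked for), baseline drift, inter-frame radiation damage,
detector smearing and incoherent background. Passing tests therefore
demonstrate correctness of the algebra and robustness to counting-type
noise, not performance on pathological beamline data.

## Chromatogram analysis

The trace is the **mean** intensity per frame over an s-window (mean, not
sum, so the value does not depend on grid density). Peak detection runs
on a 5-frame centred moving average and keeps local maxima whose
prominence exceeds a fraction (default 0.1) of the trace span; peak bases
sit where the trace has descended by 90% of the prominence. The paper
behind the original tool does not publish its automatic region criterion,
so this prominence/variance scheme is the package's own documented rule:
the suggested buffer is the minimum-variance contiguous window outside
all peak bases, with ties resolved to the earliest window, and it is
tested against exhaustive search.

Subtraction averages sample and buffer frames with
`σ_mean = √(Σσ²)/N` and differences them with quadrature error
propagation. An optional consistency screen drops frames whose reduced χ²
against the running average exceeds 3.0 — a deliberate simplification of
full pairwise similarity testing, which is out of scope.

## Guinier and Porod analysis

The Guinier fit is weighted linear least squares of ln I on s², with
weights (I/σ)² from error propagation; a non-negative slope returns a
flagged "no Guinier region" result rather than an exception, because on a
chromatogram many frames legitimately have none. The automatic range is a
deterministic fixed point: fit the first 10 positive points, re-select
all points with `s·Rg ≤ 1.3` (the globular-particle convention; there is
no universal rule), refit, repeat to convergence (≤ 50 rounds).

One accuracy note computed by the tests: for an ideal sphere the Guinier
approximation itself carries a truncation bias of about +1% in Rg when
the fit extends to `s·Rg = 1.0`; the recovery tests use a log-spaced
(low-s dense) grid, where the measured error is 0.9%. On a uniform grid
it is marginally above 1%. This is a property of the approximation, not
of the fitting code.

The Porod invariant `Q = ∫ s²I ds` uses trapezoidal integration plus an
analytic tail `K/s_max` assuming Porod behaviour `I → K/s⁴`. K is taken
from the flattest window (lowest relative spread, 20 points) of `s⁴I`
among the last decade of the curve, which averages over form-factor
oscillations. `Vp = 2π² I(0)/Q`, and `MW ≈ Vp/1.6` (nm³ per kDa, divisor
configurable) — the classical rule of thumb; the original program's exact
MW recipe is unpublished, so the divisor is exposed rather than hidden.

## Evolving factor analysis

Forward/backward EFA computes the leading k+1 singular values of every
growing prefix/suffix of D. The noise floor is the median (k+1)-th
singular value; component i's window starts where forward singular value
i+1 exceeds 5× that floor and ends where the matching backward value
(k−i-th, i.e. components leave in the order they arrived) falls below it.
The factor 5 is a documented default (`noise_factor`), not published by
the original tool. Windows are forced into first-in/first-out order; if a
threshold is never crossed the error message suggests a smaller k —
singular values at the numerical-noise floor of noiseless data are not a
reliable detection signal, so rank-deficiency detection is only
meaningful when real noise defines the floor.

Rotation: with `M = U_k Σ_k`, column i of the rotation R is the
least-squares null vector (smallest right singular vector) of the rows of
M outside window i, oriented to make the in-window concentration
positive. Identical windows are rejected, not perturbed. The algebraic
solution is then refined by alternating least squares with the window
masks and non-negativity clipping on C (tolerance 1e-10 on the relative
residual change, ≤ 1000 iterations) because the pure null-space rotation
is fragile at realistic noise. Finally S = C⁺D and each C column is
scaled to maximum 1 (the usual scale indeterminacy of bilinear models).
The relative Frobenius residual is always reported; by construction it
cannot beat the rank-k SVD optimum, and the tests assert both the lower
bound and closeness to it on noiseless data. k is always user-supplied;
a singular-value scree is printed as advice but never auto-applied.

## Bragg-peak analysis

Profiles are parameterised by position, FWHM and **integrated area**
(not height), so changing the Lorentzian fraction η cannot silently
rescale the intensity; Gaussian and Lorentzian are unit-area normalised
and mixed as `η·L + (1−η)·G`. The background is linear in s — the
minimal two-parameter choice. Fitting is bounded weighted least squares
(scipy trust-region reflective): FWHM above the grid step, η in [0, 1],
positions inside the grid; all peaks and the background refine
simultaneously.

Order parameters derive from one constants table, echoed in every
result because different communities use different prefactors:
`d = 2π/s0`; `L = 2πK/fwhm` with Scherrer-type K = 1; `Δ/d =
(1/π)√(fwhm·d/2)` (paracrystalline next-neighbour disorder, Vainshtein-
style); `R_m = L/2`. Each constant is overridable per call.

## Mixture modelling

Form factors are per-particle intensities in units of (Δρ·V)²: the
sphere amplitude `Φ(x) = 3(sin x − x cos x)/x³` (series-expanded below
x = 1e-4), core-shell as the contrast-weighted difference of two sphere
amplitudes, ellipsoid of revolution and cylinder by 64-node
Gauss-Legendre orientational averaging in cos α (exact for the smooth
integrands at the default node count; the ε = 1 ellipsoid reproduces the
sphere to 1e-8).

Polydispersity is a **number average** over the size distribution on the
leading dimension (the original tool does not say which average it uses;
number averaging is the documented choice here). Gaussian distributions
are truncated at zero and integrated over ±4 relative widths with 51
fixed Gauss-Legendre nodes; the Schulz (gamma) distribution uses the same
quadrature against its density with an extended upper span for its heavy
tail. Doubling the node count moves results by less than 1e-4, which the
tests check for both distributions; a closed-form Schulz sphere average
exists but a single quadrature path is simpler to verify and its accuracy
is covered by the same test.

The bilayer model is the three-Gaussian electron-density profile:
headgroup Gaussians (ρ_H, σ_H) at ±z_H and a methyl trough (ρ_C < 0,
σ_C) at the centre, giving the analytic amplitude
`F(s) = √(2π)[2σ_Hρ_H cos(s z_H)e^(−σ_H²s²/2) + σ_Cρ_C e^(−σ_C²s²/2)]`.
Multilamellarity multiplies F² by a paracrystalline stacking factor
`S(s) = N + 2Σ(N−j)cos(jsd)e^(−js²σ_d²/2)` (equal to N² at the Bragg
position for σ_d = 0), normalised per bilayer so N = 1 reduces exactly to
the diffuse term; `f_diffuse` mixes unilamellar and stacked populations.
A 1/s² Lorentz factor applies for s > 0 (skipped at s = 0 to keep the
value finite; disablable). Modified Caillé theory is deliberately out of
scope — the paracrystalline factor is simpler and desk-testable.

Mixtures combine components as `I = Σ v_k I_k/V_k` (volume-fraction
weighting of per-particle intensities; the weighting convention is a
config-level choice since the original is unstated), optionally times the
analytic Percus-Yevick hard-sphere structure factor. Fitting solves the
overall scale analytically at every step and reparameterises volume
fractions through a softmax so Σv = 1 holds without a constrained
optimiser. Because oscillatory form factors make the χ² surface
multimodal in the particle dimensions, the fit restarts from a small
deterministic grid of rescaled geometric initials (factors 0.85/1/1.18
per free length, up to three) and keeps the best final cost; chained
batch fits skip the multi-start since each frame starts at the previous
optimum. With it, two-sphere volume fractions are recovered to ~3e-4
(median) at 1% noise and ±20% initial errors; without it roughly half of
such starts land in local minima.

## Problem sizes

The recovery suites run 20 replicates each: EFA on 100-frame × 100-point
series, peak fitting on 600-point patterns, mixture fitting on 200-point
curves. These sizes give stable statistics while keeping the full suite
and the acceptance script fast; all quantities are recomputed from
scratch on every run.

## Known limitations

- Automatic Guinier range selection assumes a monotone low-s region; it
  does not detect aggregation or inter-particle repression upturns.
- EFA window prediction needs genuine measurement noise to define its
  floor; on noiseless data the thresholds reflect numerical rank only.
- The paracrystalline stacking factor requires an integer number of
  lamellae; a distribution over N is not modelled.
- `D_max`/P(r) inversion, CorMap-style frame similarity, modified Caillé
  theory and automatic component-count selection are out of scope.
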