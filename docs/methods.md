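# Methods

## Forward model

The acoustic pressure spectrum recorded by an ideal point detector at
`r_m` for wavenumber `k_n = 2π f_n / c` is modelled as the discretised
outgoing spherical-wave superposition

    Φ[(m,n),(i,j)] = −i c k_n exp(i k_n d) / d,   d = |r_m − r_ij|,

acting on the flattened absorbed-energy image `x` (pixel centres
`r_ij`).  Units are mm and µs: frequencies in MHz, sound speed default
`c = 1.5` mm/µs (1500 m/s, soft tissue), wavenumbers in rad/mm.  The
thermoacoustic prefactor (volume-expansion coefficient over specific
heat) is set to 1, so image and measurements share one arbitrary
positive scale; all metrics compare against phantoms simulated through
the same operator, which this convention does not affect.

Geometry defaults: a 30 mm × 30 mm field of view at 128×128 (pixel
0.234 mm); detectors equally spaced on a 90° arc of radius 30 mm
(outside the 21.2 mm field-of-view half-diagonal); per detector, 64
frequencies drawn without replacement from 128 candidates equally
spaced over [0.2, 2.5] MHz, independently per detector from one seeded
RNG stream.  The operator is stored dense, single-precision complex by
default (the full 5120×16384 protocol is ≈0.7 GB); small builds used in
exactness tests are double precision.

Two spectral consequences of this acquisition matter for everything
below.  The transducer band [0.2, 2.5] MHz corresponds to wavenumbers
[0.84, 10.5] rad/mm: image content smoother than ≈7.5 mm and sharper
than ≈0.6 mm is never measured.  And a 90° arc observes only half of
the spatial-frequency directions (the "visible cone"); the orthogonal
directions are invisible to the data and can only be supplied by the
sparsity prior.

## Phantoms and noise

Phantoms are sparse sets of circular absorbers (default five disks,
radii 0.5–1.5 mm, intensities 0.4–1.0) placed uniformly at random with
a margin keeping every disk inside the field of view; overlaps take the
maximum; images are affinely rescaled to [0, 1].  Disks keep the ground
truth analytic and the image sparse both in pixels and under wavelets.

Measurement noise is white complex Gaussian at a vector-level SNR: the
total noise power is `‖y‖² · 10^(−SNR_dB/10)`, split equally between
real and imaginary parts of every sample.  At the default 2560-sample
length the realised SNR concentrates within ±0.5 dB of the target.

## Sparsifier

An orthonormal 2-D Symmlet-4 wavelet transform, four decomposition
levels, periodised boundaries.  Periodisation with an orthogonal filter
bank is exactly orthonormal on dyadic grids, so synthesis is both the
inverse and the adjoint of analysis, Parseval holds to machine
precision, and the stopping criterion measured on coefficients equals
the one measured on images.  An identity "transform" is provided for
pixel-domain sparsity experiments.

## Solver

The unconstrained basis-pursuit-denoising problem

    min_θ ‖θ‖₁ + (1/2μ) ‖y − A θ‖²,   A = ΦΨ⁻¹ in stacked-real form,

is solved by a primal alternating-direction iteration: exact update of
the auxiliary residual `r`, one proximal-gradient (shrinkage) step on
`θ`, relaxed ascent on the multiplier `λ`.  The shrink threshold is
τ/β, the proximal weight implied by the β-weighted quadratic
subproblem; this convention reproduces the separable closed form
`θ* = shrink(y, μ)` when `A = I`, which the alternative τ·β convention
(selectable for comparison) does not.  Complex data are handled by
stacking real and imaginary parts, keeping all iterates real.

Default parameters, derived from the data: `β = 1/mean|y_i|`;
`τ = 0.99/L` with `L` a 20-step power-iteration estimate of ‖A‖²;
`γ = 1`; `μ = 10⁻⁶·max|A^T y|` for noiseless data (the basis-pursuit
limit) or `0.3·σ_w` under noise, where `σ_w` is the per-component noise
level of the (whitened) system — a fraction of the noise floor sitting
between the risk-minimising and universal thresholds, calibrated once
on the synthetic study.  Iteration stops when the relative coefficient
change δ falls below 0.005 (the comparison protocol used throughout),
or, in high-accuracy mode (`kkt_tol`), when the first-order subgradient
certificate of the objective is met — near the basis-pursuit limit the
coefficient iterate can go numerically quiescent for long stretches
while the multiplier still relaxes at rate ≈γμβ per iteration, so δ
alone is not a reliable optimality signal at tiny μ.

## Row whitening (preconditioning)

Neighbouring frequencies at one sensor see almost the same image, so
the rows of Φ are strongly correlated and the Gram spectrum spans many
orders of magnitude.  Un-preconditioned first-order L1 solvers then
need tens of thousands of iterations.  The default pipeline therefore
left-multiplies the system by `(ΦΦ^H + ε·s·I)^(−1/2)` (Cholesky-based;
`s` is the mean Gram diagonal), which orthonormalises the informative
rows while damping near-null ones.  For noiseless, consistent data this
rescales equations without changing their solution set, hence leaves
the basis-pursuit solution untouched; convergence drops to tens of
iterations.  Defaults: `ε = 10⁻¹⁰` noiseless; with noise,
`ε = 10^(−SNR_dB/10)` — the noise-to-signal power ratio, so directions
whose eigenvalue falls below the noise floor are damped rather than
amplified (a Wiener-style choice) — and the data-fidelity weight μ is
driven by the post-whitening noise level, estimated from the exact
noise model and a stochastic probe of ‖L⁻¹‖²_F.

## Baselines and oracles

* **Adjoint backprojection**: `rescale_unit(Re(Φ^H y))`.  A qualitative
  stand-in for classical full-data reconstruction — not a filtered
  backprojection — used to exhibit limited-view streaks and as the
  comparison baseline.
* **Monotone FISTA** with gradient-scheme adaptive restart: an
  algorithmically independent solver for the same objective; without
  restart its momentum oscillates essentially forever at tiny μ.
* **LP basis pursuit**: the equality-constrained L1 problem solved
  exactly through the split positive/negative linear program (HiGHS),
  with the dual certificate returned; limited to ≤500 unknowns.

On seeded Gaussian instances (40×100, 5-sparse, noiseless, μ = 10⁻⁶)
the three routes agree to ~10⁻⁷ relative, and converged ADM solutions
satisfy the subgradient optimality check to ~10⁻⁵.

## Metrics and study harness

Relative error `RelErr = ‖x′ − x‖/‖x‖ × 100%` and reconstruction SNR
`20 log₁₀(‖x‖/‖x′ − x‖)` dB (so SNR = −20 log₁₀(RelErr/100)).  The SNR
formula is a package convention; its values are comparable within this
artifact only.  Sweep harnesses re-run the study over detector counts
or noise levels with fresh frequency draws and noise per repetition,
identical stopping everywhere, per-run seeds recorded, and means with
standard deviations reported.  Cross-solver cost is counted in operator
applications (two per ADM iteration), not wall-clock time.

## Problem sizes

The full-protocol recovery runs at 128×128 with 80 positions × 64
frequencies.  The noise sweep (40 positions; noiseless, 30, 20, 10 dB)
and the detector-count sweep (16, 40, 80 positions) run on a 48×48
discretisation of the same 30 mm field of view with three repetitions —
desk-scale versions of the same physical protocol.

## What the synthetic study does and does not show

The generator emulates idealised point detectors, exact knowledge of
the forward operator, white Gaussian noise, and analytically known
compact absorbers.  It does not model transducer impulse response or
finite aperture, acoustic heterogeneity, optical fluence, 3-D
propagation, or model mismatch; passing tests therefore demonstrate the
solver and protocol, not performance on experimental data.

Known limitation, quantified in the error spectrum: at the full
128×128 / 80-position protocol the converged wavelet-sparse solution
retains ≈20–25% relative error, essentially all of it either in the
invisible direction cone of the 90° view or above the 2.5 MHz cutoff
(sharp disk edges); the sub-0.2 MHz hole is fully recovered by the
prior.  The same physical protocol discretised at 48×48 — where the
band covers the grid's spectrum — recovers to ≈0.7–3.6% depending on
detector count.  Pixel-domain sparsity (identity transform) recovers
point-like phantoms exactly even at 128×128, the wavelet prior being
the weaker constraint along invisible directions.

## Numerical choices

Shrinkage maps threshold-boundary values exactly to zero.  δ at a zero
previous iterate is defined as 0 if the step is also zero (so `y = 0`
converges to `θ = 0` in one iteration) and ∞ otherwise.  Non-finite
iterates raise a numerical-failure error naming the iteration; reaching
`max_iter` flags the result as not converged without raising.  Sweep
cells that fail are recorded and the sweep continues.  Sub-seeds for
sweep cells derive from `numpy.random.SeedSequence(base_seed, condition,
repetition)`.  The Gram matrix for whitening is accumulated blockwise in
double precision; the whitened operator is stored in single precision.
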