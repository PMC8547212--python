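# Methods

## The mSMR model

The package analyses photon-count traces from confocal fluorescence
fluctuation experiments (single-photon excitation, one detection
channel).  The central statistic is Mandel's Q parameter of the counts
k accumulated over bins of width T,

    Q(T) = (⟨k²⟩ − ⟨k⟩² − ⟨k⟩) / ⟨k⟩,

which is 0 for Poisson light, and its normalisation, the *mean
single-molecule rate*

    μ(T) = Q(T) / T.

For N independent molecules diffusing through a 3D Gaussian detection
volume (lateral 1/e² radius r0, axial radius z0, aspect ratio
r = z0/r0 ≥ 1), the first two sampling-time-dependent intensity
cumulants give

    μ(T) = γ₂ · μ0 · Γ_diff(T) · Γ_iso(T),

with γ₂ = 1/(2√2) the Gaussian PSF shape factor, μ0 the detected count
rate of a single molecule at the PSF maximum, and the binning functions

    Γ(T) = (2/T²) ∫₀ᵀ (T − τ) g(τ) dτ

of the diffusion kernel g_3DG(τ) = [(1+τ/τD)√(1+τ/(r²τD))]⁻¹ and the
on/off blinking kernel g_iso(t) = 1 + F/(1−F)·e^(−t/τF).  The
amplitude of μ(T) at short T is γ₂μ0/(1−F) (γ₂μ0 without blinking) and
its decay with T encodes the diffusion time τD, from which
D = r0²/(4τD).  The model assumes timescale separation (blinking much
faster than diffusion: the two kernels' binning functions factorise),
identical non-interacting emitters, and a stationary trace.

Blinking is modelled as a binary bright/dark system; a DNA molecule
carrying M dyes is really an (M+1)-state birth–death chain, but the
binary form describes curves well and is the deliberate model scope
here; multi-exponential blinking and 2D membrane diffusion are out of
scope.

## Numerical choices

* **Closed forms vs series.** Γ_diff has two closed-form branches (r=1
  and the artanh form for r>1).  Both lose ~1e-8 relative accuracy to
  cancellation near α = T/τD ≈ 1e-3, so for α < 5e-3 a 5-term Taylor
  series is used (coefficients c_m = (−1)^m Σ_j C(2j,j)(β/4)^j,
  β = r⁻²); it agrees with adaptive quadrature to ≤4e-13 there.  The
  r=1 branch is selected when |β−1| < 1e-6 because the artanh branch
  degenerates to 0/0 as β→1.  Note that the *true* Γ_diff at
  r = 1+1e-5 differs from r = 1 by up to ~6e-6 at large α, so branch
  continuity is meaningful (and asserted, to 1e-6 relative) only at the
  switch tolerance itself.
* **Γ_iso cancellation.** For x = T/τF < 1e-4 the exact expression
  suffers x + expm1(−x) cancellation and a series
  1 − x/3 + x²/12 − x³/60 + x⁴/360 is used.
* **artanh domain.** The artanh argument is checked against (−1, 1)
  and raises rather than clamping silently.
* **Moments.** Raw moments are computed via `bincount` plus
  unbounded-integer powers: exact for arbitrary trace lengths and
  count magnitudes (⟨k³⟩ of long bright traces overflows int32 and
  loses bits in naive float accumulation).
* **Quadrature oracles.** Each closed form has an adaptive-quadrature
  counterpart (`*_numeric`, scipy `quad` at 1e-12 relative) that
  integrates the kernel directly; tests compare the two routes.
* **Degenerate inputs.** Sampling times with zero mean count are
  dropped (never imputed); a curve with fewer than 4 valid points is an
  error; Q of a constant trace is exactly −1; rebinning by a
  non-divisor factor is an error, never a truncation.

## The empirical curve

The trace is rebinned at every integer divisor d of its length
(exact matrix-free reshape+sum), and Q, μ computed per sampling time
T = d·Δ.  The default maximum T is T_obs/100 so every point is an
average over ≥100 bins; the second-moment estimator variance explodes
with fewer.  The divisor grid is used as-is for fitting (no
logarithmic thinning).  Replicates can be combined by averaging curves
on a shared grid before fitting (used for simulation validation) or by
fitting each and averaging parameters (typical for measurements); both
are provided.

## Detector corrections

Measured moments are corrected jointly for first-order afterpulsing
(probability P_A) and dead time (δ = t_dead/T) before Q is formed;
background is corrected at curve level by the constant factor
(1 − ⟨b⟩/⟨k⟩)⁻¹, with ⟨b⟩ from a blank measurement.  Correction order
is fixed: dead time and afterpulsing together (their first-order
equations are coupled), then background.  The moment correction is
first-order only and valid for ⟨k⟩δ ≪ 1; the implementation warns above
⟨k⟩δ = 0.1 and refuses above 0.5.  Stored curves keep the *measured*
moments alongside corrected Q/μ, so the background ratio ⟨b⟩/⟨k⟩ stays
exactly T-invariant (asserted to 1e-9) even after moment corrections.

For testing, artefacts are *injected* synthetically: dead time by
per-bin thinning (uniform arrival times within the bin, greedy removal
within t_dead — cross-bin blanking neglected), afterpulsing by adding
an extra count per detection with probability P_A into the same or
next bin, background as added Poisson counts.  These generators exist
only to verify correction direction and approximate magnitude; the
first-order correction recovers most but not all of the injected
dead-time deficit (the injection is exact, the correction first-order),
which the tests reflect.

## The simulator

The Monte Carlo generator is the package's ground-truth instrument: a
lattice random walk (one step per time slice along ±x/±y/±z with
probability 1/6 each, *not* Gaussian displacements — the recovery
statistics of the lattice scheme, e.g. a fitted D of ~53 µm²/s for an
input of 50, are part of what the method validation reproduces) in a
periodic box of 12·r0 × 12·r0 × 12·z0.  The time slice is
Δt = ε²/(6·D_fast) with maximum step ε = 20 nm; slower species step
√(6DᵢΔt).  Emission per slice is Poisson(μ0·Δt·PSF(r)), summed over
particles (a superposition of independent Poisson draws, sampled as one
Poisson of the summed intensity — exact and fast).  Defaults: uniform
initial placement (the stationary density under periodic wrapping, so
no burn-in), output bins of 1 µs rounded to the nearest multiple of Δt,
one seeded NumPy generator with a fixed vectorization chunk so traces
are bit-reproducible given a seed; replicate runs derive per-run seeds
through a `SeedSequence`.

What the simulator emulates: photon shot noise, occupancy
fluctuations, diffusion through the full PSF including its tails, and
optionally two-state blinking (continuous-time switching sampled at
slice starts).  What it does not: detector artefacts (injected
separately, see above), photobleaching, triplet kinetics, optical
saturation, flow, or real-PSF aberrations.  Passing recovery tests
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to every real-measurement imperfection —
that is what the correction modules plus the external re-analysis
script are for.

## Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, bounds
μ0 ∈ (0, 1e9) cps, τD ∈ (1e-7, 10) s, F ∈ [0, 0.99],
τF ∈ (1e-8, 1e-2) s; xtol = ftol = gtol = 1e-10, ≤1e4 evaluations),
unweighted by default, exposed as a scikit-learn estimator
(`MSMRRegressor`).  Initial guesses: amplitude from the largest
positive μ, τD from the log-interpolated half-plateau crossing with the
largest T as fallback.  The aspect ratio r is *fixed* by default and
should come from a calibration: the model is nearly insensitive to r
above ~3 (the r = 5 and r = 10 curves practically coincide), so
freeing it there is an identifiability trap and triggers a warning.
Non-convergence is a flagged result, not an exception; standard errors
come from the Jacobian-based covariance scaled by the residual
variance.

## Validation problem sizes

The recovery validation uses five replicate 10 s traces per condition
(20 particles, r0 = z0 = 0.4 µm, D = 50 µm²/s; ≈7.5 million 1.33 µs
bins per trace), matching the conditions under which the reference
recovery values (40.5 ± 0.6 / 98.4 ± 2.6 kCps, 53 ± 3 / 102 ± 5 µm²/s)
were obtained; the fast-diffusion condition (D = 100 µm²/s) uses 5 s
traces, which halves the run count per curve while keeping ≈7.5 million
bins at its finer 0.67 µs slice.  Unit-test simulations use 0.2–4 s
traces — long enough for the tested statistic, short enough to keep the
suite quick.

## Known limitations

* First-order artefact corrections only; second/third-order
  afterpulsing and dead-time loading beyond ⟨k⟩δ ≈ 0.1 are outside
  validity.
* The binary blinking model is phenomenological for multi-dye
  molecules.
* Single species only in the fit (no two-component diffusion, no
  global fits across concentrations).
* The per-bin dead-time injection model ignores cross-bin blanking, so
  it slightly overestimates recoverable counts at very high rates.
* Timestamp input assumes sorted arrivals and drops events at the
  window edge (with a warning) rather than extending the window.
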