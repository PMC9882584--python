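# Methods

This note documents the model, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Two-pool model and state representation

The voxel model has six biophysical unknowns — the semi-solid pool fraction
`m0s` (with `m0f = 1 - m0s` always derived, never stored), the free-pool
rates `R1f`, `R2f` (1/s), the exchange rate `Rx` (1/s), and the semi-solid
`R1s` (1/s) and `T2s` (s) — plus three system unknowns: off-resonance `ωz`
(rad/s), transmit scale `b1` (actual/nominal Rabi frequency), and a complex
overall scale `M0` (spin density × coil sensitivity).  The magnetization is
a homogeneous 6-vector `(xf, yf, zf, xs, zs, 1)`; appending the constant 1
turns relaxation toward thermal equilibrium into a linear operation, so
every evolution step is a matrix exponential and compositions stay exact.
The `ys` component is dropped (`ωx = 0`; the semi-solid transverse dynamics
are dominated by `R2s,l ≫ ωz`).

Conventions that matter downstream:

* RF rotations are about ±y (the π phase cycling is folded into the sign of
  `ωy`), coupling `x` and `z`.  The signal is `xf + i·yf`, demodulated by
  `(-1)^i` per TR and scaled by `M0`.
* The exchange terms couple only `zf`/`zs` with rates `Rx·m0s` (out of the
  free pool) and `Rx·m0f` (into it), preserving total longitudinal
  magnetization when `R1f = R1s = 0`.

## Apparent (constrained-model) parameters

Without RF, the `(zf, zs, 1)` sub-system has eigenvalues `0` (equilibrium)
and two negative ones; the smaller magnitude is the apparent free-pool rate
`R1f,a` and the larger the apparent exchange rate `Rx,a`.
`eigen_relaxation` computes them exactly; `taylor_apparent` evaluates the
expansion around `R1s = R1f` with `δ = R1s − R1f`:

* `R1f,a ≈ R1f + m0s·δ − m0f·m0s·δ²/Rx`
* `Rx,a ≈ (Rx + R1f) + m0f·δ + m0f·m0s·δ²/Rx`
* `m0s,a ≈ m0s·(1 − 2·m0f·δ/Rx)`

`order=1` truncates the rates after the linear term.  The `m0s,a`
correction is linear in `δ` but divides by `Rx`; it is reported at both
orders because it is the useful result, and `Rx = 0` (no exchange — the
constrained-model bias is then undefined) falls back to order-1 rates and
an uncorrected `m0s` with a warning.  An exact eigenvector-derived `m0s,a`
is deliberately not offered: only the expansion above is part of the
contract.

Note a statistical subtlety the `analysis` module inherits: applying these
conversions to ROI *means* is not the same as the ROI mean of voxel-wise
conversions; only `Rx,a`, whose expansion is dominated by the linear terms,
is robust to this distinction.

## Semi-solid saturation (generalized Bloch) and linearization

During a rectangular pulse the semi-solid longitudinal magnetization obeys

```
∂t zs(t) = -ωy·xs(t) + R1s·(m0s − zs(t)),
xs(t)    =  ωy·∫₀ᵗ G(t−τ)·zs(τ) dτ,
```

with `G` the lineshape Green's function.  For the super-Lorentzian,
`G(κ) = ∫₀¹ exp(−(κ/T2s)²·(3ζ²−1)²/8) dζ`.  Numerics:

* The public `greens_function` uses adaptive quadrature (`scipy`'s QUADPACK,
  absolute tolerance 1e-10) with an explicit break point at the magic angle
  `ζ = 1/√3`, where the integrand peaks for large `κ`.  The solver's grid
  path uses a fixed 4-panel, 80-node Gauss-Legendre rule split at the same
  point, accurate to ≤2e-11 for `κ/T2s ≤ 400` — two orders below the solver
  tolerance and ~100× faster than per-node adaptive calls.
* The Volterra system is integrated by product integration: trapezoidal
  memory kernel and Crank-Nicolson time step (implicit but linear in the
  unknown), globally second order.  The step starts at `T2s/10` and halves
  until successive solutions differ by `< 1e-7`; the returned value is
  Richardson-extrapolated (observed residual error ~1e-9 against the
  closed-form Lorentzian limit).
* `linearize_r2s` finds the `R2s,l ≥ 0` for which the ordinary 2-component
  Bloch model reproduces the generalized-Bloch `zs(TRF)` (Brent root find,
  tolerance ~1e-12 on the rate).  The matching is performed with `R1s = 0`
  so that `R2s,l` is a pure saturation surrogate; longitudinal relaxation
  and exchange act in the full 6×6 generator instead, avoiding double
  counting (with `T2s ≪ TRF ≪ T1s` the residual error of this split is
  negligible).  Flip angles below 1e-3 rad are evaluated at that limiting
  value (continuity; saturation is negligible there anyway).

The linearized rate is tabulated as the dimensionless `r2sl·T2s` over
`(α, TRF·R2s)` — nondimensionalization makes one table serve every `T2s`.
Default grid: 128 linearly spaced flip angles in `[0.01, π]` (saturation
varies fastest near π, where log spacing is too coarse) × 64 log-spaced
duration products in `[5, 200]`, covering 100 µs–1 ms pulses at
`T2s ≈ 5–20 µs`.  Queries use tensor-product monotone (PCHIP)
interpolation — exact at grid nodes, mid-cell error ~1e-4 relative, well
inside the 1e-3 contract.  Out-of-hull queries raise by default.  Two
clamping policies exist for the simulator: the flip-angle axis saturates at
its edges (`b1 > 1` pushes effective flips past π, where the end-of-pulse
matching can become infeasible because the generalized-Bloch `zs` can leave
the ordinary model's attainable range; below the first node the continuity
convention applies), and the inversion pulse clamps both axes (its 500 µs
duration sits beyond the excitation-pulse grid, where the dimensionless
rate varies slowly).  The voxel fitter clamps fully during optimization so
that transient trial points at extreme `T2s` or `b1` cannot abort a fit;
converged estimates at physiological values are always in-hull.

## Pulse sequence and periodic steady cycle

A cycle is a rectangular π inversion pulse with ideal crushers followed by
`floor(Tc/TR)` rectangular pulses (default: 1142 pulses, TR 3.5 ms, 4 s
cycle), phases alternating by π.  Each TR is modeled symmetrically: free
precession for `(TR−TRF)/2`, the pulse, free precession for `(TR−TRF)/2`;
"mid-TR" sampling therefore means the point midway between consecutive
pulse centers — the balanced-SSFP echo — and is the default;
`sample_delay` configures the offset after pulse end (the closed-form bSSFP
test samples immediately post-pulse, which is where the textbook steady
state is defined).  The inversion operator rotates the free pool by `b1·π`
with relaxation active over its 500 µs, attenuates `zs` through the
linearized rate (exchange during the sub-millisecond pulse is negligible
and omitted), and zeroes all transverse components (ideal crushers).

Because the within-cycle dynamics are affine in the homogeneous 6-vector,
the periodic steady cycle is the fixed point `M = A·M` of the cycle
propagator and is solved exactly as a 5×5 linear system (singular if an
eigenvalue of `A` is within 1e-9 of 1, which is reported, not papered
over).  `simulate_transient` exposes the cycle-by-cycle approach to that
fixed point — a linear contraction that reaches 1e-8 within ~20 cycles for
brain-like parameters.

`default_train` generates the smooth stand-in experiment: five seeded
low-frequency sinusoids mapped into `[0.05, 0.9π]`, rescaled to respect the
hybrid-state adiabaticity bound `|Δα| ≤ 0.1` rad between neighbors, with
pulse durations alternating blockwise between 100 µs and 1 ms to modulate
semi-solid saturation independently of flip angle.  It is deterministic in
its seed.  The encoding quality of such a train is far below a
CRB-optimized protocol; that is why estimator-precision tests quote their
own train and noise conditions.

## Cramér-Rao bounds and train optimization

With i.i.d. complex Gaussian noise (SD `σ` per real channel), the Fisher
matrix of the real unknowns is `Re(Jᴴ·J)/σ²`.  The two real components of
`M0` are always unknowns; their Jacobian columns are analytic (the signal
is linear in `M0`), all others are central finite differences with relative
step 1e-5 (absolute floor 1e-8 for parameters near zero such as `ωz`) —
validated against an exact forward-sensitivity oracle built from augmented
12×12 matrix exponentials.  The Fisher matrix is inverted on the
correlation scale (`F = D·C·D` with `D` the diagonal square root): its raw
condition number reflects parameter-unit disparity (seconds vs rates), not
information loss, and the correlation-scale condition number is the honest
singularity diagnostic (bounds are reported as +∞ beyond 1e12).

The normalized CRB follows
`rCRB(θ) = CRB(θ)·T_total·(|M0|/σ)²/θ_ref²` — units of time, invariant to
scan-time, scale and noise bookkeeping.  The exact constant is a
convention; it is exposed and nothing quantitative depends on it.

`optimize_train` minimizes a weighted sum of normalized CRBs over all flip
angles and durations: logistic reparameterization into the box bounds
(`α ∈ [0.01, π]`, `TRF ∈ [100 µs, 1 ms]`), L-BFGS-B with finite-difference
gradients, a quadratic penalty on violations of the smoothness bound, and
monotone acceptance (the initial train is returned if the objective did not
improve).  This is a local refinement tool, not a global designer.

## Estimation

`build_dictionary` simulates one unit-`M0` fingerprint per point of a
Cartesian parameter grid; `compress_basis` takes its top singular vectors
(rank ~15 captures held-out physiological fingerprints to <1% relative
error when the grid spans all varying parameters — a dictionary missing an
axis, e.g. `R2f`, leaves that variation outside the span).

`fit_voxel` minimizes `‖s − M0·f(θ)‖²` with `M0` eliminated in closed form
at every iterate (`M0 = ⟨f, s⟩/‖f‖²`, variable projection), a bounded
trust-region-reflective solver over log-parameterized rates (bounds applied
in natural units; defaults `m0s ∈ [0, 0.5]`, `R1f ∈ [0.1, 5]`,
`R2f ∈ [1, 50]`, `Rx ∈ [1, 100]`, `R1s ∈ [0.2, 20]` 1/s,
`T2s ∈ [1, 50] µs`, `ωz ∈ ±π/TR`, `b1 ∈ [0.5, 1.5]`), initialization from
the best-correlated dictionary atom plus seeded jittered restarts (best
residual wins, ties to the smaller `m0s`), and optional constraints
(`R1s` fixed, or `R1s = R1f` — the classical constrained model, whose fits
to unconstrained-truth data reproduce the expected downward `m0s` bias).
Subspace coefficients are accepted in place of full fingerprints by
projecting the model through the same basis.  `fit_volume` loops masked
voxels independently and records failures in a flag map.  Noiseless
recovery from dictionary initialization reaches ~1e-6 relative; the
1e-3/1e-2 figures asserted in tests are deliberately loose contracts.

## Synthetic data

The generators encode the study conditions rather than convenient ones:

* **BSA phantom** — seven tubes at mass fractions 0.05…0.35, parameters from
  empirical linear surfaces `a0 + a_BSA·c + a_B0·B0 + a2·c·B0` per
  parameter (the `m0s` surface gives 0.1097 at `c = 0.2`, `B0 = 2.89 T`),
  with physical floors where a surface goes negative (the `R2f` intercept).
* **Digital brain** — procedural nested-ellipsoid labels (cortical GM
  shell, WM core, central CSF, two callosal blobs, five seeded subcortical
  nuclei, lesions with a ≥1-voxel radius floor), per-label parameters at
  healthy-adult ROI means, lesions carrying WM parameters with
  `m0s × 0.6` and `T1f × 1.1` (illustrative demyelination defaults —
  the literature constrains the direction, not the magnitude), and smooth
  random low-order polynomial B0 (±2π·20 rad/s) and B1 (0.9–1.1) fields.
  The fields are quantized (0.1 rad/s, 1e-3) so that equal voxels share one
  simulation; the quantized values are the recorded truth.
* **Noise** — i.i.d. complex Gaussian, SD `σ` per real channel, seeded.

What these phantoms do *not* emulate: k-space acquisition and undersampling
artifacts, partial-volume mixtures, spatially correlated noise, motion, and
anatomical geometry.  Passing end-to-end tests therefore demonstrates
estimator correctness and noise behavior for the per-voxel signal model,
not robustness to reconstruction artifacts.

## Problem sizes in the test suite

The suite runs on one core in roughly a quarter hour, with sizes chosen as
the smallest that still exercise the claim: linearization tables at
12×10 nodes (the contract tolerance is met with large margin; the
128×64 default is a user-scale build), 100-pulse trains for unit tests,
the reference 1142-pulse TR-3.5 ms train for end-to-end estimator checks
(shorter cycles genuinely encode the MT parameters too weakly for
SNR-100 precision targets), a 75-voxel seeded subsample of the digital
brain, 3 voxels per phantom tube at two field strengths, 24-case recovery
sweeps, and 2000-draw Monte-Carlo CRB attainability on a 50-pulse
single-free-parameter toy (the SD of an SD estimate from 2000 draws is
~1.6%, so the attainability check allows a 3-sigma sampling margin below
the theoretical floor).

## Known limitations

* Shaped (non-rectangular) pulses, finite crushers, slice profiles and
  gradient/eddy-current effects are out of scope.
* The `R2s,l` linearization matches end-of-pulse magnetization only, by
  contract; within-pulse trajectories of the semi-solid pool differ from
  the generalized-Bloch solution.
* For effective flips beyond π (large `b1`) the linearization is clamped at
  the table edge; the induced error is confined to unphysical transient
  iterates and the inversion pulse's saturation term.
* The train optimizer is local and gradient-based; it refines, it does not
  design from scratch.
* Neural-network fitting is intentionally replaced by NLLS: the scientific
  content is the signal model, and NLLS makes the estimator auditable
  against the CRB.
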