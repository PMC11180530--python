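# Methods

## Problem and model

A 2-D parallel-beam transmission scan measures line integrals
`p(θ, s) = ∫ f(x) dl` of the attenuation map `f` along rays with detector
offset `s` at view angle `θ`.  With 8 views of 256 bins against a 256²
image, the measurements determine only ~3% of the unknowns; reconstruction
is possible only through constraints.  Three are used here, each enforced by
its own sub-algorithm of a POCS loop: data fidelity (MLEM), piecewise
constancy (TV descent) and membership in a small set of known attenuation
levels (snapping).

The emission-type MLEM update is used for the fidelity step even though the
simulated noise is Gaussian rather than Poisson.  That mismatch is
deliberate: with strong TV and level priors the likelihood model matters
little, and the experiments are designed to show exactly that.  Negative or
zero measurements produced by the additive Gaussian noise are floored at
`projection_floor` (default 10⁻⁶) before MLEM, the minimal intervention
that keeps the multiplicative update defined; forward projections below
10⁻¹² are clamped the same way so rays grazing the support cannot divide
by ~0.

## Geometry and system model

View angles are `k·π/n_views`, starting at 0, over the half circle.  The
detector axis at angle θ is `(cos θ, sin θ)`; rays travel along
`(−sin θ, cos θ)`; bin centers are symmetric about the rotation axis at
unit pitch, matching unit pixels (no physical scale is attached — the
attenuation values are in phantom units per world unit).

The system matrix is materialized as a `scipy.sparse` CSR matrix (about 1M
non-zeros at full scale), which makes the back projector the exact adjoint
of the forward projector by construction — a requirement for the MLEM
sensitivity normalization to be consistent.  The default ray model is
Joseph-style interpolation (one ray per bin, marched along the dominant
axis, linear interpolation across it, weights scaled by the slab path
length `pixel_size / max(|cos θ|, |sin θ|)`); interpolating projectors
suppress the stripe artifacts that exact intersection-length models produce
at very few views.  A Siddon-style exact-intersection model is available as
an option and doubles as a structurally different implementation in tests.
A circular support mask (the circle inscribed in the image square) freezes
exterior pixels at zero during reconstruction; the projectors themselves
are unmasked.

## Phantom and simulated data

The reference phantom is one large disc (value 0.5, radius 0.45·FOV,
centered) and eight small discs (radius 0.05·FOV) on a ring of radius
0.28·FOV, numbered clockwise from 12 o'clock: discs 1–5 have total value
1.5, discs 6–8 total value 1.0.  Disc values are *totals* (replacement
semantics — later discs overwrite earlier ones), matching the snap levels
0.51/1.01/1.51: additive superposition would put 2.0 and 1.5 inside the
small discs and make the level prior wrong.  The ring radius is this
package's choice; it keeps the small discs well inside the large one, which
is also what makes the replacement rule analytically tractable (each disc
pair nested or disjoint, so replacement rewrites exactly into additive
deltas).

Sinograms are computed in closed form from chord lengths
`2√(r² − d²)`, never through the discrete projector, so reconstruction is
always tested against data its own forward model cannot reproduce exactly
(the rasterized-phantom projection agrees with the analytic sinogram to
about 1.7% RMS at 64 bins and better at 256 — the documented, intentional
model mismatch).  Measurement noise is zero-mean Gaussian added directly to
the line integrals (variance 5 at full scale), unclipped.

Ground truth for metrics is the pixel-center rasterization (deterministic,
exactly the discrete level set {0, 0.5, 1.0, 1.5}); 4×4 supersampling is
available but not the default, because a fractional-coverage truth would
blur the very levels the prior encodes.

## Numerical choices

* **TV definition.** Isotropic forward-difference TV; differences across
  the last row/column are zero, so constant images have TV exactly 0 and
  the subgradient is conservative.  The subgradient uses the ε-smoothed
  root `√(· + ε²)` with ε = 10⁻⁸; at step size 2·10⁻⁷ the distinction from
  a true subdifferential is numerically negligible.
* **TV schedule.** A very small step repeated many times (5000/iteration)
  rather than few large steps: large steps destabilize the descent near the
  non-smooth minimum, while a tiny single step would do nothing.  The inner
  loop is JIT-compiled (numba); one 5000-step block on a 256² grid takes
  about 2 s on one core, which puts the full 1009-iteration run at rough
  half-hour scale per method.
* **Nonnegativity.** TV descent can push pixels slightly negative; the
  estimate is clamped to ≥ 0 after each TV block, since attenuation is
  nonnegative and the next MLEM step requires it.
* **Initialization.** Uniform 1.0 inside the support mask (strictly
  positive, as the multiplicative update demands), 0 outside.
* **Snap timing.** `Count` starts at 1 and the snap fires when
  `Count mod snap_period = 0`, so the first snap happens after a full
  period of data-driven iterations, and a total count that is not a
  multiple of the period guarantees the run ends with MLEM + TV, not with
  segmentation.  Configurations that would end on a snap trigger a warning,
  not an error.

## Metrics

PSNR is `10·log₁₀(peak²/MSE)` with peak = 1.59, the display-window maximum
(the only scale constant the experiment fixes); SSIM uses the standard
constants (K₁ = 0.01, K₂ = 0.03, Gaussian window σ = 1.5) with
data_range = 1.59.  SNR is the reference-power form
`10·log₁₀(mean(ref²)/MSE)` — the one common definition under which
PSNR − SNR is a constant independent of the image under test, which is the
consistency property the tabulated metrics should (and here provably do)
exhibit.  Identical images score SSIM 1 and infinite PSNR/SNR.

## Experiment presets and problem sizes

The full preset (256², 8 views, 1009 iterations, 5000 TV steps, η = 2·10⁻⁷,
snap every 100, noise variance 5) is a batch job; the shipped desk-scale
preset reproduces every structural feature of the schedule at ~100× less
compute: 64² grid and bins, 8 views, **209** iterations (not a multiple of
the snap period 20), 500 TV steps with η = 8·10⁻⁷ (scaled by the 4× grid
ratio), noise variance 5/16 (line integrals shrink 4× with the grid, so
this preserves per-ray SNR).  The test suite and the acceptance script run
the desk-scale preset; `scripts/full_table.py` runs the full one.

## What the synthetic data do and do not show

The simulator emulates ideal monochromatic parallel-beam line integrals of
a piecewise-constant object with additive Gaussian noise.  It does not
model Poisson counting statistics, beam hardening, scatter, detector
blur/crosstalk, motion, or objects whose attenuation levels are *not* known
in advance.  Passing tests therefore demonstrate the mathematics of the
method — and specifically that the discrete-level prior adds accuracy over
TV alone when the level assumption holds — not performance on clinical
data.  The desk-scale reconstruction problem is relatively less
under-determined than the full-scale one (512 measurements for 4096 pixels
vs 2048 for 65536), so quality numbers are not comparable across scales;
the quantity the test suite certifies is the desk-scale method ordering
(POCS > TV > MLEM by SSIM, with and without noise).

## Known limitations

* Replacement-overlap analytic sinograms require nested-or-disjoint disc
  pairs; partial overlaps raise (use additive mode for those).
* The snap prior assumes the true values lie near the preset levels; badly
  chosen levels act as a structured artifact generator.  Conversely, on
  instances easy enough that TV alone nearly recovers the object (simple
  layouts, noiseless data, smooth projectors), the snap has little left to
  fix and need not improve fidelity further — the prior pays off when the
  data are weakest.
* Convergence of the POCS loop is not analyzed (the alternation is not a
  contraction in general); schedules are validated empirically.
* Fan-beam, cone-beam and polychromatic physics are out of scope.
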