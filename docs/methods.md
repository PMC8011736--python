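# Methods

## Model

A population lives on a bounded attribute interval [a, b] (default [0, 1];
all results are affine-equivariant, so the choice of bounds is cosmetic)
with probability density ρ(x). Two groups form, one containing each
extreme. A group's boundary z splits the space into its in-group and
out-group; each category is represented by its prototype, the truncated
center of mass of ρ on that side.

The individual categorization error of an in-group member at u is the
expected squared mismatch between the true pairwise distance |u − v| and
the prototype-based distance (0 within the group, |g_out − g_in| across
it), with partners v drawn from ρ over the whole space — partner sampling
is *not* renormalized within groups, so more populous sides weigh more.
The collective error Err(z) averages the individual error over the
in-group with weight ρ(u) and normalizing mass ∫_in ρ. The boundary
evolves by gradient descent, dz/dt = −k dErr/dz; the rate constant k only
rescales time and never moves the fixed points (default k = 1).

Membership convention: the left group's in-group is the half-open
interval [a, z), so a partner exactly at z counts as out-group. For
continuous densities this is measure-zero; fixing it keeps histogram
densities deterministic.

## Exact moment-based evaluation

Because the error integrand is quadratic in positions, err(u, z) is a
quadratic polynomial in u whose coefficients are partial moments
m_k(lo, hi) = ∫ x^k ρ dx, k ≤ 2, over the two sides of the boundary:

    err(u, z) = u² + B u + C,
    B = −2 m₁(a, b) ± 2 D_g m₀(out),
    C = m₂(a, b) + D_g² m₀(out) ∓ 2 D_g m₁(out),

with the upper signs for the left group. Averaging over the in-group,

    Err(z) = (m₂(in) + B m₁(in)) / m₀(in) + C.

The partial moments are closed-form for every supported family: polynomial
for the uniform and histogram densities, and differences of regularized
incomplete beta functions for Beta and Beta-mixture families, using
x^k f(x; α, β) = c_k f(x; α + k, β) with c_k = B(α + k, β)/B(α, β).
No nested quadrature is needed, so Err(z) is exact to floating-point
round-off and cheap enough for dense scans. The test suite independently
cross-checks this route against dense trapezoid-sum (Riemann) evaluation
of the defining integrals and against `scipy.integrate.quad`, for all
families; the uniform closed forms err(u, z) = u² − uz + z²/2 − z/4 + 1/12
and Err(z) = z²/3 − z/4 + 1/12 serve as exact regression oracles.

## Numerical choices

- **Gradient** dErr/dz: central finite difference with step
  h = 1e-5·(b − a). On the uniform case the difference of the quadratic
  closed form is exact; elsewhere Err is smooth and exactly evaluated, so
  the truncation error is O(h²) ≈ 1e-10.
- **Flow integration**: `scipy.integrate.solve_ivp` RK45, rtol 1e-8,
  atol 1e-10; the flow is one-dimensional and non-stiff. Defaults:
  z0 = (a + b)/2, t_max = 100/k, stop event |dz/dt| < 1e-8.
  Non-convergence by t_max returns the trajectory flagged
  `converged=False` rather than raising.
- **Edge margin**: the group masses in the denominators of g_in and Err
  vanish as z → a or b, so z is confined to (a + ε, b − ε) with
  ε = 1e-4·(b − a) during integration and root scanning. Grid points
  where one side's mass still underflows (thin Beta tails) are skipped as
  carrying no sign information.
- **Fixed points**: the gradient's sign is scanned on a 256-point grid
  over (a + ε, b − ε); each sign change is refined by Brent's method to
  |dErr/dz| < 1e-9. Stability is classified by the central second
  difference with step 1e-4·(b − a): stable for positive curvature,
  unstable for negative, "marginal" (flagged, not silently classified)
  when |d²Err/dz²| < 1e-6. All roots are reported; the two-group solver
  selects, per side, the stable root nearest the endpoint of the flow
  integrated from z0, so the initialization chooses the basin and the
  root-finder supplies precision.
- **Grid oracle**: an independent derivative-free check evaluates Err on
  a 2048-point grid and returns the argmin; solver and oracle must agree
  to one grid spacing for every studied density.
- **Degenerate inputs**: a ≥ b, non-positive Beta shapes, boundaries at
  the edges, zero-mass intervals and out-of-range samples raise typed
  errors (`DomainError`, `ParameterError`, `DegenerateGroupError`,
  `DataError`). Crossed boundaries (z₁\* > z₂\*, not observed for any
  studied density) are reported with `nonempty=False` plus a warning, not
  an error, since the model does not forbid that regime.

## Density families and fitting

Uniform, Beta(α, β) (defined on [0, 1] and affinely rescaled to [a, b]),
and the equal mixture of Beta(α, β) with Beta(β, α) — symmetric about the
midpoint and bimodal for well-separated shapes such as (2, 7). The
supported Beta regime is α, β ≥ 1 (bounded pdf); smaller shapes are
accepted because the endpoint singularities are handled analytically
through the incomplete beta function, but the studied examples all use
α, β ≥ 2.

Empirical data enter as a one-column CSV of attribute values.
`fit_from_samples` (≥ 30 values required) offers a 64-bin equal-width
histogram density — smooth enough for the gradient flow, stable at
n ≈ 10³ — or a Beta fit by the method of moments on the rescaled samples,
α̂ = m(m(1−m)/v − 1), β̂ = (1−m)(m(1−m)/v − 1).

## Synthetic samples

`catbounds fixture` draws seeded i.i.d. samples from any parametric
family (NumPy `default_rng`; identical seeds give byte-identical files).
These fixtures emulate only the sampling noise of a finite survey of a
stationary attribute distribution: independent draws, no measurement
error, no missingness, no clustering. Round-trip tests (sample → moment
fit → boundary solve, recovering the parametric boundaries to 0.02 at
n = 10⁴) therefore demonstrate statistical consistency of the pipeline,
not robustness to the messiness of real survey data.

## Problem sizes

The default test and verification sizes are: 256-point gradient scans,
2048-point oracle grids, 10⁴-sample fixtures, 100-point closed-form
regressions, and 20 random initializations per density family for the
descent checks. These are comfortable desk-scale sizes at which every
tolerance above is met with orders of magnitude to spare.

## Limitations

- One-dimensional attribute spaces only; no multivariate extension.
- The two boundaries evolve independently, as the model prescribes;
  there is no coupling or reaction between groups, and no dynamics for
  inbetweeners forming a third group.
- The attribute distribution is static; demographic or cultural drift is
  out of scope.
- Densities whose gradient has no interior sign change return an empty
  fixed-point list; the behavior is reported, not interpreted.
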