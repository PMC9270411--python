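# Methods

## Model and assumptions

The SEATS system tracks a constant student population `N` in four
compartments: Susceptible, Exposed, Animosity-infected, Treated.
Turnover is balanced — entry (recruitment `Λ = μN`) equals exit at the
per-capita rate `μ` in every compartment — so both the count system and
its scaled (proportion) version conserve the total exactly.  Contact is
density-dependent: the count system uses `βSA` on raw head counts, and
the scaled system uses `βsv` on proportions.  The two coincide at
`N = 1`; for other `N` the same numeric `β` gives different per-capita
dynamics (the count system's effective contact rate is `βN`).  Both
forms are provided as printed; users comparing them at matched dynamics
should rescale `β` by `N`.

All rates are per month.  The simplex `{s+e+v+z = 1, components ≥ 0}`
is positively invariant; the solvers do not re-project states onto it —
conservation is asserted by the test suite, not enforced.

## Threshold and equilibria

`R0 = βγ/((μ+γ)(μ+δ))` is the spectral radius of the next-generation
matrix.  The animosity-free equilibrium is `(1,0,0,0)`; the interior
equilibrium has `s* = 1/R0`, `v*` in closed form, `e* = (μ+δ)v*/γ`,
`z* = δv*/(μ+α)`.  At `R0 = 1` exactly, the interior point is returned
as the boundary point (continuity limit).  The closed-form denominator
`αδγ − (μ+α)(μ+δ)(μ+γ)` is strictly negative whenever `μ > 0`, so the
degenerate-parameter error path is reachable only at `μ = 0`.

The low-transmission bundled preset (`β = 0.05, γ = 0.035, α = 0.03,
μ = 0.02, δ = 0.01`) evaluates to `R0 = 1.0606` under this formula; the
package always reports the computed value, and threshold behaviour is
validated as a property over random parameter sweeps rather than at any
single quoted number.

## Stability machinery

* **Local**: eigenvalues of the analytic Jacobian, plus Routh–Hurwitz
  leading-minor determinants of the monic characteristic polynomial.
  The polynomial is computed by the Faddeev–LeVerrier trace recursion so
  that the Hurwitz route stays independent of the eigenvalue route (the
  two are cross-checked on 10,000 random quartics built from known
  roots).  Verdicts: stable / unstable / marginal, with a marginality
  tolerance of 1e−9 on the maximal real part.
* **Global, boundary point**: the linear Lyapunov function
  `l(e,v) = m·e + n·v` with `m = R0`, `n = β/(μ+δ)`.  Its exact orbital
  derivative is `β(R0·s − 1)·v`; the reported quantity `β(R0 − 1)·v` is
  the `s = 1` value and an upper bound on the simplex (`s ≤ 1`), which
  is what makes the sign of `R0 − 1` decisive.  Tests check the exact
  identity at `s = 1` and the bound elsewhere.
* **Global, interior point**: a diagonal quadratic form
  `L = Σ vᵢ(xᵢ − xᵢ*)²` certified through Volterra–Lyapunov stability of
  the quadratic-form system matrix `A`, evaluated at the equilibrium.
  Both bilinear cross terms of the contact nonlinearity carry the weight
  `βs*`; this matrix differs from the Jacobian in the sign of its (2,3)
  entry, deliberately so: the Jacobian's principal minor on the (e,v)
  block equals `(μ+γ)(μ+δ)(1 − R0·s*) = 0` identically (because
  `s* = 1/R0`), so the linearisation itself can never be strictly
  diagonally stable and the certificate must concern the quadratic-form
  matrix.  The witness search follows the classical recursive reduction:
  closed-form conditions for 2×2 blocks (`a11 < 0`, `a22 < 0`,
  `det > 0` — the determinant condition is required for the equivalence
  to hold), then the last diagonal weight chosen by maximising the
  definiteness margin of the Schur complement (a concave quadratic in
  that weight; the 1-D maximisation is numerically more robust than
  picking the midpoint of its root interval), with a Nelder–Mead polish
  as fallback.  `certified=true` is only ever set after a direct
  eigenvalue check that `VA + AᵀV` is negative definite.

## Stochastic variant

The CTMC tracks integer `(S, E, A)` with `T = N − S − E − A` implicit.
Six events: influx to S at `μN + αT`, exposure at `βSA`, exits from S
and E at `μS`/`μE`, progression at `γE`, removal from A at `(μ+δ)A`.
The influx propensity does not vanish at the `T = 0` boundary as
written, so it is suppressed when `S + E + A = N` to keep the implicit
treated count nonnegative; in the regimes simulated here the boundary is
never reached.  Simulation is exact Gillespie (exponential waiting
times, inverse-CDF event selection) with one seeded generator per run;
identical seeds give identical trajectories.

The fluid-limit validation uses `N = 5000`, 500 replicates, and the
high-transmission per-capita dynamics (`β = 0.5/N`, so the count ODE and
the CTMC share the same contact term), checked at ten 2-month
checkpoints over the 20-month transient against the count ODE within
three Monte-Carlo standard errors of the replicate mean.  A smaller
companion test verifies that the deviation shrinks from `N = 500` to
`N = 5000`.

The outbreak assessment implements the threshold rule as stated:
extinction certain when the expected number of animosity-infected
students `n ≤ 1`, otherwise extinction probability `τ = N/(s·R0)`
clamped to [0, 1].  `n` has no computable definition in this framework
and is a user input (conventionally `n = R0`, with which it shares the
threshold role); note that `τ` is *not* the standard branching-process
extinction probability `(1/R0)^a`.  An empirical companion estimates the
outbreak fraction (replicates whose infected count never hits zero
before the horizon) with a binomial standard error.

## Optimal control

Controls: prevention `u1` multiplying the contact term by `(1−u1)` and
treatment `u2` multiplying `δ`, both in [0, 1]; note `u1 = 0, u2 = 1`
recovers the uncontrolled count system, while the `u ≡ 0` baseline has
*no* treatment flow at all.  Objective: running cost
`∫ w1·A + (b1/2)u1² + (b2/2)u2² dt` with defaults `w1 = 1`,
`b1 = b2 = 100` over 300 months on a population of 100 with initial
counts `(74, 9, 7, 10)`.  The adjoint system is the negative Hamiltonian
gradient (the `A`-costate equation carries `−w1`, the derivative of the
running cost); controls are the projected pointwise minimisers
`u1 = clamp(βSA(λ2−λ1)/b1, 0, 1)`, `u2 = clamp(δA(λ3−λ4)/b2, 0, 1)`.

Solver: forward–backward sweep on a uniform grid (default 2001 nodes),
fixed-step RK4 in both directions with controls/states averaged at the
half step, convex relaxation `u ← ½u_new + ½u_old`, convergence when the
relative L1 control change drops below 1e−4, at most 500 sweeps.  The
problem is nonconvex: at these parameters a weak-control and a
strong-control stationary pair coexist (costs 17213 vs 14279 for both
controls), so `solve_optimal_control` runs the sweep from `u ≡ 0` and
`u ≡ 1` and keeps the lower-cost converged solution; `scenario_compare`
uses it for the both/treatment-only/prevention-only comparisons.

A structural consequence worth knowing: because the objective has no
terminal cost, transversality (`λ(Tf) = 0`) forces the controls to zero
near the horizon, and with strongly supercritical uncontrolled dynamics
the infected class rebounds during the final months of any optimal
solution.  Eradication-by-the-horizon claims therefore do not follow
from this formulation; the cost orderings
`J(both) ≤ J(single) ≤ J(none)` do, and are verified.

## Numerical choices

* Deterministic integration: adaptive RK45, `rtol 1e−6`, `atol 1e−9`;
  input states validated to the simplex within 1e−8.
* Positive invariance is spot-checked over 300 random simplex initial
  conditions × random parameter draws (tolerance −1e−6).
* Fixture generation: rates log-uniform on [1e−3, 1] per month with
  rejection by R0 regime; fully seed-determined.
* Stability sweeps exclude the measure-zero band `|R0 − 1| < 1e−6`.

## What the synthetic conditions do and do not show

All inputs are synthetic parameter sets (no real attitude data exist for
this system).  Passing tests demonstrate internal mathematical
consistency — threshold behaviour, equilibrium formulas, certificate
validity, fluid-limit convergence, optimality conditions — under the
stated rate ranges; they say nothing about how well the SEATS structure
or any particular rates describe real student populations.  Known
limitations: no parameter estimation, no master-equation or diffusion
approximation for the CTMC, no existence/uniqueness theory or
second-order conditions for the optimal control, and
Volterra–Lyapunov certification restricted to the 2×2–4×4 cases the
model needs.
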