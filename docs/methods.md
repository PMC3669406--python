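# Methods

## Model

The package models hard-corona formation as competitive reversible
adsorption of `m` protein species onto a population of identical spherical
nanoparticles.  The surface is treated as a continuum of binding area:
species `i` occupies on average `1/n_i` of one particle's surface per
molecule, where `n_i` is the number of its molecules needed for full
coverage.  Protein–protein interactions, soft-corona layering, irreversible
binding and conformational change are outside the model's scope; these
require additional mechanisms and rate constants the present mass-action
description does not contain.

State is the vector of bound concentrations `x_i` (M).  Free protein is
eliminated exactly through conservation, `free_i = c_i0 - x_i`, and the
free surface fraction is `theta = 1 - sum_j x_j/(n_j N0)`.  The rate law is

    dx_i/dt = k_a,i (c_i0 - x_i) · n_i N0 · theta - k_d,i x_i .

This is the unique two-term mass-action form in which (a) association acts
on the free sites `n_i N0 theta` available to species `i`, (b) the
fast-phase composition reduces to flux weighting `k_a,i c_i0 / sum_j
k_a,j c_j0` independent of `n_i N0`, (c) the equilibrium reduces to the
competitive Langmuir isotherm in `K_i c_i0`, and (d) the fast time constant
is `1 / sum_j k_a,j c_j0`.  All four consequences are asserted by tests.

Standing assumption (validated per panel, warned about when violated):
protein excess — every species can supply the amount of protein its
metastable share demands, `x_bar_i <= c_i0`.  When the warning fires, the
closed-form metastable composition is still returned but the empirical
fast-phase composition from a full simulation is the recommended quantity.

## Units and parameters

Fixed package-wide: concentrations in M, time in s, `k_a` in M^-1 s^-1,
`k_d` in s^-1, so `K = k_a/k_d` is in M^-1 and all surface fractions are
dimensionless.  `k_d = 0` is allowed (pure-association runs, used as an
internal oracle); the equilibrium constant is then undefined and all
stable-composition operations reject the species by name.

State invariants use an absolute tolerance of 1e-9 on fractions — far above
double-precision noise, far below any meaningful fraction.  A breach beyond
ten times that aborts a simulation with a diagnostic.

## Numerical choices

**Full model.**  The fast/slow separation spans up to ~9 decades, so the
default integrator is implicit (`scipy` BDF) with the analytic Jacobian,
`rel_tol = 1e-10`, `abs_tol = 1e-18` M.  The absolute tolerance must sit
far below the smallest site capacity `n_i N0` (~1e-8 M for nanomolar
particles) because theta must be resolved near zero; the relative tolerance
is chosen so that every output state respects the 1e-9 fraction bounds
without projection — at 1e-8 the solver can undershoot theta below -1e-9
during the fast-phase collapse.  States are clipped at zero before each RHS
evaluation (standard positivity guard for mass-action systems).  The
default output grid is geometric over `[tau_fast/100, 100/min k_d]` so both
phases are visible in one run.

**Exact equilibrium.**  The equilibrium equations with depletion retained
collapse to one scalar unknown: given theta, each species' balance has the
unique solution `x_i(theta) = n_i N0 K_i c_i0 theta / (1 + n_i N0 K_i
theta)`, increasing in theta, so the coverage identity `h(theta) = 1 -
theta - sum_i x_i(theta)/(n_i N0)` is strictly decreasing with a sign
change on [0, 1].  The root is found with Brent's method to machine
precision.  A damped fixed-point iteration on the same identity was
considered and rejected: the update map's slope near the root is
`-(sum_i K_i c_i0)`, which is ~1e5 for realistic high-affinity panels, so
no fixed damping converges.  Bracketed root-finding is unconditionally
robust here.

**Reduced model.**  Singular perturbation eliminates the fast variable
(total coverage `s = sum f_i`): setting the aggregate coverage balance to
zero gives the quasi-steady free surface fraction

    theta* = [sum_j k_d,j x_j/(n_j N0)] / [sum_j k_a,j (c_j0 - x_j)]

and the slow flow `dx_i/dt = k_a,i (c_i0 - x_i) n_i N0 theta* - k_d,i x_i`,
whose fraction derivatives sum to zero identically.  All terms are of the
order of dissociation rates, so the system is non-stiff and integrates
explicitly (RK45) at steps of order `1/min k_d`.  The default initial
condition is the metastable closed form.  The separation parameter is
`epsilon = max_i k_d,i / sum_j k_a,j c_j0`; above 0.01 the reduction is
flagged as dubious.

One structural consequence deserves note: the slow flow conserves total
coverage exactly, and its fixed points form a one-parameter family
`x(theta)` (the per-species balances hold at *any* theta, which then equals
the quasi-steady value automatically).  Started from the metastable state
(`sum f = 1`), the reduced trajectory therefore converges to the family
member on the `sum f = 1` slice, which differs from the exact equilibrium
(`sum f = 1 - theta*`) by O(theta*) in each fraction.  In the model's
intended regime theta* is tiny (`sum K c0 >> 1`, "the free area is very
small"), so the distinction is below 1e-5 for serum-like panels; the exact
equilibrium is itself a fixed point of the reduced flow to machine
precision.

Measuring the reduction error against epsilon requires care: with the
default protocol (metastable initial condition, comparison window from
`10 tau_fast`) the discrepancy against the full model carries two additive
epsilon-independent floors — the fast-phase boundary-layer tail
(`e^-10 ~ 4.5e-5` of coverage still missing at the window start) and the
metastable formula's own approximation gap.  The error–epsilon scaling is
therefore measured with the reduced flow initialized on the full-model
state at `30 tau_fast`; under that protocol the log–log slope is 1.00 over
epsilon in [1e-6, 1e-3].

**Sensitivities.**  Both closed forms have the structure `f_i = w_i / D`,
so the relative sensitivities are `d ln f_j / d ln p_i = delta_ij - f_i`
exactly; the implementation is this closed form, and central finite
differences (relative step 1e-6) on the compositions serve as the oracle in
tests.  Sweeps recompute the closed forms (cheap and exact); sweeping `K`
scales `k_a` at fixed `k_d`.

**Stochastic simulator.**  A direct Gillespie simulation at particle
resolution: each particle carries a continuous free surface fraction
`theta_p`; binding propensities are `k_a,i n_i free_i / V · theta_p` with
`V` the explicit counts-per-molar volume factor (default `n_particles/N0`),
unbinding is first-order in per-particle bound counts.  Binding decrements
`theta_p` by a surface increment with mean `1/n_i` — deterministic by
default, uniform on `[0, 2/n_i]` as an option, since only the mean is
physically constrained — clipped so `theta_p >= 0`; unbinding restores the
increment the departing molecule originally claimed (a uniform pick among
those bound), which keeps `theta_p` in [0, 1] exactly and makes per-species
molecule conservation an integer identity.  The total free surface is
re-summed every event rather than tracked incrementally, so a fully covered
ensemble reaches total propensity exactly zero.

The clipping is a boundary effect absent from the mean-field limit: near
full coverage, bound *counts* keep their nominal `1/n_i` footprint in the
fraction bookkeeping while the applied increments are smaller, so replicate
means overshoot the ODE by O(1/n) once theta approaches zero (measured
~0.007 at `10 tau_fast` on the demonstration panel, independent of particle
number).  Mean-field comparisons are therefore made at checkpoints spanning
the active fast phase (coverage up to ~98%), where the agreement is within
replicate noise and improves with particle number.

## Synthetic panels

The generator samples `k_a` in [1e3, 1e7] M^-1 s^-1, `k_d` in [1e-6, 1e-3]
s^-1, `n` in [10, 1000], `c0` in [1e-7, 1e-3] M log-uniformly, with
nanoparticles at 1 nM and three species by default — engineering choices
spanning serum-plausible magnitudes, not measured values.  Draws are
rejected (deterministically from the same stream) until `epsilon <= 0.01`,
so generated panels sit in the two-phase regime the model describes; the
rejection can be disabled.  Each panel reports its regime flags (epsilon
and the protein-excess factor).

The demonstration panel is constructed, not measured: three species whose
fast-phase ranking (set by `k_a c0`) and equilibrium ranking (set by
`K c0`) differ, with `epsilon < 1e-4` and large protein excess.  What
passing tests on these panels shows is that the *model's* internal
structure is consistent (closed forms match their simulation oracles, the
reduction error scales as predicted, the stochastic process has the stated
mean-field limit); it does not show that any real serum corona follows
these dynamics — real systems add irreversible binding, conformational
change and protein–protein interaction, all outside scope.

## Problem sizes

Default test and acceptance runs use 20–100 synthetic panels per property,
500-particle stochastic ensembles with 10–20 replicates, and 60–300-point
output grids; these sizes put every statistical bound well inside its
tolerance while keeping the whole suite in the low minutes on one CPU.

## Known limitations

* The metastable formula degrades when protein excess fails; the package
  warns and recommends the empirical fast-phase composition instead.
* The reduced model is meaningless for panels with any `k_d = 0` and
  dubious for `epsilon > 0.01`; both cases are rejected or flagged.
* The stochastic simulator's replicate means deviate from the ODE by
  O(1/n_i) near complete coverage (increment clipping, discussed above).
* No global (variance-based) sensitivity analysis; sensitivities are local
  logarithmic derivatives.
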