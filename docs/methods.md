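# Methods

## Model and assumptions

Two cell populations compete on a proportion scale inside the box
`0 ≤ x1 ≤ K1`, `0 ≤ x2 ≤ K2`: healthy cells `x1` grow logistically at rate
`alpha1` toward carrying capacity `K1` and are suppressed by malignant cells
at rate `beta1` and by collateral radiation at rate `epsilon*gamma`;
malignant cells `x2` grow at `alpha2` toward `K2`, are suppressed by healthy
cells at `beta2` and killed by radiation at `gamma`. The dose rate `gamma`
is constant over a run (no fractionation schedule), and `gamma = 0` encodes
the untreated system. All rates are per hour.

The time derivative is the fractal-fractional operator with Mittag-Leffler
kernel: fractional order `mu` sets the memory depth (the state's history
enters through a weakly singular convolution kernel), fractal dimension `nu`
replaces `t` by `t^nu` as the differentiation variable (modelling irregular
temporal structure of tissue response). Both indices live in `(0, 1]`;
`mu = nu = 1` is the classical memoryless system, and every classical-limit
quantity in this package is checked against an adaptive ODE solution.

### Reference scenarios

Three reference patients share all biological rates
(`alpha1 = 9.7041e-4`, `alpha2 = 0.3396`, `beta1 = 0.0433`,
`beta2 = 0.2385`, `K1 = K2 = 1`, `epsilon = 8e-4` per hour / dimensionless)
and differ in dose rate and initial proportions: high arms
`gamma = 0.75 / 0.65 / 0.85` Gray/h, every low arm `gamma = 0.35`, initial
states `x1(0) = x2(0) = 0.284 / 0.174 / 0.306`. These presets are frozen in
`ffrt.scenarios` and drive all headline checks. For every treated arm
`R0 < 1` and `epsilon*gamma < alpha1`, so the cancer-free equilibrium
`E0 = (K1(alpha1 - gamma*epsilon)/alpha1, 0)` is feasible and locally stable
at every fractional order (both eigenvalues real negative, so the Matignon
angle condition `|arg λ| > mu·π/2` holds trivially).

## Operator conventions

Published presentations of the fractal-fractional integral disagree about
the fractal weight: the power-law form is printed with `ξ^(ν-1)`, the
exponential and Mittag-Leffler forms with `t^(1-ν)`/`ξ^(1-ν)`, and the
numerical scheme is derived with weight `ν σ^(ν-1)` plus a local term
`ν t^(ν-1)(1-μ)/AB(μ)`. This package fixes the scheme's convention as
canonical for the Mittag-Leffler-kernel integral, because (a) the numerical
results flow from it and (b) it is the unique choice among the printed
variants that reduces to the plain Riemann integral at `mu = nu = 1`. The
power-law integral keeps its own printed form `(1/Γ(μ)) ∫ (t-ξ)^(μ-1)
ξ^(ν-1) z dξ`. The exponential-kernel operator is out of scope (no stepping
scheme exists for it here), and the `(2-ν)` normalization sometimes attached
to the pointwise fractal derivative is documented but consumed by no
computation — the solver needs only integrals.

Quadrature: both integrals integrate the doubly singular kernel
`σ^(ν-1)(t-σ)^(μ-1)` exactly against the piecewise-linear interpolant of the
sampled integrand, using regularized incomplete Beta functions for the cell
moments. No regularization constants are introduced at the `σ = 0` or
`σ = t` singularities. The operators are exactly linear by construction and
match Beta-function closed forms for constant and power-law integrands to
better than 1e-5 at the tested resolutions.

The Mittag-Leffler function is summed as its power series with stopping rule
`|term| < 1e-16·|partial sum|` and a 10,000-term cap; summation runs in
arbitrary precision with the working precision raised until the observed
cancellation (ratio of largest term to the sum) is covered, so alternating
arguments such as `E_1(-20)` are returned to full double accuracy.
Arguments the series cannot reach within the cap raise an error rather than
silently switching algorithms.

## The stepping scheme

Writing `A = (F1, F2)` for the vector field and `t_v = v·Δt`,

```
x^{r+1} = x^0 + ν t_r^{ν-1} (1-μ)/AB(μ) · A(t_r, x^r)
          + μν Δt^μ / (AB(μ) Γ(μ+2)) ·
            Σ_{v=0}^{r} [ t_v^{ν-1} A_v · w1(q) - t_{v-1}^{ν-1} A_{v-1} · w2(q) ]
w1 = q^μ (q+1+μ) - p^μ (1+2μ+q),   w2 = q^{μ+1} - p^μ (q+μ),   q = r+1-v, p = q-1.
```

The weights come from integrating the memory kernel exactly against the
two-point Lagrange interpolant on each history cell. At `μ = 1` they
collapse to `(3, 1)` for every lag and the scheme is exactly the
Euler-started two-step Adams-Bashforth method; empirical order 2 is
confirmed by Richardson estimates, and max-norm agreement with a DOP853
solution at rtol = atol = 1e-10 is ~5e-6 at `Δt = 0.01` over 200 h.

Two boundary conventions, applied once and documented here:

* the `v = 0` term references `t_{-1}`, `x^{-1}`; these are defined as
  `t_0`, `x^0`, so the first step degenerates to an Euler step and the
  choice is irrelevant once `r` grows;
* for `ν < 1` the fractal weight `t^(ν-1)` is singular at `t_0 = 0`; the
  `t = 0` node uses `t := Δt` instead (one-cell regularization, exact for
  `ν = 1`, logged whenever it engages).

Cost is O(n²) in the step count from the full history sum; the inner sums
are BLAS dot products, which keeps n ≈ 2·10⁴ under a second per run. No
fast-history compression is implemented. States are never clipped: a
non-finite state raises naming the step, and any component below -1e-9 logs
a positivity warning. Default `Δt = 0.05` h; the table regeneration refuses
the "converged" label unless halving `Δt` changes no reported 4-decimal
value. For `μ < 1` the scheme is self-convergent but at reduced empirical
order (≈0.5–0.7 on these problems), the expected behavior of explicit
product-integration schemes near the `t = 0` kernel singularity.

## Stability analytics

The analytic Jacobian of the vector field is authoritative for all
eigenvalue verdicts; it is validated against central finite differences.
The published closed-form Jacobian at `E0` has an inconsistent (2,2) entry
(it omits `alpha2` and uses `beta1`); that form is exposed only through
`model.eigenvalues_at_E0_as_printed` for comparison — on the reference
scenarios both forms give negative values, so no verdict changes. Likewise
the healthy-free equilibrium is implemented as
`E* = (0, K2(alpha2 - gamma)/alpha2)` (the structurally correct carrying
capacity; with `K1 = K2 = 1` the printed variant is numerically identical).
The pointwise logistic comparison bound sometimes quoted for boundedness is
printed without its `(1/x(0) - 1/K)` term; only its correct asymptotic
consequence (lim-sup `x_i ≤ K_i`, checked on the final quartile of a
trajectory with a 1e-6 tolerance band that absorbs adaptive-solver jitter in
extinction tails) is implemented.

### Lyapunov diagnostics

The Volterra function `L = Σ (x_i - x_i* - x_i* ln(x_i/x_i*))` handles
boundary references by the limit `x* ln(x/x*) → 0`, leaving the bare `x_i`
term, so `L` stays finite against `E0` and `E*`. Three derivative-like
quantities are exposed and deliberately kept distinct:

* `lyapunov_time_derivative` — the exact chain rule `∇L·F`; finite
  differences of `L` along trajectories reproduce it to 1e-3.
* `lyapunov_decomposition` — the published quadratic split Υ1/Υ2 of the
  dissipation balance. Its derivation evaluates the vector field at the
  deviations `x_i - x_i*`, so it is **not** algebraically identical to
  `∇L·F` away from the reference; along the converging treated trajectories
  the two agree in sign everywhere, and `Υ1 < Υ2` is the LaSalle-style
  dominance evidence reported by `global_stability_check`.
* `lyapunov_second_derivative` — the analytic derivative of the chain-rule
  form (cross-checked by differencing it numerically).

Points with a state component below 1e-9 (extinction tails) are excluded
from the pointwise trace and counted; evaluation below 1e-12 raises rather
than returning infinities. The threshold `Rh` is reported together with the
truth value of `Rh > 1`, but that condition is never used to assert global
stability: on the reference scenarios `Rh ≈ 0.0086` while the trajectories
nevertheless converge to `E0`, so the numeric Lyapunov evidence, not the
threshold, carries the conclusion.

## Existence and uniqueness constants

On a bounded horizon the squared components are bounded by
`M = (sup|x1|², sup|x2|²)`, defaulting to the invariant-region bounds
`(K1², K2²)`. The four constants

```
k1 = 4(alpha1² + alpha1²/K1²·M1 + beta1²·M2 + epsilon²gamma²)
k2 = 4(alpha2² + alpha2²/K2²·M3 + beta2²·M4 + gamma²)
k̄1 = 4alpha1² + 4alpha1²/K1²(2M5+2M6) + 4beta1²M7 + 4epsilon²gamma²
k̄2 = 4alpha2² + 4alpha2²/K2²(2M8+2M9) + 4beta2²M10 + 4gamma²
```

bound `|F_i|² ≤ k_i(1+|x_i|²)` and `|F_i(a)-F_i(b)|² ≤ k̄_i|a_i-b_i|²` (the
non-varied component frozen at its sup, matching the derivation). The ten
sup slots all reduce to the two suppliable scalars and are expanded back in
the report for traceability. Verification samples 10,000 states uniformly in
the box at a caller-visible seed; the derived constants are conservative by
construction (worst observed ratios ≈ 0.1–0.4 on the reference scenarios).

## Table regeneration and what is reproducible

The published 8×4 result grids (report times 50–400 h ×
`mu ∈ {0.75, 0.85, 0.95, 1}`, fractal dimension 1) are embedded as a data
fixture and regenerated by `reproduce_tables`, rounding half away from zero
to 4 decimals. Only the malignant-cell extinction cells (the 0.0000 entries)
are treated as ground truth: at `mu = nu = 1` the system is the unambiguous
classical ODE whose malignant decay rate (≈0.35–0.58 h⁻¹ across patients)
drives `x2` below 1e-20 long before the reported times, independent of any
reasonable step size. The remaining printed values are mutually inconsistent
with direct integration of the stated system (e.g. the printed healthy-cell
growth to 0.3019 by 400 h would need ≈5× the maximum net growth rate the
parameters permit, and the printed `mu = 1` malignant value at 50 h implies
a decay rate ≈6× slower than the model's), and the source's step size and
reporting convention are unknown; report times are interpreted as model
hours. The regeneration therefore emits a quantified side-by-side
discrepancy report, and tests assert only the reproducible cells plus the
qualitative structure: malignant values fall with time in every column and
with rising `mu` in every row (deeper memory retards extinction), and
healthy cells decline initially under competition and converge toward `E0`
— with a dip-then-recover shape exactly for the patients whose `E0` healthy
coordinate exceeds the initial proportion (patients 1 and 2; patient 3's
`E0.x1 = 0.2993` lies below its start 0.306, so it approaches from above).

## Synthetic observations and fitting

No real treatment-course measurements ship with the package. The generator
integrates a scenario and adds independent Gaussian noise (default study
condition: SD 0.005 on the proportion scale, 200 observation points over
~100 h, explicit seed) to both series. This emulates dense, homoscedastic,
uncorrelated measurement error on both populations; real radiotherapy data
are sparser, usually observe tumour burden only (not the healthy
proportion), and carry correlated, state-dependent error — so passing
recovery tests demonstrate identifiability of the fitting machinery under
the stated noise model, not clinical identifiability. Fitting minimizes the
summed squared residual of both series over a caller-chosen free-parameter
subset by bounded trust-region least squares with seeded multi-start
(3 starts: the template value plus uniform draws in the bounds). Zero-noise
fits recover the dose rate to 1e-4; at SD 0.005 recovery is within 5%.

## Numerical choices and degenerate inputs

* Construction rejects non-positive growth rates or capacities and negative
  competition/dose parameters; thresholds raise on zero denominators.
* Rounding for table artifacts is half away from zero via decimal
  arithmetic, not banker's rounding.
* Trajectory CSV export writes `repr`-exact doubles with provenance header
  comments and is byte-deterministic for identical inputs.
* Problem sizes used by the shipped checks: classical-limit comparisons run
  at `Δt = 0.01` over 200 h; table regeneration at `Δt = 0.05` (confirmed
  by a `Δt/2` rerun) over 400 h; Lyapunov traces at `Δt = 0.05–0.1`;
  existence sampling at n = 10,000.

## Known limitations

* The exponential-kernel fractal-fractional operator is documented only; no
  stepping scheme or normalization for it is implemented.
* No two-parameter Mittag-Leffler function.
* The dose rate is constant per run: no fractionation schedules or
  treatment optimization.
* The explicit scheme's accuracy for `mu < 1` near `t = 0` is limited by
  the kernel singularity (no graded meshes or starting corrections);
  fractional-order results should be quoted with a self-convergence check
  (`convergence_study`).
* Global stability is evidenced numerically along computed trajectories,
  not proven symbolically.
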