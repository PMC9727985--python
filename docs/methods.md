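# Methods

## Generating mechanisms

Two mechanisms produce continuous outcomes for balanced two-condition
parallel designs with `g` groups per condition, `m` members per group and `t`
equally spaced periods (default time values 0, 1, …, t−1, used raw and
uncentered):

* **RM-ANOVA**: categorical time. Random intercepts for group (`s2_g`),
  time × group (`s2_tg`), member (`s2_m`, cohort only), plus residual
  (`s2_e`). With one observation per member per occasion a time × member
  intercept is indistinguishable from residual error, so it is constrained to
  zero.
* **Random coefficients (RC)**: linear time. Random intercepts and slopes at
  the group level (`s2_g`, `s2_t(lin)g`) and, for cohort data, at the member
  level (`s2_m`, `s2_t(lin)m`), plus residual. Intercepts and slopes are
  generated independently by default; `VarianceComponents.cov_g` / `cov_m`
  allow a nonzero intercept-slope covariance when wanted.

All random effects are independent normals. Fixed effects default to zero
everywhere (the type I error setting); arbitrary condition, period,
interaction and slope effects are supported with reference-level constraints
(condition 1 and period 1 are references).

Cross-sectional data draw a fresh set of `m` members per period; member
identifiers encode condition, group and period of entry so both structures
share one long-format schema (`member_id, group_id, condition, period, time,
y`).

## Correlation algebra

The four summaries (WPICC, BPICC, CAC, IAC) are the standard variance-ratio
expressions given in the README. RC components are summarized through the
same definitional mapping, with slope variances occupying the time-varying
slots; the genuinely time-dependent between-period correlation of RC data is
deliberately not summarized (a known non-constant function of time, out of
scope here). `solve_components` inverts the algebra: with the group-level
variances anchored (the study grid uses `s2_g = s2_tg = 1`, or `s2_tg = 0.1`
for the CAC ≈ 0.91 variant), the residual variance follows from the WPICC
target, and for cohort structures the member variance follows from the IAC
target with the time × member variance held fixed (0 under RM, the member
slope variance — default 1 — under RC). Infeasible targets (e.g. an IAC
requiring negative residual variance) raise with an explanation. Negative
input components — which arise legitimately from unconstrained fits — pass
through the formulas unchanged with a warning.

## The REML engine

Every analytic model in the registry has a marginal covariance that is
*linear* in its parameters. For one group's stacked outcomes (member-major),

    V(theta) = sum_r theta_r [ J_m ⊗ B_r  +  I_m ⊗ A_r ],

with t × t group-level patterns `B_r` (intercept `J_t`, time × group `I_t`,
unstructured `E_jk`, slope patterns built from the time values) and
within-member patterns `A_r` (member random effects, residual `I_t`,
unstructured R matrices). Because all fixed effects are constant across
members within a group-period, an orthonormal change of basis per group —
the member-mean series plus `m − 1` member-contrast series — block-
diagonalizes `V` exactly: the mean series has covariance `m·B + A` and
carries the fixed effects; each contrast series has covariance `A` and mean
zero. The transform is orthogonal, so the REML criterion, the fixed-effect
GLS solution, and every Kenward-Roger ingredient are *identical* to the
individual-level computation while all dense algebra is t × t. The test
suite pins this with a brute-force dense multivariate-normal REML oracle
(full n × n covariance assembled pair-by-pair from the model definition).

Estimation is Fisher scoring — the expected-information Newton step, which
for linear covariance structures is the natural algorithm (the profiled
criterion is close to quadratic in `theta`; correctly specified registry
models typically converge in 1–3 iterations) — with step-halving, and
**no nonnegativity constraint** on the parameters ("nobound"): any `theta`
with positive-definite stratum covariances is admissible, and negative
variance estimates are reported with a flag rather than truncated.

* Starting values: method-of-moments. The mean- and contrast-stratum
  empirical covariances are targeted by a least-squares projection onto the
  templates; if the projected start is not positive definite it is blended
  toward a safe diagonal start built from the pooled variance.
* Convergence: relative log-likelihood change ≤ 1e−10 *and* natural-gradient
  norm ≤ 1e−6; at most 200 iterations; one perturbed restart before a fit is
  declared non-convergent. Non-convergence is a reported result
  (`converged = False`), never an exception inside a simulation loop.
  Degenerate inputs (e.g. exactly constant outcomes, which send the REML
  criterion to infinity) end in that state by construction.
* UN matrices are parameterized elementwise (symmetric, unconstrained), not
  via Cholesky factors, because the unbounded contract must admit
  non-positive-definite G blocks as long as the assembled stratum
  covariances stay positive definite; inadmissible iterates are rejected by
  step-halving.

### Group-mean fitting

The cross-sectional RM-ANOVA-with-UN and both saturated models are fitted on
group means by default, as a t-dimensional series per group with one
unstructured t × t covariance (15 parameters for t = 5): at that level the
group-level UN matrix, the time-invariant group variance and the scaled
residual are aliased and collapse into a single identifiable UN block. A
`force_individual` flag fits the full individual-level formulation instead
(16, 20 or 30 parameters, matching the registry accounting); for balanced
data the likelihood factorizes so the interaction F-test — including its
Kenward-Roger df — is identical between the two formulations, and the test
suite asserts that equality to 1e−8.

## Small-sample inference

The time × condition interaction ((t−1)(c−1) contrasts under categorical
coding, c−1 under linear coding) is tested with a scaled F statistic.

* **Kenward-Roger**: the model-based covariance of the fixed effects is
  inflated for the uncertainty of the covariance-parameter estimates, using
  the inverse *expected* REML information as the covariance of `theta`; the
  scale factor and fractional denominator df come from matching the first
  two moments of the Wald statistic to a scaled F distribution. Because all
  structures here are linear in `theta`, the second-derivative terms that
  distinguish the improved ("kr2") adjustment from the original first-order
  one vanish, so the `kr1`/`kr2` options share one code path. The
  implementation reproduces the known exact cases (OLS limit `ddf = n −
  rank X`; the balanced one-period nested ANOVA F with `ddf = cg − 2`) and
  agrees with the independent `pbkrtest` R implementation to at least four
  significant figures on reference fits. Where the moment matching
  degenerates (non-positive scale denominators) the test falls back to the
  OLS-limit df and says so in its `note`.
* **Between-within**: integer design-based df. Effects varying within groups
  (time, interaction) receive `n − G − (within-group columns)`; group-
  constant effects (condition) receive `G − (between columns)`. `n` and the
  column counts refer to the fitted level (individual or group-mean).

Fractional df are never rounded; p-values are upper-tail F probabilities.

## Monte Carlo harness

A scenario couples one mechanism (design + components, zero fixed effects)
with a list of analytic models. Per replication: simulate, fit every model
(design matrices and covariance templates are compiled once per scenario),
test the interaction, and record `p ≤ alpha`. The rejection proportion over
converged fits estimates the type I error rate, with a 95% Wilson score
interval; non-convergent replications are excluded from the denominator and
counted separately — the transparent choice, logged with a replayable seed.
Replication seeds derive deterministically from `(base_seed, rep)`, so any
flagged fit can be reproduced in isolation, and grid runs with the same
config and seed are byte-identical. The YAML grid config rejects unknown
keys and accepts either explicit components or correlation targets (routed
through `solve_components`).

Problem sizes: the package defaults to 300 replications per scenario — large
enough that a Wilson interval around a true 5% rate spans roughly ±2.5
percentage points, small enough that a scenario at the study's largest
per-fit cost (cohort, 40 members × 5 periods, 20 groups) runs in seconds —
while the historical 1000-replication setting remains an ordinary config
value.

## What the synthetic data do and do not establish

The generator emulates exactly the stated mechanisms: independent normal
random effects, balanced designs, no missingness, equal group sizes, linear
time trends in the RC case. Passing tests therefore demonstrate *internal*
validity — the algebra, the estimator and the test behave as designed under
their own assumptions — and reproduce the qualitative operating
characteristics (nominal error control of the RC and saturated models with
KR df; inflation of models that omit an existing time × group effect,
growing with the WPICC). They do not speak to non-normal outcomes,
informative attrition, unbalanced clusters, decaying autocorrelation
structures, or mean-model misspecification beyond the time codings studied.

## Accounting choices

The registry reproduces the published covariance-parameter accounting for
all fourteen model variants. Two cells require a documented interpretation:

* Cross-sectional RM-ANOVA with UN, time × group (16 parameters): the
  time-invariant group variance is absorbed by the unstructured matrix on
  the time × group effects, so the fitted formulation is UN(5) + residual.
* Cohort RC, intercept only (4 parameters): with the group slope dropped,
  the member intercept and slope are kept as *independent* components
  (group intercept + 2 member variances + residual); keeping their
  covariance would give five parameters and dropping the member slope three,
  neither matching the published count.

## Known limitations

* The engine requires balanced data (the designs under study); unbalanced
  datasets are rejected with a schema error rather than fitted.
* Only linear covariance structures are supported — which covers VC, CS,
  UN, UN(1) and random-coefficient blocks, but not exponential-decay
  autocorrelation structures.
* The between-within rule implemented is the classic containment-free
  partition; software packages differ in corner cases outside this design
  family.
* Power analysis under nonzero fixed effects works incidentally (the
  generator accepts arbitrary effects) but has no dedicated surface.
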