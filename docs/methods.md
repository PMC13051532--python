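# Methods

## Model

`idmaft` fits a parametric illness–death model for semi-competing risks on
the age scale. Three transition-specific Weibull accelerated-failure-time
(AFT) submodels describe disease incidence (*i*, healthy → diseased),
mortality without disease (*m0*, healthy → dead) and mortality after
diagnosis (*m1*, diseased → dead):

    log T_p = x'β_p + u_p + (1/κ_p) ε_p,    p ∈ {i, m0, m1},

equivalently: conditional on covariates `x` (a design vector with leading 1)
and a subject-level random effect `u_p`, the event age is Weibull with scale
`η_p = exp(x'β_p + u_p)` (years) and shape `κ_p > 0`,
`S_p(t) = exp(−(t/η_p)^κ_p)`. A note on naming: in the AFT formulation the
error-scale multiplier is `1/κ_p`; everywhere in this package `κ_p` denotes
the Weibull *shape* — the convention under which the mean and median event
ages are `exp(x'β_p) Γ(1 + 1/κ_p)` and `exp(x'β_p) (log 2)^{1/κ_p}`.

The m1 transition is Markov in age: the post-diagnosis death hazard depends
only on current age, so `S_m1(t2 | t1) = S_m1(t2)/S_m1(t1)`.

Effect measures: `exp(β)` is the acceleration factor (multiplicative effect
on the event age); for the Weibull family this converts exactly to a
proportional-hazards ratio `HR = exp(−κ β)`, so a negative β (earlier
events) yields HR > 1.

## Observed data and likelihood

Each subject contributes `O = ([Tl, Tr], δ1, Y2, δ2, L, x)`: entry age `L`,
the interval `[Tl, Tr]` bracketing disease onset (degenerate `[Y2, ∞)` when
no diagnosis was observed, `δ1 = 0`), last observed age `Y2 = min(T2, C)`
and the death indicator `δ2`. The four contribution cases (conditional on
`x` and `u`):

| δ1 | δ2 | contribution |
|----|----|--------------|
| 1  | 1  | `[S_i(Tl) − S_i(Tr)] · S_m0(Tr) · f_m1(Y2) / [S_i(L) S_m0(L) S_m1(T*)]` |
| 1  | 0  | as above with `S_m1(Y2)` in place of `f_m1(Y2)` |
| 0  | 1  | `S_i(Y2) · f_m0(Y2) / [S_i(L) S_m0(L)]` |
| 0  | 0  | `S_i(Y2) · S_m0(Y2) / [S_i(L) S_m0(L)]` |

Division by `S_i(L) S_m0(L)` conditions on being healthy and alive at study
entry (left truncation / delayed entry). The post-diagnosis death
distribution is left-truncated at `T*`, an imputed onset age; by default the
interval midpoint `Tm = (Tl + Tr)/2` (the right bound `Tr` is available via
`m1_truncation="right"`), because with long visit intervals truncating at
`Tr` biases the m1 distribution more.

**Truncation-point cap (numerical/statistical guard).** A visit interval
built around the true onset age can extend past the death or censoring age
(death inside the visit interval), putting `Tm > Y2`. Conditioning the m1
distribution on survival beyond an observed death makes the contribution an
improper conditional (probability > 1) and the log-likelihood *unbounded*
in `κ_m1` — in early-censoring settings the optimizer finds log-likelihoods
of order 1e300 and garbage estimates. The truncation point is therefore
always capped at the last observed age, `T* = min(Tm, Y2)`.

Random effects `u = (u_i, u_m0, u_m1)` are trivariate normal with mean zero.
Two structures are exposed: `homvar` — a single shared effect
`u ~ N(0, s²)` added to all three linear predictors — and `hetvar` —
transition-specific variances `s_i², s_m0², s_m1²` with covariances
`c_{i,m1}` and `c_{m0,m1}`; the (i, m0) covariance is fixed at zero
(mortality without the disease is taken as independent of the onset
process). `structure="none"` drops the random effect entirely.

The marginal likelihood integrates `u` out by **non-adaptive Gauss–Hermite
quadrature**, default 2 nodes per dimension (1-d grid for homvar, a
tensor-product `n³` grid mapped through a symmetric eigenvalue square root
of the covariance for hetvar — the symmetric root degrades gracefully as
variances approach zero, where a Cholesky factor would fail). Weights are
normalized to sum to one. The node mixture is accumulated with log-sum-exp:
individual contributions underflow at realistic ages. Increasing `n_points`
(8–16) changes the log-likelihood by well under 1e-4 at the variance
magnitudes relevant here, which is why the 2-point default is adequate.

All survival quantities are evaluated in log space
(`log S = −exp(κ(log t − log η))`) so large ages and shapes cannot
overflow. Subjects whose contribution is zero at every node raise an error
naming their row indices; inside the optimizer they are instead floored at
a large finite penalty (−1e4 per subject) so line searches see a finite,
informative objective rather than a cliff.

## Estimation

1. **Warm starts.** Three univariate transition models without random
   effects are fitted first (each maximizing only its own factor of the
   likelihood), initialized from moment estimates
   (`κ ≈ cv^−1.086` from the coefficient of variation of the relevant event
   ages). Transitions with zero informative events fall back to the moment
   initialization with a warning.
2. **Random-effect grid.** Variances are initialized by a coarse grid
   search over {1e-6, 1e-4, 1e-2} (values near zero are deliberately
   included: small starting variances avoid numerical trouble).
3. **Optimization.** Bounded quasi-Newton (L-BFGS-B, numerically
   differenced gradients, iteration cap 500). Working scale: β natural
   (bounded ±20), `log κ` (κ ∈ [0.05, 60]), `log` variances (down to
   e^−25 ≈ 0), and the two hetvar correlations through a sequential bounded
   transform `r_{i,m1} = tanh(z₁)`,
   `r_{m0,m1} = tanh(z₂)·sqrt(1 − r_{i,m1}²)`, which keeps the covariance
   matrix positive semi-definite for every real `(z₁, z₂)`.
   Because the likelihood is nearly flat in `log`-variance near the
   zero-variance boundary, a boundary candidate (variances at the lower
   bound) is checked after optimization and adopted if it improves the fit.
4. **Convergence.** Declared on optimizer success, or when a polish restart
   from the terminal point improves the objective by less than a relative
   1e-8 (line-search aborts at the optimum are common with
   finite-difference gradients and are not failures).
5. **Uncertainty.** Central finite-difference Hessian of the negative
   marginal log-likelihood at the optimum (relative step 1e-3); delta
   method maps the working-scale covariance to the natural scale. A
   near-singular information matrix (typical when a variance sits at the
   zero boundary) triggers a pseudo-inverse and NaN flags on the affected
   standard errors. Wald intervals are formed on the natural scale;
   acceleration-factor intervals exponentiate the β interval; hazard-ratio
   and profile-summary (mean/median age, median-survival-difference)
   intervals use the delta method on the joint natural-scale covariance.
   AIC = −2ℓ + 2k, BIC = −2ℓ + k·log n with n the number of subjects.

## Synthetic-data generator

The generator emulates an ageing-cohort study (dementia-like in its default
calibration):

1. random effects from N(0, Σ_gen) with Σ_gen variances
   (0.008237, 0.000714, 0.000063), `cov(u_i, u_m1) = 0.000115` and the
   other covariances zero;
2. a binary sex covariate, P(male) = 0.4;
3. latent onset and disease-free death ages from the i and m0 Weibulls;
4. when onset precedes disease-free death, the death age is redrawn from
   the m1 distribution left-truncated at the onset age by inverting the
   truncated cumulative hazard,
   `t2 = (t1^κ − η^κ log(1−U))^{1/κ}` (exact, no rejection);
5. entry age ~ U(55, 60) and censoring age ~ U(85, 95) (early) or
   U(95, 105) (late); subjects entering after an event age are deleted
   (left truncation);
6. a subject is diagnosed (δ1 = 1) iff onset precedes both death and
   censoring; the visit interval is then `[max(t1−U₁, l), t1+U₂]` with
   independent U₁, U₂ ~ U(0, 3) (visits at most 6 years apart), so the
   interval always brackets the true onset and never precedes study entry.
   The interval's right bound may legitimately exceed the last observed age
   (death inside the interval); the likelihood handles this (see the
   truncation cap above).

Transition truth: sex coefficients (0.03, −0.04, −0.08) and shapes
(7.0, 10.8, 8.1). The shapes are back-solved from the reported
(β, AF, HR) triples of the dementia-cohort fit via `κ = −log(HR)/β` and are
recorded openly in the scenario catalogue as assumptions. Intercepts are
calibrated so the *reference (female) profile* attains target mean event
ages — onset 95, disease-free death 85, post-diagnosis death 65 or 80 —
through `β₀ = log(E/Γ(1+1/κ))`. The lognormal random-effect factor lifts
the marginal (over-u) mean by `exp(σ²/2)`, ≈ 0.4% (95.0 → ≈ 95.4) at the
default variances.

The shipped catalogue crosses early/late censoring × post-diagnosis mean
(65/80) × initial cohort size (2400/1200/500), named `E65_L` … `L80_S`.
Each replicate is seeded by `SeedSequence([scenario_seed, replicate_index])`
so scenario × replicate is reproducible independently of execution order.

What the generator does *not* emulate: visit processes tied to covariates
or health state, non-uniform entry/censoring laws, measurement error in the
death age, or covariate-dependent random-effect variance. Passing recovery
tests on these cohorts therefore demonstrates correctness of the estimator
under its own sampling assumptions, not robustness to real-data violations
of them.

## Simulation-study harness and what it shows

`run_study` executes scenario × structure × replicate grids with optional
per-replicate CSV checkpoints (restartable; any execution order yields the
identical archive). Metrics per parameter: median bias, MSE, empirical
coverage of Wald 95% intervals, and convergence counts; metrics are
computed over converged replicates only, with the counts reported
alongside. Derived Weibull mean/median summaries per sex are compared
against the truth computed from the generating parameters by the same
closed forms.

Reduced studies of 100 replicates (rather than a four-digit count) are the
package's default validation size; the harness accepts any replicate count.
At n_initial = 2400 under early censoring, the HomVar model converges on
100/100 replicates, recovers all six regression coefficients with |median
bias| ≤ 0.011 and the covariate (sex) coefficients with coverage in
[0.90, 0.98]. Two known limitations, both consequences of the likelihood's
deliberate approximations (onset imputed at the interval midpoint for the
m1 truncation; `S_m0` evaluated at `Tr`):

* shape parameters κ carry visibly more bias than regression coefficients
  (|median bias| up to ≈ 0.5 here); their coverage degrades with increasing
  sample size as standard errors shrink around a fixed approximation bias;
* intercept coverage at n = 2400 falls below the nominal level
  (≈ 0.81–0.93) for the same reason — a few-per-mille systematic bias is
  large relative to an intercept standard error of ≈ 0.003.

Under the transition-specific generator the fitted HomVar shared variance
has no single true counterpart; its bias/coverage are reported as
undefined. The HetVar variance components are weakly identified at the
generating magnitudes (1e-4 … 1e-2 on the log-age scale) and often sit at
their small initial values — the regression and shape parameters are
unaffected.

## Degenerate inputs and edge cases

* `s² = 0` (or structure `none`): the quadrature grid degenerates to a
  single node at zero and the marginal likelihood equals the
  no-random-effect likelihood exactly.
* Diagnosis intervals starting before study entry (possible in real data):
  the left bound is clamped to the entry age with a warning; a clamp that
  empties the interval yields a −inf contribution flagged by subject index.
* Datasets are validated on read: indicator columns in {0,1}, non-negative
  ages, `last_age > entry_age`, finite `Tl < Tr` for diagnosed rows;
  undiagnosed rows get `[Y2, ∞)` filled automatically; the right bound is
  written as the literal `inf` and read back from `inf` or an empty field.
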