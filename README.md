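# idmaft

**Parametric Weibull accelerated-failure-time (AFT) illness–death model for
semi-competing risks data.**

In cohort studies of chronic disease, death competes with the disease of
interest asymmetrically: death can censor disease onset, but a diagnosed
subject can still die. `idmaft` models this semi-competing structure with a
three-state illness–death model — healthy, diseased, dead — and one Weibull
AFT regression per transition: disease incidence (*i*), mortality without
disease (*m0*) and mortality after diagnosis (*m1*). On the age scale,

```
log T_p = x'β_p + u_p + (1/κ_p) ε_p ,   p ∈ {i, m0, m1},
```

so that given covariates `x` and the subject-level random effect `u_p`, the
event age is Weibull with scale `η_p = exp(x'β_p + u_p)` and shape `κ_p`.
Covariates act multiplicatively on the event *age*: `exp(β)` is an
acceleration factor (AF), directly interpretable as a ratio of event ages,
and convertible to a hazard ratio via `HR = exp(−κβ)`.

The observed-data likelihood handles, per subject:

* **left truncation** — subjects enter at age `L` and must be event-free at
  entry (the contribution is divided by `S_i(L) S_m0(L)`);
* **interval censoring** of disease onset — onset is only known to lie
  between the last disease-free visit `Tl` and the first visit with
  diagnosis `Tr` (contribution `S_i(Tl) − S_i(Tr)`);
* **right censoring** of death at the study end;
* a trivariate normal **random effect** linking the three transitions,
  integrated out by non-adaptive Gauss–Hermite quadrature (default 2 nodes
  per dimension), in a shared-variance (`homvar`) or transition-specific
  (`hetvar`) structure.

The package also ships the **synthetic cohort generator** and the
**simulation-study harness** (scenario catalogue, replicate grids, median
bias / MSE / coverage / convergence metrics) used to validate the estimator.

## Worked example

```python
import idmaft

# generate an early-censoring cohort: 2400 subjects entering at ages 55-60,
# censored at 85-95, mean onset age 95, mean death ages 85 (healthy) / 65
# (after diagnosis)
scen = idmaft.scenario("E65_L", seed=42)
dataset, truth = idmaft.generate(scen)

fit = idmaft.fit(dataset, structure="homvar", n_points=2)
print(fit.summary().round(4))
```

```
           estimate      se  ci_low  ci_high
parameter
b0_i         4.6105  0.0110  4.5890   4.6320
b1_i         0.0191  0.0135 -0.0074   0.0456
kappa_i      6.8800  0.3921  6.1114   7.6485
b0_m0        4.4890  0.0035  4.4821   4.4959
b1_m0       -0.0332  0.0052 -0.0434  -0.0231
kappa_m0    10.5235  0.2717  9.9910  11.0560
b0_m1        4.2196  0.0201  4.1802   4.2590
b1_m1       -0.0677  0.0121 -0.0914  -0.0439
kappa_m1     7.9307  0.5354  6.8813   8.9801
s2           0.0000  0.0000  0.0000   0.0000
```

The generating values were `β = (4.62, 0.03)`, `(4.49, −0.04)`,
`(4.23, −0.08)` and `κ = (7.0, 10.8, 8.1)`: one cohort recovers every
regression coefficient well inside its Wald interval. Effects convert to
acceleration factors and hazard ratios with intervals:

```python
print(idmaft.effect_table(fit, covariate_names=["sex"]).round(3))
#   transition covariate   beta     af     hr  ...
# 0          i       sex  0.019  1.019  0.877
# 1         m0       sex -0.033  0.967  1.419
# 2         m1       sex -0.068  0.935  1.711
```

and per-profile mean/median event ages (years) with delta-method intervals:

```python
for s in idmaft.profile_summaries(fit, {"female": [0.0], "male": [1.0]}):
    print(s.profile, s.transition, round(s.mean, 1), round(s.median, 1))
# female i 94.0 95.3     male i 95.8 97.2
# female m0 84.9 86.0    male m0 82.1 83.2
# female m1 64.0 64.9    male m1 59.8 60.7
```

A thin CLI mirrors the library:
`idmaft simulate --scenario E65_S --seed 1 --out cohort.csv`, then
`idmaft fit --data cohort.csv --structure homvar --out fit.txt`, plus
`simstudy`, `profiles` and `report` subcommands.

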