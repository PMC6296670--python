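# welchslopes

Power analysis and sample-size determination for the **extended Welch test**
of equality of two regression slopes when the error variances differ
between groups.

## The problem

In many biomedical studies the question is whether a treatment changes the
*relationship* between a continuous predictor and a response — a
treatment-by-covariate interaction. With two groups each following a simple
linear regression

    Y_ij = β0_i + β1_i X_ij + ε_ij,    ε_ij ~ N(0, σ_i²),   i = 1, 2,

the interaction is the slope difference β1D = β11 − β12, and the test of
H0: β1D = 0 with **unequal** σ1² ≠ σ2² is a Behrens–Fisher problem for
slopes. The classical pooled-variance slope comparison loses type-I error
control badly when unequal variances pair with unequal group sizes; the
extended Welch statistic

    T* = (β̂11 − β̂12) / √(σ̂1²/SSX1 + σ̂2²/SSX2),

referred to a t distribution with Satterthwaite degrees of freedom

    1/ν̂ = w1²/c1 + w2²/c2,   w_i = (σ̂_i²/SSX_i)/(σ̂1²/SSX1 + σ̂2²/SSX2),
    c_i = n_i − 2,

is robust to this heteroscedasticity.

For **design planning** the predictor values are not yet observed, so power
must be unconditional: with normal predictors X_ij ~ N(θ_i, τ_i²), the sum
of squares SSX_i/τ_i² is chi-square with n_i − 1 df. The package implements
two analytic power functions:

* **Simplified t (ST)** — replaces each SSX_i by its expectation
  (n_i − 1)τ_i², giving one noncentral-t evaluation with noncentrality
  Δ* = β1D / √(σ1²/((n1−1)τ1²) + σ2²/((n2−1)τ2²)) and the working effect
  size δ* = Δ*/(n1+n2).
* **Mixed t (MT)** — keeps the chi-square law of both predictor sums of
  squares and averages the conditional noncentral-t rejection probability
  over them by deterministic Gauss–Legendre quadrature. MT tracks simulated
  power closely everywhere; ST can overstate power by more than 0.10 for
  large effects with unbalanced allocation.

A minimal-sample-size solver (smallest n1 with n2 = ⌈r·n1⌉ reaching a
nominal power), a vectorized Monte Carlo engine for empirical power and
type-I error, and a design-table generator round out the toolkit.

Intended users: biostatisticians and quantitative researchers planning
two-group interaction (moderated regression) studies.

## Worked example

The bundled `bishop_mice` fixture holds the published summary statistics of
a classic organ-weight study: body weight predicting kidney weight in
crossbred diabetic (n=9) and normal (n=25) mice, with slope estimates
{15.9286, 3.8398}, error variances {10124.8980, 9097.9625} and predictor
variances {31.1111, 23.8600}.

```bash
$ welchslopes test --fixture bishop_mice
Extended Welch test of equal slopes
  slope difference  12.0888
  T*                1.6073
  df (Satterthwaite)   12.9349
  p-value           0.1321
  reject H0 at alpha=0.05: no
Pooled-variance comparison
  T                 1.6478
  df                30
  p-value           0.1098
```

The slope difference (12.09 g kidney weight per g body weight) is not
significant at α = 0.05 under either test, but the Welch df (12.93) is far
below the pooled 30 because group 1 is small and its variance estimate
dominates. Was the study big enough to detect such a difference?

```bash
$ welchslopes power --fixture bishop_mice --n1 9 --n2 25 --method MT
Mixed-t power at n=(9,25), alpha=0.05
  power       0.3013
  ncp Delta*  1.6073
  delta*      0.0473
  plug-in df  12.9349
```

Power 0.30 — badly underpowered. The sizes needed for a balanced design:

```bash
$ welchslopes samplesize --fixture bishop_mice --power 0.80 --rn21 1
Minimal sample sizes (MT method), nominal power 0.8, ratio r=1
  N1              42
  N2              42
  N total         84
  achieved power  0.8025
```

With allocation ratio r = 3 (normal mice cheaper than diabetic ones),
`--rn21 3` gives {28, 84}, total 112. A Monte Carlo check of any design is
one command, e.g.
`welchslopes simulate --fixture bishop_mice --n1 42 --n2 42 --reps 10000 --seed 1`.

The same operations are available as library functions
(`welch_test`, `power_mixed`, `solve_sample_size`,
`simulate_rejection_rate`, `reproduce_table`), and plan parameters can be
given in a YAML/JSON config file using the keys `alpha, power, n1, n2,
beta11, beta12, sigsq1, sigsq2, tausq1, tausq2, rn21`.

## Limitations

Two groups only; two-sided tests only; normal predictors and errors are
assumed both by the power theory and the simulator. See `docs/methods.md`
for the model details, numerical choices and their rationale.
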