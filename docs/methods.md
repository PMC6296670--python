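# Methods

## Model and test

Each group i = 1, 2 follows a simple linear regression
Y_ij = β0_i + β1_i X_ij + ε_ij with ε_ij ~ N(0, σ_i²) iid, and the two
error variances are allowed to differ. The hypothesis of interest is
H0: β1D = β11 − β12 = 0 against a two-sided alternative — equivalently, no
interaction between the dichotomous group indicator and the continuous
predictor in the combined moderated-regression model.

The least-squares slope of group i satisfies
β̂1i ~ N(β1i, σ_i²/SSX_i) conditional on the predictors, with
SSX_i = Σ(x_ij − x̄_i)², and σ̂_i² = SSE_i/c_i, c_i = n_i − 2, is the
unbiased error-variance estimate with c_i σ̂_i²/σ_i² ~ χ²(c_i). The
extended Welch statistic standardizes the slope difference by the
per-group variance terms a_i = σ̂_i²/SSX_i,

    T* = (β̂11 − β̂12) / √(a1 + a2),

and is referred to t(ν̂) where 1/ν̂ = w1²/c1 + w2²/c2 with
w_i = a_i/(a1+a2) (a Satterthwaite moment match of the weighted chi-square
sum in the denominator). ν̂ always lies in [min(c1, c2), c1 + c2]. H0 is
rejected when |T*| strictly exceeds the upper-α/2 quantile of t(ν̂); the
boundary case counts as non-rejection, so `reject`, `p < α` and
`|T*| > crit` are always consistent.

The pooled-variance comparison (Sp² = (SSE1+SSE2)/(n1+n2−4), fixed df
n1+n2−4) is included as the classical reference. It is exact under
homogeneity but its type-I error degrades when variances and sample sizes
are unequal — most severely under *inverse pairing* (larger variance in
the smaller group), where the simulator shows rejection rates near 0.15 at
nominal 0.05.

All test functions consume `GroupSummary` sufficient statistics
(n, slope, intercept, SSX, SSE, σ̂², x̄), so published summary tables can
be analyzed without raw data; `summarize_group` reduces raw vectors to the
same form. `GroupSummary.from_moments` accepts either SSX directly or a
predictor sample variance τ̂², converted as SSX = (n−1)τ̂² — the
convention used by the bundled mice fixture, whose source defines
τ̂_i² = SSX_i/(n_i − 1).

## Unconditional power

At the planning stage the predictors are random: X_ij ~ N(θ_i, τ_i²), so
K_i = SSX_i/τ_i² ~ χ²(n_i − 1) independently across groups. Intercepts
and predictor means never enter any power formula (slope inference is
invariant to location shifts); they are accepted in `PlanningConfig` only
so that planning values can be transcribed completely.

**Simplified t (ST).** Replacing SSX_i by its expectation (n_i − 1)τ_i²
gives plan-level variance terms ā_i = σ_i²/((n_i−1)τ_i²), noncentrality
Δ* = β1D/√(ā1 + ā2), plug-in degrees of freedom ν* from the Satterthwaite
formula evaluated at ā_i, and power

    Ψ_ST = P(|T'| > t_{ν*, α/2}),   T' ~ noncentral t(ν*, Δ*).

The working effect size δ* = Δ*/(n1+n2) is the dimensionless summary used
to rank configurations in the design tables.

**Mixed t (MT).** Conditional on K = (K1, K2) the variance terms are
a_i(K) = σ_i²/(τ_i² K_i); the conditional rejection probability is the
same noncentral-t expression with Δ(K) = β1D/√(a1(K)+a2(K)) and ν(K) from
the Satterthwaite formula, and

    Ψ_MT = E_K [ P(|T'(K)| > t_{ν(K), α/2}) ].

The mixture is taken over (K1, K2) only; the variance estimators enter
through the noncentral-t form itself. Both functions reduce exactly to α
at β1D = 0, because the critical value is the central-t quantile of the
same df that the (then central) statistic follows.

ST is one cheap evaluation but treats a skewed random denominator as
fixed; MT integrates over it. The two agree as n grows, while in small
samples with large effects and unbalanced allocation ST overstates power —
by ≈0.11 at the benchmark configuration β1D = 1, τ² = (4,1), σ² = (1,1),
n = (6,18) — which translates into undersized studies. MT stays within
Monte Carlo noise of simulated power across all tabulated conditions.

## Numerical choices

* **Quadrature.** Ψ_MT uses a tensor-product Gauss–Legendre rule with 48
  nodes per dimension on the probability scale u ∈ (ε, 1−ε), ε = 1e−7,
  mapped through the χ² quantile function; weights are renormalized to sum
  to one. The integrand (a smooth conditional power) makes the rule
  converge fast; by default the result is recomputed at 96 nodes and the
  refinement is kept, with a warning (or an error in strict mode) if the
  two differ by more than 5e−5. `power_mixed_mc` provides an independent
  Monte Carlo evaluation of the same expectation for cross-checks.
* **Noncentral-t tails.** Two-sided probabilities are
  sf(crit) + cdf(−crit) from scipy's noncentral t. At very large df scipy
  can return NaN for a far tail whose true mass is negligible; those
  entries fall back to the large-df normal limit T' → N(Δ, 1).
* **Central-t machinery** (quantiles, p-values) uses scipy throughout; no
  hand-rolled distribution functions are on production paths (a quadrature
  oracle for the p-value lives only in the tests).

## Sample-size search

`solve_sample_size` returns the smallest n1 ≥ 4 (n2 = ⌈r·n1⌉, exact
rational arithmetic for the ceiling) whose design attains the target power
with the requested method. The search seeds n1 from the normal
approximation Δ* = z_{α/2} + z_β, then walks down to the first failure or
up to the first success; power is monotone in n1 at fixed ratio, so this
matches an exhaustive scan from the floor (monotonicity is asserted along
the recorded trace and violations are warned about). Evaluations are
cached per n1; a configurable ceiling (default 1e5) guards against
unattainable requests, and β1D = 0 is rejected immediately since power
then equals α for every n. The minimum planning size of 4 per group keeps
c_i ≥ 2 and at least 3 df in each chi-square mixing variable. Non-integer
r·n1 is rounded up (conservative); tabulated designs only use r ∈ {1, 3}.

The ceiling convention for n2, and reporting δ* at the simplified-method
sizes when regenerating tables, are deliberate conventions chosen to match
the published table layout.

## Monte Carlo engine

`simulate_rejection_rate` draws all replicates at once: predictor matrices
X_i ~ N(θ_i, τ_i²) of shape (reps, n_i), responses from the group
regressions, row-wise least squares via centered cross-products, then the
chosen test at level α. Degenerate predictor draws (SSX numerically zero;
probability zero for continuous normals, guarded against anyway) are
redrawn and counted in `n_redraws`. Results are bit-for-bit reproducible
from the scenario seed; table regeneration spawns independent child
streams per cell from a single `SeedSequence`, so cells are reproducible
individually and under parallel execution. The default 10,000 replicates
give a binomial standard error of about 0.004 near power 0.8 and 0.002 at
the null; `reproduce_table(..., reps=500)` supports desk-scale smoke runs.

The generator emulates exactly the sampling model the power theory
assumes — normal predictors, normal errors, independence. It therefore
validates the *computation* of Ψ_ST/Ψ_MT and the df approximation, not
robustness: agreement here says nothing about skewed predictors,
heavy-tailed errors, or dependence in real data.

## What the simulator's defaults represent

Slope differences {0.50, 0.75, 1.00} with β12 = 0, allocation ratios
{1, 3}, predictor-variance patterns {(1,1), (1,4), (4,1)} and
error-variance patterns {(1,1), (1,2), (1,4), (2,1), (4,1)} — the 90
conditions of the reference design tables, covering balanced and
unbalanced designs with direct and inverse variance pairing — are encoded
in `VARIANCE_CASES`/`TableSpec`, with α = 0.05 and nominal power 0.80.
The full 90-condition regeneration at 10,000 replicates is supported
(`welchslopes tables`) but the test suite exercises representative rows at
reduced replicates; problem sizes in the tests were chosen so the whole
suite runs in well under a minute.

## Known limitations

* Two groups only; no joint coincidence or intercept tests, no >2-group
  extension, no one-sided variants.
* Power theory and simulator both assume normality of predictors and
  errors; no non-normal options.
* No cost-optimal allocation: the ratio r is fixed by the user.
* The mixed-t quadrature is accurate to roughly 1e−5 at the default grid;
  results are quoted to 4 decimal places.
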