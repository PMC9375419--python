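# Methods

`smallcrt` implements and evaluates analysis methods for two-arm
cluster-randomised trials (CRTs) with a binary outcome and a small number
of clusters (8–30). This note documents the statistical models, the
numerical choices behind them, the synthetic-data generator, and the
limits of what the test suite demonstrates.

## Data model and sufficiency

A trial is a set of clusters `(arm, events, size)`. Every supported
analysis uses only the cluster-constant arm indicator as a covariate, so
the cluster totals are sufficient statistics: individual-level and
aggregated encodings of the same trial give identical results to machine
precision, and all internal computation is cluster-collapsed. This is
what makes the Monte-Carlo study cheap even with clusters of 1000
individuals.

## Cluster-level analysis

Each cluster is summarised by its continuity-corrected log odds
`s_c = log[(y_c + 0.5) / (m_c − y_c + 0.5)]`; the correction (half an
event and half a non-event per cluster) keeps the summary finite when a
cluster has zero or all events, at the price of shrinking extreme
summaries toward zero — the mechanism behind the attenuation of the
estimate with small clusters and rare outcomes.

* **CL-UNW** — equal-variance two-sample t-test on the `s_c`, df = n − 2.
* **CL-W** — Kerry–Bland inverse-variance weights
  `w_c = m_c / (1 + (m_c − 1)ρ)`. The ICC `ρ` is estimated by the method
  of moments under the null: the pooled within-arm variance of `s_c`
  estimates the total `σ_b² + E[1/(p(1−p)m)]` (Taylor approximation);
  the within-cluster term is estimated by the mean of
  `1/(m·p̃(1−p̃))` with `p̃` the corrected cluster proportion; the excess
  (truncated at zero) is converted to a proportion-scale ICC at the
  pooled corrected prevalence. The weighted t machinery treats the
  estimated weights as known: the pooled weighted variance uses divisor
  n − 2 (unbiased for the per-unit-weight variance when
  `Var(s_c) = C/w_c`), and `SE² = sp²(1/Σw₀ + 1/Σw₁)`. With constant
  weights this reduces exactly to the unweighted test. The residual
  understatement of uncertainty comes from ignoring the sampling noise of
  `ρ̂`, which is what makes CL-W anti-conservative in some designs.

Non-convergence is declared only when the summaries are constant within
both arms (zero pooled variance).

## Random-intercept logistic GLMM

`logit Pr(y = 1 | u_c) = β₀ + β₁·arm + u_c`, `u_c ~ N(0, σ_b²)`; `β₁` is
a cluster-specific (conditional) log odds ratio.

**REPL (restricted pseudo-likelihood).** The model is linearised at the
current predictions (subject-specific expansion): the cluster-mean
pseudo-response is `z̄_c = η_c + (y_c/m_c − μ_c)/w_c` with working weight
`w_c = μ_c(1−μ_c)` per individual, and the implied linear mixed model
(residual variance `φ/w_c`, random intercept variance `σ_b²`) is fitted
by REML; the fit updates the predictions through the BLUPs and the
process repeats. Because weights are constant within a cluster, the REML
criterion depends on the data only through `z̄_c`, `W_c = m_c w_c` and
the pooled within-cluster sum of squares, giving the profiled 1-D
criterion documented in `smallcrt/_repl.py`. The variance ratio
`γ = σ_b²/φ` is found by a log-spaced grid scan (including the γ = 0
boundary) refined by golden-section search; `φ` and the fixed effects are
profiled in closed form. The residual scale `φ` is estimated, not fixed:
its REML estimate below 1 with small binomial denominators is what
inflates REPL standard errors (and produces the conservative small-
cluster type-one error the evaluation reproduces).

Controls: at most 100 linearisation iterations, joint relative-change
tolerance 1e−8 on `(β₀, β₁, σ_b²)`, variance floor 1e−12. Failure to
meet the tolerance flags the fit non-converged (still returned). The
same compiled kernel serves the single-fit API and the batch engine.

**Degrees of freedom.**

* `DF_CP = n − 2` (clusters minus cluster-level parameters).
* `DF_S` (Satterthwaite): `2·Var(β̂₁)²/Var[Var(β̂₁)]`, with the outer
  variance from the delta method over `(φ, σ_b²)` and the REML
  information obtained by central finite differences of the criterion on
  the converged pseudo-data (one-sided at the σ_b² = 0 boundary); the
  df is clamped to [1, 1e7] in degenerate cases. In a balanced design
  this recovers ≈ n − 2, the df of the between-cluster mean square.
* `DF_KR` (Kenward–Roger): the adjusted covariance is computed on the
  cluster-mean collapsed model (diagonal covariance `φ/W_c + σ_b²`,
  linear in the variance parameters, so the second-derivative term
  vanishes and the fixed-effect contractions equal the individual-level
  ones); the df equals `DF_S` for this one-random-effect model, the
  correction acting through the (weakly) inflated SE.

Both small-sample rules require the REPL pseudo-model and are rejected
for AQ fits.

**AQ (adaptive Gauss–Hermite quadrature).** The exact marginal
likelihood is integrated per cluster with nodes centred at the cluster's
conditional mode and scaled by its curvature (Newton inner loop;
log-sum-exp accumulation; Q = 11 nodes by default, 1 node = Laplace).
Optimisation is L-BFGS-B over `(β₀, β₁, log σ_b²)` with the variance
floored at 1e−12; a boundary solution is reported as σ̂_b² = 0, not an
error. The fixed-effect covariance is the corresponding block of the
inverse observed information (numerical Hessian), falling back to the
β-only Hessian at the boundary.

## GEE with sandwich corrections

The marginal model `logit E[y|X] = Xβ` is solved by Fisher scoring on the
cluster-collapsed estimating equations; the exchangeable working
correlation α is re-estimated each iteration by the moment estimator on
standardised Pearson residuals (divisor `Σm(m−1) − p`), truncated into
its validity range. With independence working correlation and an
arm-only covariate the equations coincide with pooled logistic
regression, so `β̂₁` is the pooled-counts log odds ratio in closed form.
Separation (an arm with zero or all events) is flagged non-converged.

Because the working covariance is compound-symmetric and the covariate
cluster-constant, every per-cluster matrix in the uncorrected (robust),
Kauermann–Carroll (KC) and Fay–Graubard (FG, bound 0.75) estimators
collapses to a scalar: the KC cluster adjustment becomes
`(1 − ℓ_c)^{−1/2}` with leverage `ℓ_c = W_c u_c x'V_M x`, and the FG
adjustment is a 2×2 diagonal in parameter space. The FG multiplier uses
the exponent −1/2 of the published correction. The collapsed algebra is
pinned to explicit m×m matrix assembly in the tests, which is what
licenses running mean-size-1000 scenarios at desk scale. The dispersion
parameter is fixed at 1; it cancels identically in all sandwich
estimators and leverages. Inference is `t(n − 2)` throughout.

When a KC leverage reaches 1 the inverse square root is undefined; the
fit raises (single-dataset API) or is flagged non-converged for the KC
method (engine). This happens by construction whenever an arm has a
single cluster.

## Synthetic-data generator

Cluster totals are drawn as
`Y_c ~ Binomial(expit(β₀ + β₁·arm + u_c), m_c)` with
`β₀ = logit(control prevalence)` — a conditional (median-cluster)
prevalence; the marginal prevalence is slightly different when σ_b² > 0
and is not targeted.

* **ICC.** Defined on the log-odds scale:
  `ρ = σ_b²/(σ_b² + π²/3)`, so `σ_b² = ρ(π²/3)/(1−ρ)`. Grid:
  0.001, 0.01, 0.05, 0.1.
* **Cluster sizes.** Common (CV = 0) or `m = 2 + δ` with δ negative
  binomial parameterised by `r = (m̄−2)²/(s²−(m̄−2))` successes and
  success probability `(m̄−2)/s²` (`s = CV·m̄`), which gives exactly
  `E[m] = m̄` and `Var[m] = s²`; minimum size 2. Grids: m̄ ∈ {10, 50,
  1000}, CV ∈ {0, 0.5, 0.8}. The parameterisation requires
  `s² > m̄ − 2` (all grid cells satisfy it).
* **Cluster effects.** Normal; gamma `σ_b(a−2)/√2`, `a ~ Gamma(2,1)`
  (skewness √2); or uniform on `±√(3σ_b²)` (negative excess kurtosis) —
  all with mean 0 and variance σ_b².
* **Effect sizes.** For powered cells the conditional odds ratio is
  solved by bisection so that a two-proportion normal-approximation
  power calculation (pooled-variance alpha term, unpooled beta term)
  gives 80% power at two-sided α = 0.05 with effective sample size per
  arm `(n/2)·m̄ / DE`. The design effect is `DE = [1+(m̄−1)ρ]/RE` with
  the log-odds-scale ρ used directly and
  `RE = 1 − CV²·λ(1−λ)`, `λ = m̄ρ/(1+(m̄−1)ρ)` (the van
  Breukelen–Candel–Berger relative efficiency for unequal cluster
  sizes). Using ρ on its defined scale, rather than converting to a
  proportion-scale ICC, reproduces the published span of solved odds
  ratios (≈1.1–11.5) far better than the conversion; the residual
  discrepancy at the low end (our minimum ≈1.10) reflects unpublished
  internals of the original power routine. Solved effect sizes should
  therefore be read as calibrated approximations, and quantities that
  depend on them (attenuation, power differences) carry that extra
  uncertainty.

The full factorial grid is 4 cluster counts × 3 mean sizes × 3 CVs × 2
prevalences × 4 ICCs × 3 effect distributions = 864 cells, each in a
null and a powered version (1728 scenarios).

**What the generator does not emulate:** covariates and stratified
randomisation, informative cluster size, overdispersion beyond the
random intercept, cohort/longitudinal structure, and missing data. A
method passing the grid shows calibration under a correctly specified
(if non-normal) random-intercept world, not robustness to those
features.

## Monte-Carlo engine and performance measures

Per scenario, all requested methods analyse the *same* generated
datasets (paired comparison), with per-scenario generator streams
derived from one master seed via `SeedSequence`, so a full run is
bitwise reproducible for any worker count. Per scenario × method, over
converged repetitions only:

* standardised bias: `100·(mean(β̂₁) − truth)/SD(β̂₁)` (SD with ddof 1);
* relative SE bias: `100·(ModSE/SD − 1)` with ModSE the root-mean-square
  of the model SEs (the mean of SEs would be biased low precisely where
  SEs are noisiest, at 8 clusters);
* type-one error / power: share of repetitions with p < 0.05 (strict);
* coverage: share of 95% CIs containing the truth.

The truth is the conditional log OR for cluster-level and GLMM methods
and the converted marginal log OR
`β_m = β_c·[(16√3/15π)²σ_b² + 1]^{−1/2}` for GEE. A null-scenario
rejection rate below 3.6% is *conservative* and above 6.4% *inflated* —
the 95% Monte-Carlo band of a true 5% rate at 1000 repetitions.

### Problem sizes

The reproduction workflow (`scripts/acceptance.py` and the heavier
tests) runs the full 864-cell null grid and the relevant powered
subgrids at 1000 repetitions per scenario; the compiled
REPL kernel fits roughly 3000 models per second, so the whole
reproduction completes in a few minutes on one CPU.

### Known reproduction limits

* The FG (independence) conservative-scenario share computes to ≈18–19%
  on this engine. Published summaries of this comparison quote figures
  from 17% up to 25% depending on the section and scenario denominator;
  the engine reproduces the 17% figure and cannot reconcile the larger
  one.
* Convergence *percentages* depend on software-specific iteration
  criteria and are not comparable across implementations; this package
  documents its own criteria (above) and reports its own rates.
* CL-W numerical results depend on the exact ICC estimator used for the
  weights, for which no standard choice exists; the moment estimator
  above is this package's documented choice.
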