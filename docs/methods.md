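# Methods

## Model and difference distributions

Measurements follow the two-device replicated mixed model

    y_ijl = x'_ijl δ + β_j + α_i + γ_ij + e_ijl,   i=1..n, j=1,2, l=1..m,

with independent normal random effects: subjects α_i ~ N(0, σ²_α),
subject×device interaction γ_ij ~ N(0, σ²_γ), errors e_ijl ~ N(0, σ²_e)
(optionally device-specific σ²_e1, σ²_e2).  All agreement quantities are
functions of the paired-difference distributions this model implies:

| kind  | difference                | mean        | variance                      |
|-------|---------------------------|-------------|-------------------------------|
| total | y_ijl − y_ij'l'           | μ_D = β₂−β₁ | 2σ²_γ + 2σ²_e                 |
| intra | y_ijl − y_ijl'            | 0           | 2σ²_e (per device if unequal) |
| inter | ȳ_ij· − ȳ_ij'·            | μ_D         | 2σ²_γ + 2σ²_e/m               |

Assumptions: normality of all components, exactly two devices, replicates
exchangeable within a cell, and (for the closed-form path) a balanced
design.  Between-subject variation σ²_α cancels from every difference, which
is why TDI-based agreement is insensitive to subject-level covariates — they
move σ²_α, not σ²_e or β.

## Estimation

For balanced covariate-free data, `fit_balanced_vc` uses the closed-form
strata estimators (subject stratum, subject×device contrast stratum,
within-cell stratum).  These coincide with REML when no component truncates;
negative closed-form solutions are truncated at zero and flagged
(`truncated`), the standard REML-consistent behaviour.  Without an
interaction term the contrast stratum is pooled into the error.  The same
strata with maximum-likelihood divisors (n instead of n−1) give the
closed-form MLE used by the Choudhary comparator; both are cross-checked
against `statsmodels MixedLM` in the tests.  `fit_reml_general` delegates to
MixedLM for covariates and unbalanced data, with a BFGS-first optimizer
cascade that recovers the balanced closed form to ~1e-10 relative.

## TDI as a probability interval; the p₁ search

κ_p is the half-width of the interval symmetric about zero containing mass p
of N(μ_D, σ²_D): κ_p = |μ_D| + σ_D z_{p₁} where p₁ solves
Φ(z_{p₁}) − Φ(−2|μ_D|/σ_D − z_{p₁}) = p.  The solution is unique in
[p, (1+p)/2]; at μ_D = 0 it is exactly (1+p)/2 (short-circuited), and it
*decreases* toward p as the bias grows.  `solve_p1` brackets [p, 1] and
bisects, moving the active endpoint past the midpoint by the tolerance δ
each step, so the bracket shrinks strictly and convergence is logarithmic;
the defining equation is satisfied to |·| < δ at the returned point.
Defaults: δ = 1e-10 for one-off analyses (`SearchSettings`), 1e-4 inside the
Monte-Carlo harness, iteration cap ceil(log2(1/δ)) + 5.  The sign of μ_D is
irrelevant everywhere (|μ_D| is used); the reported sign convention is
"second device minus first" in the declared device order.

The non-central-χ² route κ_p = σ_D √(χ²⁻¹(p; 1, (μ_D/σ_D)²)) is implemented
independently (`tdi_ncx2_exact`) and agrees with the search to 1e-8
relative; the MSD approximation z_{(1+p)/2}√(μ²_D+σ²_D) is provided for
diagnostics and for the Lin comparator.

## Tolerance-interval bound: N and ν conventions

The studentized interval limit follows a non-central t with non-centrality
√N z_{p₁}, giving UB = |μ̂_D| + σ̂_D t'_{1−α;ν;√N z_{p₁}}/√N.  Here
N = 2nm (the count of paired-measurement differences) for every agreement
kind.  An alternative N = 2n for the inter-method bound (which averages the
m replicates first) was considered and rejected: the inter-method difference
rests on the same 2nm underlying readings, and N = 2nm also reproduces the
reference concordance tables this implementation was validated against.

Residual df conventions (`TIPolicy.df_convention`), selectable and always
reported in results:

* `interaction`: ν = 2n(m−1) — all fixed and random effects consume df
  (conservative ANOVA position);
* `no_interaction`: ν = 2nm − (n+m−1) — default when the fitted model has no
  interaction term;
* `fixed_only`: ν = 2nm − 2 — random effects consume no df;
* `satterthwaite`: Welch combination of the two device-specific error-df
  (automatic for unequal error variances).

At the case-study size the three balanced conventions move the 0.90 bound
only within ≈17.91–17.99, which is why the convention is a reported flag
rather than a hidden constant.  Non-central-t quantiles use the library
routine, switching to the closed-form tolerance-factor normal approximation
for non-centralities above 5000 (or on numerical failure); the two agree to
<1% at the switch point.

Hypothesis test: H₀: κ_p ≥ κ₀ is rejected at level α iff UB < κ₀; rejection
is the agreement claim (interchangeability to within κ₀).

## Coverage probability

cp_estimate is two normal CDF evaluations; the lower confidence bound
searches the proportion p ∈ (0,1) whose tolerance bound equals the fixed
boundary κ, bisecting on the discrepancy between the observed studentized
boundary √N(κ−|μ̂_D|)/σ̂_D and t'_{1−α;ν;√N z_{p₁(p)}}.  The printed
description of this search resets the passive bracket endpoint each step; a
literal reset forfeits the logarithmic convergence, so the retained-bracket
form is used (the fixed point is identical).  The bound is dual to the TI
bound — cp_lower_bound at κ = UB_p returns p to within twice the search
tolerance — and the CP and TDI tests reach identical decisions at matched
(κ₀ = κ, p₀ = p).

## Comparators

* **Lin (log-MSD)**: κ̂ = z_{(1+p)/2}√(μ̂²_D + σ̂²_D) at moment estimates
  (the working-independence GEE solution for balanced data), upper bound
  exp(log κ̂ + z_{1−α}·se), with se from the delta method.
* **Choudhary (MLE plug-in)**: the exact non-central-χ² κ̂ at closed-form
  balanced MLE estimates, same log-scale construction.

Both delta-method variances use numerically differentiated gradients of
log κ̂ over (μ̂_D, contrast mean square, within mean square) against the
balanced-stratum covariance diag(2λ_C/(nm), 2λ²_C/df_C, 2λ²_W/df_W).  The
original publications' closed-form gradients and exact GEE weighting are not
reproduced; the bounds are therefore structurally faithful but approximate,
and are flagged `GEE-moment` / `MLE` in results.  The Choudhary *point*
estimate is exactly the probability-interval estimate at the MLE parameters.

## Synthetic data and the simulation harness

`generate_dataset` draws each subject's 2m-vector from the multivariate
normal MVN(X(δ,β), σ²_α J + σ²_e I) — no interaction component, matching the
evaluation design.  Defaults emulate the blood-pressure study conditions:
intercept 133.369 mmHg, σ²_α = 380.187, m = 2, device effects
{0, 2.174, 5}, error variances {16, 52.867}, n ∈ {20, 100}, 1000 replicates
per scenario, nominal 95% one-sided bounds, search tolerance 1e-4.  What the
generator does **not** emulate: non-normal or heteroscedastic errors,
digit-preference/rounding of manual readings, unbalanced designs, covariate
effects, or subject×device interaction — so passing Monte-Carlo checks
demonstrate correctness under the model, not robustness to its violations.

Per replicate the harness refits the no-interaction model by the closed-form
REML path (and the moment/ML paths for the comparators) and records log κ̂
and log UB per method and proportion.  Summaries per (scenario, p, method):
mean and MSE (×1000) of log κ̂ against the analytic truth
log σ_D√(χ²⁻¹(p;1,(μ_D/σ_D)²)) with σ_D = √(2σ²_e) exact (not the rounded
5.65/10.28 labels), and empirical confidence EC = % of replicates with
log κ_p ≤ log UB (≤ at the boundary; a measure-zero choice).  Replicate
failures are dropped and counted; >1% aborts the summary.  One master seed
keys an independent, reproducible stream per scenario cell, so any cell can
be rerun alone.

Problem sizes in the shipped tests and the acceptance script: 1000
replicates for the headline EC/mean checks (binomial SE ≈ 0.4–0.6 points),
200–500 for qualitative property checks; each 1000-replicate scenario runs
in well under a minute on one CPU.

## Numerical choices and edge cases

* Negative variance solutions truncate to 0 with a `truncated` flag.
* σ_D = 0 (constant data) raises `DegenerateDistributionError` rather than
  returning a zero-width interval.
* Data validation accepts a single subject (minimal well-formed input);
  fitting requires n ≥ 2.  Missing values are rejected, never imputed;
  unbalanced data are accepted but flagged, and routed to the general REML
  fit only.
* CSVs are written with `%.17g` and read with round-trip float parsing, so
  write→read is bit-exact.
* Results always carry their convention flags (df convention, inter-method
  mode, N, ν, confidence, iteration counts, seeds) for reproducibility.

## Inter-method mode

`tdi_inter` defaults to the mathematically consistent `strict` mode (p₁
solved from the inter-method ratio μ_D/σ_inter).  A `paper_compat` mode
solves p₁ from the *total*-difference ratio and then scales by σ_inter —
an alternative reading of the published inter-method formula that reproduces
the reference concordance tables (strict gives e.g. 12.48 vs the tabulated
12.9 at p = 0.90).  Both are labelled in output; choose `paper_compat` only
for comparability with that literature.

## Known limitations

* Exactly two devices; no crossed multi-rater designs.
* Heteroscedasticity only as device-specific error variances.
* The Lin comparator's GEE covariance is moment-based; its published table
  values are not exactly recoverable, so it should be read qualitatively.
* Tolerance-bound inference assumes the normal mixed model; no
  nonparametric or quantile-based TDI estimator is provided.
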