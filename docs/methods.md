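# Methods

## Generating model

Each replicate is a two-arm trial with fixed 1:1 allocation: exactly
`n_per_arm` patients receive treatment (T = 1) and `n_per_arm` control
(T = 0). Allocation is deterministic, not Bernoulli randomization —
the design fixes arm sizes, as trial simulations conventionally do.

The baseline covariate C is i.i.d. from one of two families calibrated
to the same variance so results are comparable across families:

* continuous: uniform on the closed interval [−0.75, +0.75]
  (mean 0, variance 1.5²/12 = 0.1875). Endpoint inclusion is
  measure-zero and immaterial.
* binary: Bernoulli(0.25) (mean 0.25, variance 0.25·0.75 = 0.1875).

One covariate SD is therefore √0.1875 = 0.4330 in both families.

The outcome is Bernoulli with

    Pr(Y = 1 | T, C) = expit(β₁T + β₂C)

There is deliberately **no intercept** in the generating model: a
control patient at C = 0 has outcome probability exactly 0.5. This
keeps event rates near 50% everywhere in the design, which is why
separation is essentially never observed. All three *fitted* models do
include an intercept.

Default factor levels: β₁ ∈ {0, 0.5, 1.0}, β₂ ∈ {0, −0.5, −1.0}, both
covariate families, n_per_arm ∈ {50, 100, 200, 500, 1000} — 90
conditions; 50,000 replicates per condition at full scale.

## Estimators and inference

* unadjusted: ML logistic fit of Y on (1, T). With a single binary
  regressor this equals the 2×2-table log odds ratio, which the tests
  exploit as a closed-form oracle.
* sample-adjusted: ML fit of Y on (1, T, C).
* true-adjusted: ML fit of Y on (1, T) with β₂C as an offset (a
  linear-predictor term with coefficient fixed at 1). With β₂ = 0 the
  offset vanishes and this estimator is *identical* to the unadjusted
  one, replicate by replicate — a structural identity the suite asserts
  to 1e-8.

Inference on the treatment coefficient is a two-sided Wald z-test
(coefficient over model-based standard error from the observed
information, normal reference), the default inference of standard
logistic-regression software. Significance is strict: p < α, α = 0.05
by default and configurable. Likelihood-ratio or score tests would
differ only within Monte-Carlo noise at these sample sizes but are not
implemented.

### Fitting algorithm

The fitter is Newton–Raphson (equivalently IRLS) on the exact Bernoulli
log-likelihood, vectorized across replicates: design columns shared by
all replicates (intercept, treatment) are broadcast against
replicate-specific ones (the covariate), and the p×p Hessians
(p ≤ 3) are assembled and solved batched. This is what makes a
50,000-replicate condition take seconds rather than hours, and it is
cross-checked in the tests against statsmodels GLM (coefficients,
standard errors, p-values) and against direct Nelder–Mead maximization
of the likelihood on tiny samples.

Convergence: max |score| < 1e-8, or relative log-likelihood change
< 1e-10, within 50 iterations. A replicate whose coefficients exceed
15 in absolute value, whose Hessian becomes numerically singular, or
which exhausts the iteration cap is flagged non-converged — the
standard heuristic for complete/quasi-separation, where the MLE is
infinite (e.g. an arm with zero events). Non-converged fits are
excluded from that estimator's summaries and counted in the run
manifest; with baseline risk 0.5 they are vanishingly rare (one fit in
a 180,000-replicate grid run at desk scale).

## Randomness and reproducibility

Every replicate draws from its own `numpy` child stream seeded by
`SeedSequence((master_seed, n_per_arm, enc(β₁), enc(β₂), kind,
replicate_index))`, where `enc` maps a float to a non-negative integer.
Seeding is keyed on the condition's *coordinates*, not its position in
any loop, so results are invariant to condition order, chunk size, and
`joblib` worker count — all asserted by tests. Any single replicate can
be regenerated in isolation (`generate_replicate`). The default master
seed, 20230213, was fixed a priori.

## Summaries

Per condition and estimator, over converged replicates only:

* bias = mean(b₁) − β₁; MC se = √(var/n).
* variance = sample variance of b₁ (divisor n − 1) across replicates —
  the empirical, not the mean model-based, variance; MC se by the
  normal approximation var·√(2/(n−1)).
* accuracy = proportion of b₁ in the closed interval β₁ ± 0.1
  (halfwidth configurable); on the odds-ratio scale the window is
  exp(β₁ ∓ 0.1), e.g. (1.49, 1.82) at β₁ = 0.5 and (2.46, 3.00) at
  β₁ = 1. Binomial MC se.
* rejection rate = proportion with p < α; type-1 error when β₁ = 0,
  power otherwise. Binomial MC se.

Report tables round bias and rejection rates to 3 decimals, variance
and accuracy to 2, matching conventional table precision; the
unrounded summary CSV keeps full precision and the MC standard errors.

Diagnostics (per condition): the 3×3 Pearson correlation matrix among
the per-replicate b₁ estimates; corr(b₁′, b₂′); corr(b₁′, d), where
Cohen's d = (mean C treated − mean C control)/pooled SD with
Bessel-corrected arm variances; and the observed range of d.
Correlations use replicates where all three models converged. Lowess
smoothing and figure rendering are out of scope — the replicate-level
tuples are exported for any plotting layer.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: variance-matched
covariate families, no intercept (≈50% event rate), a single covariate,
1:1 fixed allocation. It does **not** emulate features of real trials —
other baseline risks, multiple or correlated covariates, unequal or
blocked allocation, missing data, or treatment-effect heterogeneity —
so passing tests show correctness of the simulation and estimators
under these idealized conditions, not performance of adjustment
strategies in any particular real trial.

## Numerical and comparison choices

* Scale of runs: headline cells at n = 2×50 use the full 50,000
  replicates; n = 2×500 and 2×1000 cells use 10,000, and the grid-wide
  analysis script defaults to 2,000 per condition. These sizes put MC
  standard errors at roughly 0.001–0.005 on every compared criterion.
* Published table entries are themselves 50,000-replicate Monte Carlo
  estimates, so acceptance comparisons use the combined standard error
  of the two independent runs (ours and the published one). Where an
  exact value is computable — with β₂ = 0 the unadjusted b₁ is a
  difference of binomial log-odds whose expectation can be enumerated —
  the estimate is additionally held to the exact value at 3 MC se,
  a strictly stronger check. That enumeration gives +0.02525 at
  n = 2×50 (β₁ = 1) against a published 0.021, i.e. the printed entry
  sits about two of its own MC standard errors from the truth; the
  accompanying analysis script makes this visible across the n grid.
* Wald-test calibration: the nominal-level property (rejection within
  3 binomial se of 0.05 under β₁ = β₂ = 0) is asserted at n = 2×500.
  At n = 2×50 the Wald test is genuinely mildly anticonservative
  (≈0.056–0.059 observed — a finding, not a bug), so it is compared
  there against the published small-sample rates instead.
* The observed Cohen's-d range at 2×50 is asserted only qualitatively
  (centered, sd ≈ √(4/N)): with tens of thousands of replicates the
  extreme observed |d| is ≈0.8, and any "range" statement about the
  bulk of the distribution depends on how much tail one plots.

## Known limitations

* Single covariate, single link (logit), 1:1 allocation only.
* Model-based Wald inference only — no Firth penalization, sandwich
  variances, or exact tests; at event rates near 50% these would
  change little, but that is untested here.
* Non-converged replicates are dropped per estimator, which at
  realistic scales affects at most a handful of replicates but means
  the estimators are compared on marginally different replicate sets
  in those rare cases (correlation diagnostics use the common subset).
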