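# rctadjust

Monte Carlo evaluation of covariate adjustment strategies for logistic
regression analyses of two-arm randomized trials with a binary outcome.

## The question

Guidelines recommend adjusting trial analyses for baseline prognostic
factors, which in practice means estimating the covariate's effect from
the trial sample at hand. That sample-based model can be overfitted:
the estimated covariate effect may be far from the truth, and there is
no guarantee the resulting treatment-effect estimate is better than an
unadjusted one. This package quantifies, by simulation, how much is
lost by estimating the adjustment model from the sample instead of
knowing it exactly.

Each simulated trial has `2n` patients (1:1 allocation), a baseline
covariate `C` drawn either uniform on [−0.75, 0.75] or Bernoulli(0.25)
(both calibrated to variance 0.1875), and a binary outcome with

    logit Pr(Y = 1) = β₁ T + β₂ C

Three logistic-regression estimators of β₁ are fitted to every
replicate:

| estimator | model |
|---|---|
| unadjusted | `logit(Y) = b₀ + b₁T` |
| sample-adjusted | `logit(Y) = b₀′ + b₁′T + b₂′C`, with `b₂′` estimated |
| true-adjusted | `logit(Y) = b₀″ + b₁″T + offset(β₂C)`, the known covariate effect imposed as an offset |

Across a 90-condition grid (β₁ ∈ {0, 0.5, 1}, β₂ ∈ {0, −0.5, −1}, two
covariate families, n ∈ {50, 100, 200, 500, 1000} per arm), each
estimator is judged on bias `E[b₁] − β₁`, variance, accuracy
(proportion of estimates within ±0.1 logit of β₁), and the proportion
of significant Wald tests (type-1 error under β₁ = 0, power otherwise).
Replicate-level diagnostics relate the three estimates to each other,
to the estimated covariate effect, and to the realized baseline
imbalance in `C` (Cohen's *d*).

Two known phenomena frame the results: the *non-collapsibility of the
odds ratio* (a prognostic covariate shrinks the marginal odds ratio
toward the null even in a perfectly balanced trial, biasing the
unadjusted estimator), and the *small-sample bias* of logistic
coefficients away from the null, which adjustment amplifies.

## Worked example

```python
from rctadjust import TrialConfig, run_condition, summarize_condition, summarize_diagnostics

cfg = TrialConfig(n_per_arm=50, beta1=1.0, beta2=-1.0, covariate_kind="continuous")
res = run_condition(cfg, n_replicates=50_000, master_seed=20230213)
summary = summarize_condition(res)
for kind, est in summary.estimators.items():
    print(f"{kind:16s} bias={est.bias:+.3f} var={est.variance:.2f} "
          f"accuracy={est.accuracy:.2f} power={est.rejection_rate:.2f}")
print("min estimator correlation:", round(summarize_diagnostics(res).min_pairwise_corr, 3))
```

prints

```
unadjusted       bias=-0.018 var=0.19 accuracy=0.18 power=0.64
sample_adjusted  bias=+0.037 var=0.21 accuracy=0.18 power=0.65
true_adjusted    bias=+0.022 var=0.20 accuracy=0.18 power=0.65
min estimator correlation: 0.968
```

Read: at 50 patients per arm with a strong prognostic covariate, the
unadjusted estimate is pulled toward the null (non-collapsibility,
−0.018) while both adjusted estimates inherit the upward small-sample
bias, slightly worse when the covariate effect is estimated from the
sample (+0.037) than when it is known (+0.022). Variance, accuracy and
power are essentially the same for all three; the three estimates are
correlated at 0.97+ replicate by replicate.

## Analysis scripts

Numbered drivers under `analysis/` rerun the study at desk scale and
write CSV tables under `results/`:

* `01_run_grid.py` — the full 90-condition grid (default 2,000
  replicates per condition; `--replicates 50000` for full scale);
  writes the five criterion tables plus a provenance manifest.
* `02_diagnostics.py` — estimator correlations, `corr(b₁′, b₂′)` and
  the Cohen's-*d* imbalance diagnostics at the strong-effect corner.
* `03_small_sample_bias.py` — checks the simulated unadjusted bias
  against an exact finite-sample enumeration (no covariate effect ⇒
  the estimate is a difference of binomial log-odds).

A `rctadjust` command-line tool (`run`, `summarize`, `demo`) exposes
the same machinery with a YAML config file; every output directory
includes a `manifest.json` recording the seed and design.

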