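"""Assessment criteria per estimator and condition.

For each condition and each of the three estimators, the replicate
distribution of the treatment coefficient b1 is reduced to four
criteria:

bias            mean(b1) - beta1
variance        sample variance of b1 (divisor n-1)
accuracy        proportion of b1 within +-0.1 of beta1 (closed interval)
rejection_rate  proportion with two-sided Wald p < alpha; this is the
                type-1 error rate when beta1 = 0 and power otherwise

Every criterion carries its Monte-Carlo standard error, so scaled-down
reproductions have a principled tolerance: se(bias) = sqrt(var/n),
se(variance) ~ var * sqrt(2/(n-1)) (normal approximation), and binomial
se for the two proportions.  Only converged replicates contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TrialConfig
from .engine import ConditionResult
from .fitting import MODEL_KINDS

DEFAULT_ALPHA = 0.05
DEFAULT_ACCURACY_HALFWIDTH = 0.1


@dataclass(frozen=True)
class EstimatorSummary:
    model_kind: str
    n_used: int
    bias: float
    variance: float
    accuracy: float
    rejection_rate: float
    mc_se_bias: float
    mc_se_variance: float
    mc_se_accuracy: float
    mc_se_rejection: float


@dataclass(frozen=True)
class ConditionSummary:
    condition: TrialConfig
    estimators: dict[str, EstimatorSummary]
    alpha: float
    accuracy_halfwidth: float


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def summarize_condition(
    result: ConditionResult,
    alpha: float = DEFAULT_ALPHA,
    accuracy_halfwidth: float = DEFAULT_ACCURACY_HALFWIDTH,
) -> ConditionSummary:
    """Reduce one condition's replicates to the four criteria per estimator."""
    beta1 = result.condition.beta1
    out: dict[str, EstimatorSummary] = {}
    for kind in MODEL_KINDS:
        bf = result.fits[kind]
        ok = bf.converged
        n = int(ok.sum())
        if n < 2:
            raise ValueError(
                f"condition {result.condition.label()}: fewer than 2 converged "
                f"replicates for {kind}"
            )
        b1 = bf.treatment_coef[ok]
        pvals = bf.p_value[ok]
        variance = float(b1.var(ddof=1))
        accuracy = float((np.abs(b1 - beta1) <= accuracy_halfwidth).mean())
        rejection = float((pvals < alpha).mean())
        out[kind] = EstimatorSummary(
            model_kind=kind,
            n_used=n,
            bias=float(b1.mean() - beta1),
            variance=variance,
            accuracy=accuracy,
            rejection_rate=rejection,
            mc_se_bias=float(np.sqrt(variance / n)),
            mc_se_variance=float(variance * np.sqrt(2.0 / (n - 1))),
            mc_se_accuracy=_binomial_se(accuracy, n),
            mc_se_rejection=_binomial_se(rejection, n),
        )
    return ConditionSummary(
        condition=result.condition,
        estimators=out,
        alpha=alpha,
        accuracy_halfwidth=accuracy_halfwidth,
    )


def or_scale_interval(beta1_true: float, halfwidth: float = 0.1) -> tuple[float, float]:
    """The accuracy window exp(beta1 -+ halfwidth) on the odds-ratio scale."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    return (float(np.exp(beta1_true - halfwidth)), float(np.exp(beta1_true + halfwidth)))


#: Report rounding per criterion, matching conventional table precision.
_CRITERIA = {
    "bias": 3,
    "variance": 2,
    "accuracy": 2,
    "rejection_rate": 3,
}


def summary_frame(
    summaries: list[ConditionSummary], rounded: bool = False
) -> pd.DataFrame:
    """One row per (condition, criterion), columns per estimator.

    The layout mirrors the study's report tables: for a given criterion,
    each row is a condition and the three estimator columns sit side by
    side.  ``rounded`` applies the per-criterion report precision.
    """
    rows = []
    for s in summaries:
        for crit, ndigits in _CRITERIA.items():
            row = {
                "criterion": crit,
                "covariate_kind": s.condition.covariate_kind,
                "beta1": s.condition.beta1,
                "beta2": s.condition.beta2,
                "n_per_arm": s.condition.n_per_arm,
            }
            for kind in MODEL_KINDS:
                est = s.estimators[kind]
                val = getattr(est, crit)
                row[kind] = round(val, ndigits) if rounded else val
                row[f"{kind}_mc_se"] = getattr(
                    est, "mc_se_rejection" if crit == "rejection_rate" else f"mc_se_{crit}"
                )
                row[f"{kind}_n_used"] = est.n_used
            rows.append(row)
    return pd.DataFrame(rows)


def criterion_table(
    summaries: list[ConditionSummary], criterion: str, rounded: bool = True
) -> pd.DataFrame:
    """Extract one criterion's table (e.g. ``"bias"``) across conditions.

    ``rejection_rate`` splits naturally into a type-1-error table
    (rows with beta1 = 0) and a power table (beta1 != 0); callers filter
    on ``beta1``.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    df = summary_frame(summaries, rounded=rounded)
    df = df[df["criterion"] == criterion].drop(columns="criterion")
    return df.sort_values(
        ["covariate_kind", "beta2", "beta1", "n_per_arm"]
    ).reset_index(drop=True)
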