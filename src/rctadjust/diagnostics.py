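"""Replicate-level diagnostics: estimator correlations and baseline imbalance.

Randomization balances the covariate only in expectation; any single
trial can show "realized confounding" — a chance between-arm imbalance
in C, quantified here by Cohen's d.  These diagnostics relate the three
per-replicate treatment-effect estimates to each other, to the
estimated covariate effect, and to that imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import TrialConfig
from .fitting import MODEL_KINDS, SAMPLE_ADJUSTED, TRUE_ADJUSTED, UNADJUSTED
from .generate import TrialSample

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .engine import ConditionResult


class DegenerateDataError(ValueError):
    """Raised when a diagnostic is undefined (zero variance somewhere)."""


def cohens_d_batch(treatment: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Cohen's d of the covariate between arms, per replicate.

    d = (mean C treated - mean C control) / pooled SD, with
    Bessel-corrected arm variances pooled as
    sqrt(((n1-1)s1^2 + (n0-1)s0^2) / (n1+n0-2)).  Replicates with zero
    pooled SD (possible for a binary covariate) yield NaN.
    """
    t = np.asarray(treatment).astype(bool)
    C = np.atleast_2d(np.asarray(covariate, dtype=float))
    c1, c0 = C[:, t], C[:, ~t]
    n1, n0 = c1.shape[1], c0.shape[1]
    if n1 < 2 or n0 < 2:
        raise DegenerateDataError("each arm needs >= 2 observations for Cohen's d")
    diff = c1.mean(axis=1) - c0.mean(axis=1)
    pooled_var = (
        (n1 - 1) * c1.var(axis=1, ddof=1) + (n0 - 1) * c0.var(axis=1, ddof=1)
    ) / (n1 + n0 - 2)
    sd = np.sqrt(pooled_var)
    return np.divide(diff, sd, out=np.full(C.shape[0], np.nan), where=sd > 0)


def cohens_d(sample: TrialSample) -> float:
    """Cohen's d of the baseline covariate for a single trial."""
    d = float(cohens_d_batch(sample.treatment, sample.covariate[None, :])[0])
    if np.isnan(d):
        raise DegenerateDataError("pooled covariate SD is zero")
    return d


@dataclass
class DiagnosticSummary:
    """Second-order summaries of one condition's replicates.

    ``pairwise_corr`` is the 3x3 Pearson correlation matrix among the
    treatment-effect estimates, in model order (unadjusted,
    sample-adjusted, true-adjusted).
    """

    condition: TrialConfig
    pairwise_corr: np.ndarray  # (3, 3)
    corr_b1_b2: float  # adjusted b1' vs estimated covariate effect b2'
    corr_b1_d: float  # adjusted b1' vs baseline imbalance d
    d_range: tuple[float, float]
    n_used: int

    @property
    def min_pairwise_corr(self) -> float:
        iu = np.triu_indices(3, k=1)
        return float(self.pairwise_corr[iu].min())


def replicate_diagnostics_frame(result: "ConditionResult") -> pd.DataFrame:
    """Per-replicate tuples (b1 per model, b2', d) for converged replicates.

    This is the export behind any scatterplot layer; only replicates
    where all three models converged are kept.
    """
    mask = result.all_converged_mask()
    return pd.DataFrame(
        {
            "b1_unadjusted": result.fits[UNADJUSTED].treatment_coef[mask],
            "b1_sample_adjusted": result.fits[SAMPLE_ADJUSTED].treatment_coef[mask],
            "b1_true_adjusted": result.fits[TRUE_ADJUSTED].treatment_coef[mask],
            "b2_sample": result.fits[SAMPLE_ADJUSTED].coef[mask, 2],
            "imbalance_d": result.imbalance_d[mask],
        }
    )


def summarize_diagnostics(result: "ConditionResult") -> DiagnosticSummary:
    """Pearson correlations among estimates, and against b2' and d."""
    df = replicate_diagnostics_frame(result)
    df = df[np.isfinite(df["imbalance_d"])]
    if len(df) < 3:
        raise DegenerateDataError("need >= 3 converged replicates")
    b1 = df[["b1_unadjusted", "b1_sample_adjusted", "b1_true_adjusted"]].to_numpy().T
    if np.any(b1.std(axis=1) == 0) or df["b2_sample"].std() == 0:
        raise DegenerateDataError("zero-variance estimate column")
    return DiagnosticSummary(
        condition=result.condition,
        pairwise_corr=np.corrcoef(b1),
        corr_b1_b2=float(
            np.corrcoef(df["b1_sample_adjusted"], df["b2_sample"])[0, 1]
        ),
        corr_b1_d=float(
            np.corrcoef(df["b1_sample_adjusted"], df["imbalance_d"])[0, 1]
        ),
        d_range=(float(df["imbalance_d"].min()), float(df["imbalance_d"].max())),
        n_used=int(len(df)),
    )


def diagnostics_summary_frame(summaries: list[DiagnosticSummary]) -> pd.DataFrame:
    """Flat one-row-per-condition table of the diagnostic summaries."""
    rows = []
    names = list(MODEL_KINDS)
    for s in summaries:
        row = {
            "n_per_arm": s.condition.n_per_arm,
            "beta1": s.condition.beta1,
            "beta2": s.condition.beta2,
            "covariate_kind": s.condition.covariate_kind,
            "n_used": s.n_used,
            "corr_b1_b2": s.corr_b1_b2,
            "corr_b1_d": s.corr_b1_d,
            "d_min": s.d_range[0],
            "d_max": s.d_range[1],
            "min_pairwise_corr": s.min_pairwise_corr,
        }
        for i in range(3):
            for j in range(i + 1, 3):
                row[f"corr_{names[i]}_{names[j]}"] = float(s.pairwise_corr[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
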