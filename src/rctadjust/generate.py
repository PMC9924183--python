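"""Synthetic randomized-trial generation.

Each simulated trial has ``n_per_arm`` treated and ``n_per_arm`` control
patients (fixed 1:1 allocation), a baseline covariate C drawn from one
of two variance-matched families, and a binary outcome Y drawn with
success probability ``expit(beta1*T + beta2*C)``.  There is no intercept
in the generating model: a control patient with C = 0 has outcome
probability exactly 0.5.

Randomness contract
-------------------
Every replicate owns an independent child stream derived from
``(master_seed, condition coordinates, replicate index)`` via
:func:`replicate_seed_sequence`.  Any single replicate of any condition
can therefore be regenerated in isolation, and parallel execution cannot
change the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    BERNOULLI_P,
    BINARY,
    CONTINUOUS,
    ConfigurationError,
    TrialConfig,
    UNIFORM_HIGH,
    UNIFORM_LOW,
)


@dataclass(frozen=True)
class TrialSample:
    """One simulated two-arm trial.

    ``risk`` retains the true per-patient outcome probability used to
    draw ``outcome``; downstream analyses never see it, but it makes the
    generator exactly testable.
    """

    treatment: np.ndarray  # int {0,1}, length 2*n_per_arm
    covariate: np.ndarray  # float
    outcome: np.ndarray  # int {0,1}
    risk: np.ndarray  # float in (0,1)

    @property
    def n_total(self) -> int:
        return self.treatment.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Debug export with one row per patient."""
        return pd.DataFrame(
            {
                "id": np.arange(self.n_total),
                "arm": self.treatment,
                "covariate": self.covariate,
                "outcome": self.outcome,
            }
        )


def _encode_float(x: float) -> int:
    """Map a float to a non-negative integer for seed-key purposes."""
    q = int(round(abs(x) * 1_000_000))
    return 2 * q + (1 if x < 0 else 0)


def condition_key(config: TrialConfig) -> tuple[int, ...]:
    """Stable non-negative integer coordinates for one grid cell."""
    kind_code = 0 if config.covariate_kind == CONTINUOUS else 1
    return (
        config.n_per_arm,
        _encode_float(config.beta1),
        _encode_float(config.beta2),
        kind_code,
    )


def replicate_seed_sequence(
    master_seed: int, config: TrialConfig, replicate_index: int
) -> np.random.SeedSequence:
    """Child seed for one replicate, keyed on the condition coordinates.

    Position-based (not iteration-order-based): two runs that visit the
    conditions in different orders, or split replicates across workers
    differently, still draw identical samples.
    """
    return np.random.SeedSequence(
        entropy=(int(master_seed), *condition_key(config), int(replicate_index))
    )


def replicate_rng(
    master_seed: int, config: TrialConfig, replicate_index: int
) -> np.random.Generator:
    return np.random.default_rng(
        replicate_seed_sequence(master_seed, config, replicate_index)
    )


def generate_covariate(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. covariate values.

    continuous: uniform on the closed interval [-0.75, +0.75]
    (mean 0, variance 0.1875); binary: Bernoulli(0.25) (mean 0.25,
    variance 0.1875).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if kind == CONTINUOUS:
        return rng.uniform(UNIFORM_LOW, UNIFORM_HIGH, size=n)
    if kind == BINARY:
        return (rng.random(n) < BERNOULLI_P).astype(float)
    raise ConfigurationError(f"unknown covariate kind {kind!r}")


def outcome_probability(t, c, beta1: float, beta2: float):
    """Inverse-logit outcome probability expit(beta1*t + beta2*c).

    Accepts scalars or arrays; strictly increasing in each linear-
    predictor term.
    """
    return expit(beta1 * np.asarray(t, dtype=float) + beta2 * np.asarray(c, dtype=float))


def generate_trial(config: TrialConfig, rng: np.random.Generator) -> TrialSample:
    """Generate one trial under ``config``.

    The first ``n_per_arm`` patients are treated (T=1), the rest control;
    patient order carries no information because C and Y are i.i.d.
    given T.
    """
    n = config.n_per_arm
    treatment = np.repeat([1, 0], n)
    covariate = generate_covariate(config.covariate_kind, 2 * n, rng)
    risk = outcome_probability(treatment, covariate, config.beta1, config.beta2)
    outcome = (rng.random(2 * n) < risk).astype(np.int8)
    return TrialSample(
        treatment=treatment.astype(np.int8),
        covariate=covariate,
        outcome=outcome,
        risk=risk,
    )


def generate_replicate(
    config: TrialConfig, master_seed: int, replicate_index: int
) -> TrialSample:
    """Regenerate a single replicate from the seeding contract."""
    return generate_trial(config, replicate_rng(master_seed, config, replicate_index))
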