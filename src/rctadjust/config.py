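"""Experimental-design types for the simulation study.

A *condition* is one cell of the factorial design: per-arm sample size,
true treatment effect ``beta1``, true covariate (prognostic-factor)
effect ``beta2``, and the covariate's distribution family.  The full
default grid is 3 treatment effects x 3 covariate effects x 2 covariate
kinds x 5 sample sizes = 90 conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

CONTINUOUS = "continuous"
BINARY = "binary"
COVARIATE_KINDS = (CONTINUOUS, BINARY)

#: Bounds of the uniform covariate; chosen so Var(C) = 1.5^2 / 12 = 0.1875.
UNIFORM_LOW = -0.75
UNIFORM_HIGH = 0.75
#: Success probability of the Bernoulli covariate; Var = 0.25 * 0.75 = 0.1875.
BERNOULLI_P = 0.25
#: Common covariate variance under both families.
COVARIATE_VARIANCE = 0.1875

DEFAULT_BETA1 = (0.0, 0.5, 1.0)
DEFAULT_BETA2 = (0.0, -0.5, -1.0)
DEFAULT_N_PER_ARM = (50, 100, 200, 500, 1000)


class ConfigurationError(ValueError):
    """Raised when a trial or grid configuration is invalid."""


@dataclass(frozen=True)
class TrialConfig:
    """One cell of the experimental grid.

    Parameters
    ----------
    n_per_arm
        Patients per treatment arm (1:1 allocation, so the trial has
        ``2 * n_per_arm`` patients).
    beta1
        True treatment effect on the logit scale.
    beta2
        True covariate effect on the logit scale.
    covariate_kind
        ``"continuous"`` (uniform on [-0.75, 0.75]) or ``"binary"``
        (Bernoulli with p = 0.25); both have variance 0.1875 so the two
        families are directly comparable.
    """

    n_per_arm: int
    beta1: float
    beta2: float
    covariate_kind: str

    def __post_init__(self) -> None:
        if not isinstance(self.n_per_arm, (int,)) or self.n_per_arm < 2:
            raise ConfigurationError(
                f"n_per_arm must be an integer >= 2, got {self.n_per_arm!r}"
            )
        if self.covariate_kind not in COVARIATE_KINDS:
            raise ConfigurationError(
                f"covariate_kind must be one of {COVARIATE_KINDS}, "
                f"got {self.covariate_kind!r}"
            )

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_arm

    def label(self) -> str:
        return (
            f"n=2x{self.n_per_arm} b1={self.beta1:g} b2={self.beta2:g} "
            f"{self.covariate_kind}"
        )


@dataclass(frozen=True)
class ExperimentGrid:
    """The factorial design: cartesian product of the factor levels.

    Defaults reproduce the full 90-condition study; ``n_replicates``
    defaults to the full-scale 50,000 Monte Carlo replicates.
    """

    beta1_values: Sequence[float] = DEFAULT_BETA1
    beta2_values: Sequence[float] = DEFAULT_BETA2
    covariate_kinds: Sequence[str] = COVARIATE_KINDS
    n_values: Sequence[int] = DEFAULT_N_PER_ARM
    n_replicates: int = 50_000
    master_seed: int = 20230213

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for kind in self.covariate_kinds:
            if kind not in COVARIATE_KINDS:
                raise ConfigurationError(f"unknown covariate kind {kind!r}")

    def conditions(self) -> Iterator[TrialConfig]:
        """Yield every grid cell in canonical (documented) order.

        Order: covariate kind, then beta2, then beta1, then n.  Seed
        derivation does not depend on this order (it is keyed on the
        condition's own coordinates), so iteration order is free to
        change without affecting results.
        """
        for kind, b2, b1, n in itertools.product(
            self.covariate_kinds, self.beta2_values, self.beta1_values, self.n_values
        ):
            yield TrialConfig(n_per_arm=n, beta1=b1, beta2=b2, covariate_kind=kind)

    @property
    def n_conditions(self) -> int:
        return (
            len(self.beta1_values)
            * len(self.beta2_values)
            * len(self.covariate_kinds)
            * len(self.n_values)
        )
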