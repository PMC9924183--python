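"""Monte Carlo engine: replicate a condition, or the whole grid.

Results are held columnar (one array per quantity, indexed by
replicate) rather than as one object per replicate: at the full scale
of 50,000 replicates x 90 conditions x 3 models this is the difference
between seconds and hours.  :meth:`ConditionResult.to_records` restores
the per-replicate record view when object-level access is wanted.

Replicates are generated in bounded-size chunks so that the largest
conditions (2 x 1000 patients) never hold more than a few tens of
millions of doubles at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .config import ExperimentGrid, TrialConfig
from .diagnostics import cohens_d_batch
from .fitting import (
    BatchFit,
    FitResult,
    MODEL_KINDS,
    SAMPLE_ADJUSTED,
    TRUE_ADJUSTED,
    UNADJUSTED,
    fit_model_batch,
)
from .generate import generate_trial, replicate_rng

#: Soft cap on doubles held per generation chunk (~8 such arrays live).
_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class ReplicateRecord:
    """Object view of one replicate: the three fits plus imbalance."""

    condition: TrialConfig
    replicate_index: int
    fits: dict[str, FitResult]
    imbalance_d: float


@dataclass
class ConditionResult:
    """All replicates of one condition, columnar.

    ``fits`` maps model kind to a :class:`BatchFit` whose arrays are
    indexed by replicate; ``imbalance_d`` is Cohen's d of the covariate
    between arms, per replicate.
    """

    condition: TrialConfig
    master_seed: int
    fits: dict[str, BatchFit]
    imbalance_d: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.imbalance_d.shape[0]

    def convergence_counts(self) -> dict[str, int]:
        return {k: int(f.converged.sum()) for k, f in self.fits.items()}

    def all_converged_mask(self) -> np.ndarray:
        mask = np.ones(self.n_replicates, dtype=bool)
        for f in self.fits.values():
            mask &= f.converged
        return mask

    def to_records(self) -> list[ReplicateRecord]:
        out = []
        for r in range(self.n_replicates):
            fits = {}
            for kind, bf in self.fits.items():
                pv = bf.p_value
                fits[kind] = FitResult(
                    model_kind=kind,
                    intercept=float(bf.coef[r, 0]),
                    treatment_coef=float(bf.coef[r, 1]),
                    std_error=float(bf.std_error[r, 1]),
                    p_value=float(pv[r]),
                    converged=bool(bf.converged[r]),
                    loglik=float(bf.loglik[r]),
                    covariate_coef=(
                        float(bf.coef[r, 2]) if kind == SAMPLE_ADJUSTED else None
                    ),
                )
            out.append(
                ReplicateRecord(
                    condition=self.condition,
                    replicate_index=r,
                    fits=fits,
                    imbalance_d=float(self.imbalance_d[r]),
                )
            )
        return out

    def replicate_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (replicate, model)."""
        frames = []
        for kind, bf in self.fits.items():
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": np.arange(self.n_replicates),
                        "model": kind,
                        "intercept": bf.coef[:, 0],
                        "treatment_coef": bf.coef[:, 1],
                        "covariate_coef": (
                            bf.coef[:, 2]
                            if kind == SAMPLE_ADJUSTED
                            else np.full(self.n_replicates, np.nan)
                        ),
                        "std_error": bf.std_error[:, 1],
                        "p_value": bf.p_value,
                        "converged": bf.converged,
                        "imbalance_d": self.imbalance_d,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        for name, value in (
            ("n_per_arm", self.condition.n_per_arm),
            ("beta1", self.condition.beta1),
            ("beta2", self.condition.beta2),
            ("covariate_kind", self.condition.covariate_kind),
        ):
            df.insert(0, name, value)
        return df


def _generate_chunk(
    config: TrialConfig, master_seed: int, start: int, stop: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate replicates [start, stop) of a condition.

    Each replicate draws from its own child stream, so chunk boundaries
    and execution order cannot affect the samples.
    """
    m = config.n_total
    C = np.empty((stop - start, m))
    Y = np.empty((stop - start, m), dtype=np.int8)
    T = np.repeat([1, 0], config.n_per_arm).astype(np.int8)
    for k, rep in enumerate(range(start, stop)):
        sample = generate_trial(config, replicate_rng(master_seed, config, rep))
        C[k] = sample.covariate
        Y[k] = sample.outcome
    return T, C, Y


def run_condition(
    config: TrialConfig,
    n_replicates: int,
    master_seed: int,
    chunk_size: Optional[int] = None,
) -> ConditionResult:
    """Simulate and fit ``n_replicates`` trials of one condition."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if chunk_size is None:
        chunk_size = max(1, _CHUNK_BUDGET // config.n_total)

    parts: dict[str, list[BatchFit]] = {k: [] for k in MODEL_KINDS}
    d_parts: list[np.ndarray] = []
    for start in range(0, n_replicates, chunk_size):
        stop = min(start + chunk_size, n_replicates)
        T, C, Y = _generate_chunk(config, master_seed, start, stop)
        for kind in MODEL_KINDS:
            parts[kind].append(
                fit_model_batch(T, C, Y, kind, beta2_true=config.beta2)
            )
        d_parts.append(cohens_d_batch(T, C))

    fits = {
        kind: BatchFit(
            model_kind=kind,
            coef=np.concatenate([b.coef for b in blist]),
            std_error=np.concatenate([b.std_error for b in blist]),
            converged=np.concatenate([b.converged for b in blist]),
            loglik=np.concatenate([b.loglik for b in blist]),
        )
        for kind, blist in parts.items()
    }
    return ConditionResult(
        condition=config,
        master_seed=master_seed,
        fits=fits,
        imbalance_d=np.concatenate(d_parts),
    )


@dataclass
class GridResult:
    grid: ExperimentGrid
    results: dict[TrialConfig, ConditionResult] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "software": f"rctadjust {__version__}",
            "master_seed": self.grid.master_seed,
            "n_replicates": self.grid.n_replicates,
            "beta1_values": list(self.grid.beta1_values),
            "beta2_values": list(self.grid.beta2_values),
            "covariate_kinds": list(self.grid.covariate_kinds),
            "n_values": list(self.grid.n_values),
            "n_conditions": self.grid.n_conditions,
            "convergence": {
                res.condition.label(): res.convergence_counts()
                for res in self.results.values()
            },
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2) + "\n")


def run_grid(
    grid: ExperimentGrid,
    n_jobs: int = 1,
    conditions: Optional[Iterable[TrialConfig]] = None,
    progress: Optional[callable] = None,
) -> GridResult:
    """Run every cell of the grid.

    Seed derivation is keyed on each condition's own coordinates, so
    the result is invariant to ``n_jobs`` and to the order in which
    conditions are run.
    """
    cells = list(conditions) if conditions is not None else list(grid.conditions())
    if n_jobs == 1:
        results = []
        for cfg in cells:
            res = run_condition(cfg, grid.n_replicates, grid.master_seed)
            if progress is not None:
                progress(res)
            results.append(res)
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(run_condition)(cfg, grid.n_replicates, grid.master_seed)
            for cfg in cells
        )
        if progress is not None:
            for res in results:
                progress(res)
    return GridResult(grid=grid, results={r.condition: r for r in results})
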