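"""Report assembly: the five criterion tables, diagnostics, and manifest."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .diagnostics import diagnostics_summary_frame, summarize_diagnostics
from .engine import GridResult
from .metrics import (
    ConditionSummary,
    criterion_table,
    summarize_condition,
    summary_frame,
)

#: table name -> (criterion, beta1 filter)
TABLE_SPECS = {
    "table_bias": ("bias", None),
    "table_variance": ("variance", None),
    "table_accuracy": ("accuracy", None),
    "table_type1_error": ("rejection_rate", "null"),
    "table_power": ("rejection_rate", "alternative"),
}


def build_tables(
    summaries: list[ConditionSummary], rounded: bool = True
) -> dict[str, pd.DataFrame]:
    """Assemble the five report tables from condition summaries.

    Rejection rates are split into a type-1-error table (beta1 = 0) and
    a power table (beta1 != 0), mirroring how such studies report them.
    """
    tables = {}
    for name, (criterion, which) in TABLE_SPECS.items():
        df = criterion_table(summaries, criterion, rounded=rounded)
        if which == "null":
            df = df[df["beta1"] == 0].reset_index(drop=True)
        elif which == "alternative":
            df = df[df["beta1"] != 0].reset_index(drop=True)
        tables[name] = df
    return tables


def write_reports(
    grid_result: GridResult,
    output_dir: str | Path,
    alpha: float = 0.05,
    accuracy_halfwidth: float = 0.1,
    export_replicates: bool = False,
    diagnostics: bool = True,
) -> dict[str, Path]:
    """Summarize a grid run and write all CSV reports plus the manifest.

    Every CSV sits next to ``manifest.json`` carrying the master seed
    and replicate count, so no table is ever detached from its
    provenance.  Returns the paths written, keyed by artifact name.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summaries = [
        summarize_condition(res, alpha=alpha, accuracy_halfwidth=accuracy_halfwidth)
        for res in grid_result.results.values()
    ]
    path = out / "summary_full.csv"
    summary_frame(summaries, rounded=False).to_csv(path, index=False)
    written["summary_full"] = path

    for name, df in build_tables(summaries).items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    if diagnostics:
        diag = [summarize_diagnostics(res) for res in grid_result.results.values()]
        path = out / "diagnostics.csv"
        diagnostics_summary_frame(diag).to_csv(path, index=False)
        written["diagnostics"] = path

    if export_replicates:
        frames = [res.replicate_frame() for res in grid_result.results.values()]
        path = out / "replicates.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written["replicates"] = path

    path = out / "manifest.json"
    grid_result.write_manifest(path)
    written["manifest"] = path
    return written
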