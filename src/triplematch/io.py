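"""CSV plumbing, summary-table rendering, and run manifests.

Subject tables travel as plain CSV (UTF-8, '.' decimal): one row per
subject, covariate columns, a 3-level ``group`` column coded 1/2/3 and an
optional outcome ``Y``.  Matched samples and balance reports are also
CSV; machine outputs store percentages as plain numbers (82.6), only the
human-readable renderings append '%'.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import SimulationSummary
from .matching import MatchedSample
from .synthetic import COVARIATES

__all__ = [
    "SubjectTableError",
    "load_subject_csv",
    "write_subject_csv",
    "write_matched_csv",
    "render_summary_table",
    "write_manifest",
]


class SubjectTableError(ValueError):
    """A subject CSV violates the expected schema."""


def load_subject_csv(
    path,
    group_col: str = "group",
    covariates: list[str] | None = None,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Read and validate a subject table.

    Checks that the group column exists with exactly ``n_groups`` levels
    and that every covariate column is numeric and complete; dichotomous
    columns are those whose values are a subset of {0, 1}.  Errors name
    the offending column and 1-based data line.
    """
    path = Path(path)
    if not path.exists():
        raise SubjectTableError(f"no such file: {path}")
    table = pd.read_csv(path)
    if group_col not in table.columns:
        raise SubjectTableError(f"missing group column {group_col!r}")
    if covariates is None:
        covariates = [c for c in table.columns if c not in (group_col, "Y")]
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise SubjectTableError(f"missing covariate columns: {missing}")
    levels = table[group_col].dropna().unique()
    if len(levels) != n_groups:
        raise SubjectTableError(
            f"group column {group_col!r} has {len(levels)} levels "
            f"({sorted(levels.tolist())}), expected {n_groups}"
        )
    for col in [*covariates, group_col]:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SubjectTableError(
                f"non-numeric value {table[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise SubjectTableError(f"missing value in column {col!r} at line {line}")
        table[col] = vals
    # preserve integer typing of dichotomous and group columns
    for col in [*covariates, group_col]:
        v = table[col].to_numpy()
        if np.isin(np.unique(v), (0, 1)).all() or col == group_col:
            if np.array_equal(v, v.astype(np.int64)):
                table[col] = v.astype(np.int64)
    return table


def write_subject_csv(table: pd.DataFrame, path) -> None:
    """Write a subject table as CSV without the index."""
    table.to_csv(path, index=False)


def write_matched_csv(sample: MatchedSample, path, unmatched_path=None) -> None:
    """Write matched sets (triplet_id, id per group, distance) and optionally
    the unmatched subject ids to a side-car CSV."""
    rows = []
    for t_id, trip in enumerate(sample.triplets):
        row = {"triplet_id": t_id}
        for k, idx in enumerate(trip.indices, start=1):
            row[f"id_g{k}"] = idx
        row["distance"] = trip.total_distance
        rows.append(row)
    cols = ["triplet_id"] + [f"id_g{k+1}" for k in range(len(sample.group_labels) or 3)]
    cols += ["distance"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    if unmatched_path is not None:
        pd.DataFrame({"id": sample.unmatched}).to_csv(unmatched_path, index=False)


_SUMMARY_COLUMNS = list(COVARIATES) + ["matching_ratio", "RB13", "RB23", "MSE13", "MSE23"]


def _format_cell(col: str, value: float) -> str:
    if col in ("matching_ratio", "RB13", "RB23"):
        return f"{value:.1f}%"
    return f"{value:.3f}"


def render_summary_table(summary: SimulationSummary, style: str = "csv") -> str:
    """Render a per-caliper summary in the study's table layout.

    ``csv`` emits machine-readable numbers; ``markdown`` formats
    percentages with one decimal and SD/MSE columns with three.  Both
    renderings carry identical numbers.
    """
    table = summary.table
    if table.empty:
        raise ValueError("summary has no caliper rows")
    cols = ["caliper"] + [c for c in _SUMMARY_COLUMNS if c in table.columns]
    if style == "csv":
        return table[cols].to_csv(index=False)
    if style == "markdown":
        header = "| " + " | ".join(cols) + " |"
        sep = "|" + "|".join(["---"] * len(cols)) + "|"
        lines = [header, sep]
        for _, row in table.iterrows():
            cells = [f"{row['caliper']:.1f}"]
            cells += [_format_cell(c, row[c]) for c in cols[1:]]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown style {style!r}")


def write_manifest(path, config: dict) -> None:
    """Write a reproducibility manifest (YAML, or JSON for .json paths)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, default=str))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
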