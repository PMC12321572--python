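"""Replicate aggregation, variance-stabilizing transforms, model-table export.

Image stacks within one donor are technical replicates; donors ("cases") are
the biological replicates.  Case-level values are arithmetic means of the
case's stack values per metric.  Mixed-model fitting itself is deliberately
delegated to off-the-shelf statistics software: this module exports tidy,
model-ready tables together with the formula string, transform name and any
zero-offset applied, so a fit is fully reproducible elsewhere.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aggregate",
    "TukeyResult",
    "tukey_ladder",
    "tukey_transform",
    "fixed_transforms",
    "export_model_table",
]

#: columns identifying one measurement row at stack level
STACK_KEYS = ["case_id", "group", "region", "stack_id", "metric"]


def aggregate(stack_level: pd.DataFrame) -> pd.DataFrame:
    """Collapse stack-level (technical) rows to case-level (biological) means.

    Expects tidy columns ``case_id, group, region, stack_id, metric, value``.
    Case means ignore missing stack values; a case whose values are all
    missing for a metric keeps a missing mean (with ``n_stacks = 0``).
    Aggregation is invariant to the order of the input rows.
    """
    required = {"case_id", "metric", "value"}
    missing = required - set(stack_level.columns)
    if missing:
        raise ValueError(f"stack table lacks column(s) {sorted(missing)}")
    if "stack_id" in stack_level.columns:
        dup = stack_level.duplicated(subset=[c for c in STACK_KEYS if c in stack_level.columns])
        if dup.any():
            raise ValueError("duplicated (case, stack, metric) rows in stack table")
    keys = [c for c in ("case_id", "group", "region", "metric") if c in stack_level.columns]
    out = (
        stack_level.groupby(keys, dropna=False, sort=True)["value"]
        .agg(value="mean", n_stacks="count")
        .reset_index()
    )
    out["level"] = "case"
    empty = out[out["n_stacks"] == 0]
    if len(empty):
        import warnings

        warnings.warn(
            f"{len(empty)} case/metric group(s) have no non-missing stack values; "
            "their case means are reported as missing"
        )
    return out


@dataclass
class TukeyResult:
    """Ladder-of-powers fit: exponent, transformed data, normality score."""

    lam: float
    transformed: np.ndarray
    shapiro_w: float
    offset: float = 0.0


def tukey_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """One rung of the ladder of powers: x**lam (lam>0), log x (lam=0),
    -(x**lam) (lam<0).  Monotone increasing on positive input for every lam."""
    x = np.asarray(values, dtype=float)
    if lam > 0:
        return x**lam
    if lam == 0:
        return np.log(x)
    return -(x**lam)


def tukey_ladder(
    values: Sequence[float],
    lam_min: float = -10.0,
    lam_max: float = 10.0,
    step: float = 0.025,
) -> TukeyResult:
    """Pick the ladder-of-powers exponent that best normalizes the sample.

    Grid search over lambda in ``[lam_min, lam_max]`` (step 0.025), choosing
    the lambda that maximizes the Shapiro-Wilk W of the transformed sample.
    Zeros are shifted by half the smallest positive value (the offset is
    reported); negative input is an error.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to choose a transform")
    if np.any(x < 0):
        raise ValueError("Tukey ladder requires non-negative input")
    offset = 0.0
    if np.any(x == 0):
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all values are zero; transform undefined")
        offset = float(positive.min()) / 2.0
        x = x + offset

    grid = np.arange(lam_min, lam_max + step / 2, step)
    # exact zero rung for the log transform despite float stepping
    grid = grid[np.abs(grid) > 1e-12]
    grid = np.concatenate([grid, [0.0]])
    best_lam, best_w = 1.0, -np.inf
    logx = np.log(x)
    for lam in grid:
        if lam == 0:
            t = logx
        else:
            t = np.exp(lam * logx)
            if lam < 0:
                t = -t
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        w = stats.shapiro(t).statistic
        if w > best_w:
            best_w, best_lam = float(w), float(lam)
    return TukeyResult(
        lam=best_lam,
        transformed=tukey_transform(x, best_lam),
        shapiro_w=best_w,
        offset=offset,
    )


def fixed_transforms(
    values: Sequence[float], kind: str, percent_scale: bool = False
) -> np.ndarray:
    """Elementwise sqrt / log / arcsine-square-root transform.

    ``arcsine_sqrt`` expects proportions in [0, 1]; with ``percent_scale``
    percentages in [0, 100] are divided by 100 first.  Domain violations name
    the offending value.
    """
    x = np.asarray(list(values), dtype=float)
    if kind == "sqrt":
        bad = x[x < 0]
        if bad.size:
            raise ValueError(f"sqrt transform: negative value {bad[0]!r}")
        return np.sqrt(x)
    if kind == "log":
        bad = x[x <= 0]
        if bad.size:
            raise ValueError(f"log transform: non-positive value {bad[0]!r}")
        return np.log(x)
    if kind == "arcsine_sqrt":
        if percent_scale:
            x = x / 100.0
        bad = x[(x < 0) | (x > 1)]
        if bad.size:
            raise ValueError(
                f"arcsine_sqrt transform: value {bad[0]!r} outside [0, 1]"
            )
        return np.arcsin(np.sqrt(x))
    raise ValueError(f"unknown transform kind {kind!r}")


def export_model_table(
    table: pd.DataFrame,
    formula: str,
    out_dir: str | Path,
    name: str = "model_table",
    transform: str | None = None,
    transform_lambda: float | None = None,
    offset: float | None = None,
) -> tuple[Path, Path]:
    """Write one tidy CSV plus a JSON sidecar recording the model formula.

    Every bare column name referenced in the formula must exist in the table
    (the response may instead be a named metric present in a ``metric``
    column).  No model is fitted here.  Re-export of unchanged input is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tokens = set(re.findall(r"[A-Za-z_%][A-Za-z0-9_%]*", formula))
    tokens -= {"1"}
    cols = set(table.columns)
    metrics = set(table["metric"].unique()) if "metric" in table.columns else set()
    missing = {t for t in tokens if t not in cols and t not in metrics}
    if missing:
        raise ValueError(
            f"formula terms {sorted(missing)} not found; available columns: "
            f"{sorted(cols)}; available metrics: {sorted(metrics)}"
        )
    csv_path = out_dir / f"{name}.csv"
    table.to_csv(csv_path, index=False)
    meta = {
        "formula": formula,
        "transform": transform,
        "transform_lambda": transform_lambda,
        "zero_offset": offset,
        "n_rows": int(len(table)),
        "columns": list(table.columns),
    }
    meta_path = out_dir / f"{name}.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return csv_path, meta_path
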