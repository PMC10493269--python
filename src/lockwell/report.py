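"""Percentile inference and descriptive summaries for bootstrap ensembles.

The point estimate for each coefficient is the median of its bootstrap
draws; the 95% confidence interval is the empirical 2.5th/97.5th percentile
pair (linear-interpolation convention); an effect is flagged significant
when its interval excludes zero.  Presentation rescaling (e.g. per 10 days
of lockdown for interaction terms, per 10 years for age) multiplies the
estimate and both interval endpoints and never changes the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEnsemble
from .exceptions import SchemaError, ValidationError
from .preprocess import TIME_COLUMN

logger = logging.getLogger(__name__)

PERCENTILE_METHOD = "linear"  # numpy interpolation convention, recorded in output


def default_scales(columns) -> dict[str, float]:
    """Presentation scales: x10 for interactions and the time column (per 10
    days of lockdown) and x10 for age (per 10 years); 1 otherwise."""
    scales = {}
    for c in columns:
        if c == TIME_COLUMN or c.endswith(f":{TIME_COLUMN}"):
            scales[c] = 10.0
        elif c == "age":
            scales[c] = 10.0
        else:
            scales[c] = 1.0
    return scales


def summarize_coefficients(
    ensemble: BootstrapEnsemble,
    alpha: float = 0.05,
    scales: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Median estimate, percentile CI and significance flag per coefficient.

    Returns a frame indexed by design column with ``estimate`` (median of
    draws), ``ci_low`` / ``ci_high`` (empirical alpha/2 and 1-alpha/2
    percentiles), ``significant`` (CI excludes zero), the applied
    ``report_scale`` and the scaled triple.  Columns missing from ``scales``
    default to 1 (logged).
    """
    if ensemble.B < 2:
        raise ValidationError("need at least 2 draws per coefficient")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    scales = dict(scales) if scales is not None else default_scales(ensemble.columns)
    draws = ensemble.coefs.to_numpy()
    lo, med, hi = np.percentile(
        draws, [100 * alpha / 2, 50, 100 * (1 - alpha / 2)],
        axis=0, method=PERCENTILE_METHOD,
    )
    rows = []
    for j, col in enumerate(ensemble.columns):
        if col not in scales:
            logger.info("no report scale for %r; defaulting to 1", col)
        s = float(scales.get(col, 1.0))
        rows.append({
            "column": col,
            "estimate": med[j],
            "ci_low": lo[j],
            "ci_high": hi[j],
            "significant": bool(lo[j] > 0 or hi[j] < 0),
            "report_scale": s,
            "estimate_scaled": med[j] * s,
            "ci_low_scaled": lo[j] * s,
            "ci_high_scaled": hi[j] * s,
        })
    out = pd.DataFrame(rows).set_index("column")
    out.attrs["alpha"] = alpha
    out.attrs["percentile_method"] = PERCENTILE_METHOD
    return out


def rescale_effect(summary: pd.Series, factor: float) -> pd.Series:
    """Rescale one coefficient summary row by a positive factor.

    Scales the estimate and both CI endpoints; the significance flag is
    scale-invariant and untouched.
    """
    if factor <= 0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    out = summary.copy()
    out["report_scale"] = float(summary["report_scale"]) * factor
    for f in ("estimate_scaled", "ci_low_scaled", "ci_high_scaled"):
        out[f] = summary[f] * factor
    return out


@dataclass
class DescriptiveTable:
    """Per-week and overall descriptive statistics (counts table style)."""

    outcome: pd.DataFrame  # week, n, mean, sd (week includes "Total")
    levels: pd.DataFrame   # variable, level, week, n, pct

    def overall_pct(self, variable: str, level: str) -> float:
        sub = self.levels
        row = sub[
            (sub["variable"] == variable)
            & (sub["level"] == level)
            & (sub["week"] == "Total")
        ]
        if row.empty:
            raise KeyError((variable, level))
        return float(row["pct"].iloc[0])

    def format(self) -> pd.DataFrame:
        """Wide string table: one row per variable level, 'n (pct%)' cells."""
        sub = self.levels.copy()
        sub["cell"] = [
            f"{int(n):,} ({p:.1f}%)" for n, p in zip(sub["n"], sub["pct"])
        ]
        return sub.pivot(index=["variable", "level"], columns="week", values="cell")


def descriptive_table(
    table: pd.DataFrame,
    variables,
    week_col: str = "week",
    outcome_col: str = "wemwbs",
) -> DescriptiveTable:
    """Weekly + overall level counts/percentages and outcome mean (SD).

    Percentages are of each week's column total, as in survey descriptive
    tables; the overall column aggregates all weeks.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise SchemaError(f"unknown variable(s): {missing}")
    weeks = sorted(table[week_col].unique())
    groups = [(str(w), table[table[week_col] == w]) for w in weeks]
    groups.append(("Total", table))

    outcome_rows = []
    level_rows = []
    for label, sub in groups:
        y = pd.to_numeric(sub[outcome_col], errors="coerce")
        outcome_rows.append({
            "week": label, "n": len(sub),
            "mean": float(y.mean()), "sd": float(y.std(ddof=1)),
        })
        for var in variables:
            counts = sub[var].astype(str).value_counts()
            for level, n in counts.items():
                level_rows.append({
                    "variable": var, "level": level, "week": label,
                    "n": int(n), "pct": 100.0 * n / len(sub),
                })
    return DescriptiveTable(
        outcome=pd.DataFrame(outcome_rows),
        levels=pd.DataFrame(level_rows),
    )


def five_number(draws) -> dict[str, float]:
    """Boxplot statistics of a draw vector, Tukey-style whiskers.

    Quartiles use the linear-interpolation convention; whiskers extend to
    the most extreme data point within 1.5 x IQR of the corresponding hinge;
    points beyond are outliers.
    """
    x = np.asarray(draws, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75], method=PERCENTILE_METHOD)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(np.sum((x < lo_fence) | (x > hi_fence))),
    }


def effect_report(
    summaries: pd.DataFrame,
    group_map: dict[str, str],
    ensemble: BootstrapEnsemble | None = None,
) -> pd.DataFrame:
    """Group and sort coefficient summaries for presentation.

    Each coefficient gets a substantive ``group`` (e.g. background /
    covid / coping) from ``group_map`` — unmapped columns land in
    ``unassigned`` (logged) — and a ``role``: ``temporal`` for the time
    column and time interactions, ``main`` otherwise.  Rows are sorted by
    group, role and estimate.  When the ensemble is supplied, boxplot
    five-number summaries of each coefficient's draws are appended for
    plotting.
    """
    out = summaries.copy()
    groups = []
    for col in out.index:
        g = group_map.get(col)
        if g is None:
            logger.info("column %r has no group; placed in 'unassigned'", col)
            g = "unassigned"
        groups.append(g)
    out["group"] = groups
    out["role"] = [
        "temporal" if c == TIME_COLUMN or c.endswith(f":{TIME_COLUMN}") else "main"
        for c in out.index
    ]
    if ensemble is not None:
        stats = {
            c: five_number(ensemble.coefs[c].to_numpy()) for c in out.index
            if c in ensemble.coefs.columns
        }
        box = pd.DataFrame(stats).T
        out = out.join(box)
    return out.sort_values(["group", "role", "estimate"])
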