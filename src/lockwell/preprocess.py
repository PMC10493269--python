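"""Outcome scoring, design-matrix encoding, predictor filters, standardization.

The analysis regresses the Warwick-Edinburgh Mental Well-Being Scale total
(WEMWBS, 14 items scored 1-5, summed to 14-70) on a battery of
socio-demographic, health, COVID-related and coping predictors, entered as
main effects plus their first-order interaction with days since survey
launch.  This module turns a tidy respondent table into that numeric design
matrix and applies the two pre-model filters (near-zero-variance columns and
pairwise correlation > 0.9), then standardizes columns so the L2 penalty
treats them symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

WEMWBS_ITEMS = 14
WEMWBS_MIN = 14
WEMWBS_MAX = 70

#: Name of the time column (days since survey launch) in every design matrix.
TIME_COLUMN = "days"


def score_wemwbs(items) -> int:
    """Sum the 14 WEMWBS item responses into the 14-70 total score.

    Parameters
    ----------
    items
        Sequence of exactly 14 integer responses, each in 1..5.  Higher
        totals indicate more positive well-being.
    """
    items = list(items)
    if len(items) != WEMWBS_ITEMS:
        raise ValidationError(
            f"WEMWBS requires exactly {WEMWBS_ITEMS} items, got {len(items)}"
        )
    for i, v in enumerate(items):
        if not float(v).is_integer() or not 1 <= int(v) <= 5:
            raise ValidationError(f"WEMWBS item {i} out of range 1..5: {v!r}")
    return int(sum(int(v) for v in items))


@dataclass(frozen=True)
class Predictor:
    """One raw survey predictor and how to encode it.

    kind:
        ``binary``      -> single 0/1 column (1 = non-reference level);
        ``categorical`` -> L-1 reference-coded dummy columns;
        ``likert``      -> single numeric column (ordered scale as numbers);
        ``continuous``  -> single numeric column.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ("no", "yes")
    likert_range: tuple[int, int] = (1, 5)
    report_scale: float = 1.0

    KINDS = ("binary", "categorical", "likert", "continuous")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise SchemaError(f"unknown predictor kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary predictor {self.name!r} needs 2 levels")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise SchemaError(f"categorical predictor {self.name!r} needs >=2 levels")

    @property
    def reference(self) -> str | None:
        if self.kind in ("binary", "categorical"):
            return self.levels[0]
        return None

    def column_names(self) -> list[str]:
        """Design-matrix columns this predictor produces."""
        if self.kind == "binary":
            return [self.name]
        if self.kind == "categorical":
            return [f"{self.name}[{lv}]" for lv in self.levels[1:]]
        return [self.name]


@dataclass(frozen=True)
class PredictorSchema:
    predictors: tuple[Predictor, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate predictor names in schema")

    def __iter__(self):
        return iter(self.predictors)

    def __getitem__(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def main_columns(self) -> list[str]:
        cols: list[str] = []
        for p in self.predictors:
            cols.extend(p.column_names())
        return cols

    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": p.name,
                "kind": p.kind,
                "levels": list(p.levels),
                "likert_range": list(p.likert_range),
                "report_scale": p.report_scale,
            }
            for p in self.predictors
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PredictorSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            tuple(
                Predictor(
                    name=d["name"],
                    kind=d["kind"],
                    levels=tuple(d.get("levels", ("no", "yes"))),
                    likert_range=tuple(d.get("likert_range", (1, 5))),
                    report_scale=float(d.get("report_scale", 1.0)),
                )
                for d in payload
            )
        )


@dataclass
class DesignMatrix:
    """Numeric design matrix with per-column provenance metadata.

    ``meta`` is indexed by column name with fields ``source`` (raw predictor),
    ``role`` (``time`` / ``main`` / ``interaction``), ``reference`` (omitted
    reference level, empty otherwise) and, once standardized, ``center`` /
    ``scale``.  ``y`` holds the outcome; after :func:`standardize` it is
    centered and ``y_center`` records the subtracted mean.
    """

    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame
    standardized: bool = False
    y_center: float = 0.0

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, columns: list[str]) -> "DesignMatrix":
        """Restrict to the given columns (order preserved as given)."""
        missing = [c for c in columns if c not in self.X.columns]
        if missing:
            raise SchemaError(f"columns not in design: {missing}")
        return DesignMatrix(
            X=self.X[columns].copy(),
            y=self.y.copy(),
            meta=self.meta.loc[columns].copy(),
            standardized=self.standardized,
            y_center=self.y_center,
        )


def design_from_arrays(
    X, y, columns=None, time_column: str | None = None
) -> DesignMatrix:
    """Wrap plain arrays as an unstandardized DesignMatrix (all-main roles).

    Convenience for simulation studies and numerical checks that do not
    start from a survey table.  ``time_column`` (if given) must name one of
    the columns and is assigned the ``time`` role.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(
            np.asarray(X, dtype=float),
            columns=columns or [f"x{j}" for j in range(np.asarray(X).shape[1])],
        )
    meta = pd.DataFrame(
        {
            "source": list(X.columns),
            "role": [
                "time" if c == time_column else "main" for c in X.columns
            ],
            "reference": "",
        },
        index=pd.Index(X.columns, name="column"),
    )
    if time_column is not None and time_column not in X.columns:
        raise SchemaError(f"time column {time_column!r} not among columns")
    return DesignMatrix(X=X, y=np.asarray(y, dtype=float), meta=meta)


def encode_predictors(
    table: pd.DataFrame, schema: PredictorSchema
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Encode raw predictor columns into numeric design columns.

    Returns the numeric frame and its metadata (source predictor, role
    ``main``, reference level).  Shared by the generator (to inject effects
    on encoded columns) and by :func:`encode_design`.
    """
    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for p in schema:
        if p.name not in table.columns:
            raise SchemaError(f"predictor {p.name!r} missing from table")
        raw = table[p.name]
        if p.kind in ("binary", "categorical"):
            values = raw.astype(str)
            unseen = sorted(set(values) - set(p.levels))
            if unseen:
                raise SchemaError(
                    f"predictor {p.name!r} has unseen level(s) {unseen}; "
                    f"known levels: {list(p.levels)}"
                )
            for col, lv in zip(p.column_names(), p.levels[1:]):
                cols[col] = (values == lv).to_numpy(dtype=float)
                meta_rows.append(
                    {"column": col, "source": p.name, "role": "main",
                     "reference": p.reference}
                )
        else:
            arr = pd.to_numeric(raw, errors="raise").to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in predictor {p.name!r}")
            cols[p.name] = arr
            meta_rows.append(
                {"column": p.name, "source": p.name, "role": "main", "reference": ""}
            )
    X = pd.DataFrame(cols, index=table.index)
    meta = pd.DataFrame(meta_rows).set_index("column")
    return X, meta


def encode_design(
    table: pd.DataFrame,
    schema: PredictorSchema,
    outcome_col: str = "wemwbs",
    time_col: str = TIME_COLUMN,
) -> DesignMatrix:
    """Build the (unstandardized) design matrix: time column + main effects.

    The time column (days since survey launch) is placed first; it is a
    predictor in its own right and the variable every interaction is built
    from.
    """
    for c in (outcome_col, time_col):
        if c not in table.columns:
            raise SchemaError(f"required column {c!r} missing from table")
    Xmain, meta = encode_predictors(table, schema)
    t = pd.to_numeric(table[time_col], errors="raise").to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValidationError("days since launch must be non-negative")
    y = pd.to_numeric(table[outcome_col], errors="raise").to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite outcome values")
    X = pd.concat([pd.DataFrame({TIME_COLUMN: t}, index=table.index), Xmain], axis=1)
    time_meta = pd.DataFrame(
        [{"column": TIME_COLUMN, "source": time_col, "role": "time", "reference": ""}]
    ).set_index("column")
    return DesignMatrix(X=X, y=y, meta=pd.concat([time_meta, meta]))


def add_time_interactions(design: DesignMatrix) -> DesignMatrix:
    """Append one ``<main>:days`` column per main effect (elementwise product).

    Main and time columns are left untouched; interaction columns are built
    from the raw (pre-standardization) values, so the product structure is
    exact at construction.
    """
    if TIME_COLUMN not in design.X.columns:
        raise SchemaError("design has no time column; encode_design first")
    if design.standardized:
        raise SchemaError("interactions must be added before standardization")
    mains = design.meta.index[design.meta["role"] == "main"]
    if len(mains) == 0:
        raise SchemaError("design has no main columns to interact with time")
    t = design.X[TIME_COLUMN].to_numpy()
    inter = {f"{c}:{TIME_COLUMN}": design.X[c].to_numpy() * t for c in mains}
    meta_rows = [
        {"column": f"{c}:{TIME_COLUMN}",
         "source": design.meta.loc[c, "source"],
         "role": "interaction",
         "reference": design.meta.loc[c, "reference"]}
        for c in mains
    ]
    X = pd.concat([design.X, pd.DataFrame(inter, index=design.X.index)], axis=1)
    meta = pd.concat([design.meta, pd.DataFrame(meta_rows).set_index("column")])
    return DesignMatrix(X=X, y=design.y.copy(), meta=meta)


def _nzv_stats(col: np.ndarray) -> tuple[float, float]:
    """(frequency ratio, percent unique) of a column."""
    values, counts = np.unique(col, return_counts=True)
    counts = np.sort(counts)[::-1]
    if len(counts) == 1:
        ratio = np.inf
    else:
        ratio = counts[0] / counts[1]
    unique_pct = 100.0 * len(values) / len(col)
    return float(ratio), float(unique_pct)


def filter_near_zero_variance(
    design: DesignMatrix,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
) -> tuple[DesignMatrix, pd.DataFrame]:
    """Drop near-zero-variance columns, the standard pre-model screen.

    A column is removed when its most-frequent / second-most-frequent value
    ratio is at least ``freq_ratio_cut`` AND its percentage of distinct
    values is at most ``unique_pct_cut``; constant columns are always
    removed.  The time column is structural (interactions derive from it)
    and is never dropped.  Returns the filtered design plus a removal log
    with both statistics per dropped column.
    """
    removed: list[dict] = []
    keep: list[str] = []
    for c in design.X.columns:
        if design.meta.loc[c, "role"] == "time":
            keep.append(c)
            continue
        ratio, upct = _nzv_stats(design.X[c].to_numpy())
        constant = not np.isfinite(ratio) and design.X[c].nunique() == 1
        if constant or (ratio >= freq_ratio_cut and upct <= unique_pct_cut):
            removed.append(
                {"column": c, "freq_ratio": ratio, "unique_pct": upct,
                 "reason": "constant" if constant else "near-zero variance"}
            )
        else:
            keep.append(c)
    log = pd.DataFrame(removed, columns=["column", "freq_ratio", "unique_pct", "reason"])
    return design.subset(keep), log


def filter_correlated(
    design: DesignMatrix, threshold: float = 0.9
) -> tuple[DesignMatrix, pd.DataFrame]:
    """Iteratively drop one of each pair with |Pearson r| above ``threshold``.

    At each step the most correlated remaining pair is found; if it exceeds
    the threshold, the member with the larger mean absolute correlation to
    all other remaining columns is removed (lexicographically later name on
    ties).  The time column is structural and exempt: when it is one of the
    pair, the other member is removed.
    """
    cols = [c for c in design.X.columns]
    corr = design.X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = pd.DataFrame(corr, index=cols, columns=cols)
    removed: list[dict] = []
    while len(corr) >= 2:
        arr = corr.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        r = arr[i, j]
        if r <= threshold:
            break
        a, b = corr.index[i], corr.index[j]
        mean_a = corr.loc[a].drop(a).mean()
        mean_b = corr.loc[b].drop(b).mean()
        if design.meta.loc[a, "role"] == "time":
            drop = b
        elif design.meta.loc[b, "role"] == "time":
            drop = a
        elif mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        removed.append(
            {"column": drop, "pair": a if drop == b else b, "abs_corr": float(r),
             "mean_abs_corr": float(mean_a if drop == a else mean_b)}
        )
        corr = corr.drop(index=drop, columns=drop)
    keep = [c for c in design.X.columns if c in corr.index]
    log = pd.DataFrame(removed, columns=["column", "pair", "abs_corr", "mean_abs_corr"])
    return design.subset(keep), log


def standardize(design: DesignMatrix, strict: bool = True) -> DesignMatrix:
    """Center every column and scale non-time columns to unit SD; center y.

    The time column keeps its per-day scale (scale constant 1) so its
    coefficient stays directly interpretable in score units per day; all
    other columns are put on a common SD=1 scale so the ridge penalty is
    applied symmetrically.  Centering and scale constants are stored in the
    metadata so fitted coefficients can be reported on the original scale.

    With ``strict`` (the default) a zero-variance column raises — such
    columns should have been filtered.  ``strict=False`` assigns them scale 1
    (they become all-zero columns), which internal cross-validation uses to
    stay defined on unlucky training splits.
    """
    if design.standardized:
        return design
    X = design.X.to_numpy(dtype=float).copy()
    centers = X.mean(axis=0)
    sds = X.std(axis=0)
    scales = np.ones_like(sds)
    for k, c in enumerate(design.X.columns):
        if design.meta.loc[c, "role"] == "time":
            continue
        if sds[k] == 0:
            if strict:
                raise ValidationError(
                    f"zero-variance column {c!r}; filter before standardizing"
                )
            scales[k] = 1.0
        else:
            scales[k] = sds[k]
    X = (X - centers) / scales
    meta = design.meta.copy()
    meta["center"] = centers
    meta["scale"] = scales
    y_center = float(np.mean(design.y))
    return DesignMatrix(
        X=pd.DataFrame(X, index=design.X.index, columns=design.X.columns),
        y=design.y - y_center,
        meta=meta,
        standardized=True,
        y_center=y_center,
    )


def destandardize(design: DesignMatrix) -> DesignMatrix:
    """Invert :func:`standardize`, restoring original-scale columns and y."""
    if not design.standardized:
        return design
    X = design.X.to_numpy() * design.meta["scale"].to_numpy() + design.meta[
        "center"
    ].to_numpy()
    meta = design.meta.drop(columns=["center", "scale"])
    return DesignMatrix(
        X=pd.DataFrame(X, index=design.X.index, columns=design.X.columns),
        y=design.y + design.y_center,
        meta=meta,
        standardized=False,
        y_center=0.0,
    )
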