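"""Balanced down-sampling bootstrap over lockdown weeks.

Respondent arrivals are heavily imbalanced across survey weeks, so each
bootstrap replicate resamples every week with replacement down to the size
of the smallest week (the minority week is itself resampled with
replacement at its own size), giving every week equal weight.  Each
replicate is then encoded, standardized with its own constants, its penalty
selected by cross-validation, and refit at the selected penalty; the
aligned coefficient draws across replicates form the inference ensemble.

Column filtering (near-zero variance, pairwise correlation) happens once on
the full table before the loop so every replicate estimates the same,
aligned coefficient set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .preprocess import (
    DesignMatrix,
    PredictorSchema,
    add_time_interactions,
    encode_design,
    filter_correlated,
    filter_near_zero_variance,
    standardize,
)
from .selection import cv_select_lambda, lambda_grid


def balanced_downsample(
    table: pd.DataFrame, seed, week_col: str = "week"
) -> pd.DataFrame:
    """Resample each week with replacement down to the smallest week's size.

    Output has exactly ``m x n_weeks`` rows (m = minority-week size); every
    row keeps its original week label, and the minority week too is drawn
    with replacement at size m.  Reproducible from ``seed``.
    """
    if week_col not in table.columns:
        raise ValidationError(f"no {week_col!r} column in table")
    counts = table[week_col].value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 weeks to balance")
    if (counts == 0).any():
        empty = counts.index[counts == 0].tolist()
        raise ValidationError(f"week(s) with zero rows: {empty}")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for week in sorted(counts.index):
        rows = table.index[table[week_col] == week]
        parts.append(table.loc[rng.choice(rows, size=m, replace=True)])
    return pd.concat(parts, ignore_index=True)


@dataclass
class BootstrapEnsemble:
    """Aligned coefficient draws from B balanced-bootstrap replicates.

    ``coefs`` is a B x p frame (original predictor scale) whose columns are
    the post-filter design columns; ``lambdas`` and ``r2`` hold each
    replicate's selected penalty and full-replicate training R^2.
    """

    coefs: pd.DataFrame
    lambdas: np.ndarray
    r2: np.ndarray
    minority_size: int
    week_labels: list
    master_seed: int
    degeneracies: dict[str, int] = field(default_factory=dict)
    removal_logs: dict[str, pd.DataFrame] = field(default_factory=dict)
    cv_k: int = 20
    n_lambda: int = 100

    @property
    def B(self) -> int:
        return len(self.coefs)

    @property
    def columns(self) -> list[str]:
        return list(self.coefs.columns)

    def to_csv(self, path) -> None:
        out = self.coefs.copy()
        out["lambda_"] = self.lambdas
        out["r2_"] = self.r2
        out.to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "B": self.B,
            "master_seed": self.master_seed,
            "cv_k": self.cv_k,
            "n_lambda": self.n_lambda,
            "minority_size": self.minority_size,
            "replicate_size": self.minority_size * len(self.week_labels),
            "week_labels": [int(w) for w in self.week_labels],
            "columns": self.columns,
            "degeneracies": self.degeneracies,
            "removed_near_zero_variance": self.removal_logs.get(
                "near_zero_variance", pd.DataFrame()
            )["column"].tolist()
            if "near_zero_variance" in self.removal_logs
            else [],
            "removed_correlated": self.removal_logs.get("correlated", pd.DataFrame())[
                "column"
            ].tolist()
            if "correlated" in self.removal_logs
            else [],
        }

    def save(self, csv_path, manifest_path) -> None:
        self.to_csv(csv_path)
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def read_ensemble(csv_path, manifest_path) -> BootstrapEnsemble:
    """Rebuild an ensemble from its CSV + manifest artifacts."""
    frame = pd.read_csv(csv_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    cols = man["columns"]
    missing = [c for c in cols + ["lambda_", "r2_"] if c not in frame.columns]
    if missing:
        raise ValidationError(f"ensemble file lacks columns: {missing}")
    return BootstrapEnsemble(
        coefs=frame[cols],
        lambdas=frame["lambda_"].to_numpy(),
        r2=frame["r2_"].to_numpy(),
        minority_size=man["minority_size"],
        week_labels=man["week_labels"],
        master_seed=man["master_seed"],
        degeneracies=man.get("degeneracies", {}),
        cv_k=man.get("cv_k", 20),
        n_lambda=man.get("n_lambda", 100),
    )


def filtered_columns(
    table: pd.DataFrame,
    schema: PredictorSchema,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
    corr_threshold: float = 0.9,
) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Apply both pre-model filters once, on the full table.

    Returns the retained design columns (time + mains + interactions) and
    the per-filter removal logs.  Running the filters globally — rather than
    inside each replicate — keeps the coefficient set identical across
    replicates so the ensemble aligns by name.

    The near-zero-variance screen targets degenerate *predictors*, so it
    runs on the encoded main-effect columns before interactions are built
    (a binary-by-time product is mostly zeros by construction, which says
    nothing about the predictor); the correlation filter runs after
    interaction construction, on the full column set.
    """
    design, nzv_log = filter_near_zero_variance(
        encode_design(table, schema), freq_ratio_cut, unique_pct_cut
    )
    design = add_time_interactions(design)
    design, corr_log = filter_correlated(design, corr_threshold)
    return design.columns, {"near_zero_variance": nzv_log, "correlated": corr_log}


def run_bootstrap(
    table: pd.DataFrame,
    schema: PredictorSchema,
    B: int = 1000,
    master_seed: int = 0,
    cv_k: int = 20,
    n_lambda: int = 100,
    keep_columns: list[str] | None = None,
    eps_scale: float = 1e-3,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
    corr_threshold: float = 0.9,
) -> BootstrapEnsemble:
    """Run the full B-replicate balanced bootstrap and collect draws.

    Per replicate b (child seed spawned deterministically from
    ``master_seed``): balanced down-sample -> encode + interactions ->
    per-replicate standardization -> penalty grid + k-fold CV -> refit at
    the selected penalty -> record the original-scale coefficients.
    Columns that a replicate's resample makes constant are dropped from that
    replicate's fit, recorded as a zero draw, and counted in the degeneracy
    log, keeping B fixed.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    removal_logs: dict[str, pd.DataFrame] = {}
    if keep_columns is None:
        keep_columns, removal_logs = filtered_columns(
            table, schema, freq_ratio_cut, unique_pct_cut, corr_threshold
        )
    weeks = sorted(table["week"].unique())
    minority = int(table["week"].value_counts().min())

    children = np.random.SeedSequence(master_seed).spawn(B)
    draws = np.zeros((B, len(keep_columns)))
    lambdas = np.empty(B)
    r2 = np.empty(B)
    degeneracies: dict[str, int] = {}
    for b in range(B):
        rng = np.random.default_rng(children[b])
        sample = balanced_downsample(table, rng)
        design = add_time_interactions(encode_design(sample, schema))
        design = design.subset(keep_columns)
        sds = design.X.to_numpy().std(axis=0)
        degenerate = [c for c, s in zip(keep_columns, sds) if s == 0]
        for c in degenerate:
            degeneracies[c] = degeneracies.get(c, 0) + 1
        live = [c for c in keep_columns if c not in degenerate]
        design = design.subset(live)
        grid = lambda_grid(standardize(design), n_lambda, eps_scale)
        fold_seed = rng.integers(2**31)
        result = cv_select_lambda(design, grid, k=cv_k, seed=fold_seed)
        aligned = result.fit.coef.reindex(keep_columns, fill_value=0.0)
        draws[b] = aligned.to_numpy()
        lambdas[b] = result.best_lambda
        r2[b] = result.fit.r2_train
    return BootstrapEnsemble(
        coefs=pd.DataFrame(draws, columns=keep_columns),
        lambdas=lambdas,
        r2=r2,
        minority_size=minority,
        week_labels=[w for w in weeks],
        master_seed=master_seed,
        degeneracies=degeneracies,
        removal_logs=removal_logs,
        cv_k=cv_k,
        n_lambda=n_lambda,
    )
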