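"""Synthetic repeated cross-sectional lockdown survey generator.

Emulates the statistical structure the inference pipeline assumes: heavily
week-imbalanced respondent arrivals (weekly proportions default to the
published arrival counts of the 2020 French lockdown survey), a battery of
binary / categorical / Likert / continuous predictors drawn independently
from configurable marginals, and a bounded integer well-being outcome
generated by a linear model with known main effects and linear-in-time
interaction effects:

    y = intercept + sum_j b_j x_j + sum_j g_j x_j t + b_t t + eps,
    eps ~ Normal(0, noise_sd),

rounded to the nearest integer and clipped to the WEMWBS range [14, 70].
Because the injected effects are known, every downstream stage (encoding,
filtering, ridge, bootstrap, inference) can be tested for recovery.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import margins
from .exceptions import ConfigurationError
from .preprocess import (
    TIME_COLUMN,
    Predictor,
    PredictorSchema,
    WEMWBS_MAX,
    WEMWBS_MIN,
    encode_predictors,
)

#: Survey launch date (day 0 of the days-since-launch clock).
LAUNCH_DATE = _dt.date(2020, 3, 25)


@dataclass(frozen=True)
class PredictorSim:
    """Marginal distribution of one raw predictor.

    binary:      ``probs = (p_yes,)`` over levels ("no", "yes") or custom pair
    categorical: ``probs`` over ``levels`` (first level = reference)
    likert:      ``probs`` over the integer range (uniform if omitted)
    continuous:  uniform on ``(low, high)``
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ("no", "yes")
    probs: tuple[float, ...] | None = None
    likert_range: tuple[int, int] = (1, 5)
    low: float = 16.0
    high: float = 75.0

    def schema_predictor(self) -> Predictor:
        return Predictor(
            name=self.name, kind=self.kind, levels=self.levels,
            likert_range=self.likert_range,
        )

    def draw(self, n: int, rng: np.random.Generator):
        if self.kind == "binary":
            p = self.probs[0] if self.probs else 0.5
            return np.where(rng.random(n) < p, self.levels[1], self.levels[0])
        if self.kind == "categorical":
            probs = self.probs or tuple(1 / len(self.levels) for _ in self.levels)
            if len(probs) != len(self.levels):
                raise ConfigurationError(
                    f"{self.name!r}: {len(probs)} probabilities for "
                    f"{len(self.levels)} levels"
                )
            return rng.choice(np.asarray(self.levels), size=n, p=np.asarray(probs))
        if self.kind == "likert":
            lo, hi = self.likert_range
            values = np.arange(lo, hi + 1)
            probs = self.probs or tuple(1 / len(values) for _ in values)
            return rng.choice(values, size=n, p=np.asarray(probs))
        if self.kind == "continuous":
            return rng.uniform(self.low, self.high, size=n)
        raise ConfigurationError(f"unknown predictor kind {self.kind!r}")


def default_week_day_ranges(week_labels) -> dict[int, tuple[int, int]]:
    """Week w of lockdown spans days 7*(w-2) .. 7*(w-2)+6 since launch."""
    return {int(w): (7 * (int(w) - 2), 7 * (int(w) - 2) + 6) for w in week_labels}


def default_predictors() -> tuple[PredictorSim, ...]:
    """A ~20-variable battery with published overall marginals where known."""
    L = lambda name, probs=None: PredictorSim(name, "likert", probs=probs)  # noqa: E731
    B = lambda name, p: PredictorSim(name, "binary", probs=(p,))  # noqa: E731
    return (
        PredictorSim("sex", "categorical", ("male", "female"), (0.233, 0.767)),
        PredictorSim("age", "continuous", low=16, high=75),
        B("relationship", 0.639),
        PredictorSim(
            "education", "categorical",
            ("up to 12y", "12-14y", "14y-bachelor", "bachelor-masters", "masters+"),
            (0.166, 0.134, 0.211, 0.385, 0.104),
        ),
        B("outdoor_space", 0.829),
        PredictorSim(
            "work", "categorical",
            ("employee", "self-employed", "student", "retired", "other"),
            (0.663, 0.103, 0.115, 0.076, 0.043),
        ),
        B("prev_lockdown", 0.203),
        B("chronic_illness", 0.161),
        PredictorSim(
            "psych_history", "categorical",
            ("none", "past", "current"), (0.748, 0.141, 0.111),
        ),
        PredictorSim(
            "living_area", "categorical",
            ("urban", "semi-rural", "rural"), (0.541, 0.218, 0.241),
        ),
        B("pet", 0.462),
        L("phone_contacts", (0.10, 0.20, 0.30, 0.25, 0.15)),
        L("face_contacts", (0.35, 0.30, 0.20, 0.10, 0.05)),
        L("agree_lockdown", (0.05, 0.10, 0.20, 0.35, 0.30)),
        L("info_satisfaction", (0.10, 0.20, 0.30, 0.25, 0.15)),
        L("worry_ppe", (0.25, 0.25, 0.20, 0.18, 0.12)),
        L("worry_products", (0.30, 0.25, 0.20, 0.15, 0.10)),
        L("worry_precarious", (0.40, 0.22, 0.16, 0.12, 0.10)),
        B("support_home", 0.60),
        B("support_neighbors", 0.40),
        B("cope_favorable", 0.50),
        B("cope_resilience", 0.50),
        B("collective_action", 0.25),
    )


def default_main_effects() -> dict[str, float]:
    """Default injected effects, emulating the magnitudes the field reports.

    Keys are encoded design-column names; values are score units per
    predictor unit (per day for the time column).
    """
    return {
        TIME_COLUMN: -0.030,
        "age": 0.071,
        "psych_history[current]": -2.26,
        "psych_history[past]": -1.27,
        "phone_contacts": 0.36,
        "worry_precarious": -0.57,
        "worry_products": -0.37,
        "info_satisfaction": 0.60,
        "agree_lockdown": 0.60,
        "cope_resilience": 1.35,
        "cope_favorable": 1.14,
    }


def default_interaction_effects() -> dict[str, float]:
    """Default time-interaction effects, score units per predictor unit per day."""
    return {
        "psych_history[current]": -0.037,
        "worry_ppe": -0.009,
        "cope_favorable": 0.029,
        "support_neighbors": 0.024,
        "collective_action": 0.023,
    }


@dataclass
class SimulationConfig:
    n_total: int = 18_957
    week_labels: tuple[int, ...] = tuple(sorted(margins.WEEK_COUNTS))
    week_proportions: tuple[float, ...] = tuple(
        margins.week_proportions()[w] for w in sorted(margins.WEEK_COUNTS)
    )
    week_day_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: default_week_day_ranges(sorted(margins.WEEK_COUNTS))
    )
    predictors: tuple[PredictorSim, ...] = field(default_factory=default_predictors)
    true_intercept: float = 43.0
    true_main_effects: dict[str, float] = field(default_factory=default_main_effects)
    true_interaction_effects: dict[str, float] = field(
        default_factory=default_interaction_effects
    )
    noise_sd: float = 7.0
    seed: int = 0

    def schema(self) -> PredictorSchema:
        return PredictorSchema(tuple(p.schema_predictor() for p in self.predictors))

    def validate(self) -> None:
        props = np.asarray(self.week_proportions, dtype=float)
        if len(props) != len(self.week_labels):
            raise ConfigurationError("week_proportions length != week_labels length")
        if abs(props.sum() - 1.0) > 1e-12 or np.any(props <= 0):
            raise ConfigurationError(
                "week_proportions must be positive and sum to 1"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_total < len(self.week_labels):
            raise ConfigurationError("n_total must be >= number of weeks")
        for w in self.week_labels:
            if w not in self.week_day_ranges:
                raise ConfigurationError(f"no day range for week {w}")
        known = set(self.schema().main_columns()) | {TIME_COLUMN}
        for key in self.true_main_effects:
            if key not in known:
                raise ConfigurationError(
                    f"main-effect key {key!r} matches no encoded column"
                )
        for key in self.true_interaction_effects:
            if key not in known - {TIME_COLUMN}:
                raise ConfigurationError(
                    f"interaction-effect key {key!r} matches no encoded column"
                )

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["week_day_ranges"] = {
            str(k): list(v) for k, v in self.week_day_ranges.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)


def generate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Draw one synthetic respondent table, fully reproducible from the seed.

    Columns: ``respondent_id``, ``response_date`` (ISO-8601), ``week``,
    ``days`` (days since survey launch, drawn uniformly within the week's
    day range), the raw predictors, and the integer ``wemwbs`` outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    weeks = np.asarray(config.week_labels)
    week = rng.choice(weeks, size=n, p=np.asarray(config.week_proportions))
    lo = np.asarray([config.week_day_ranges[int(w)][0] for w in week])
    hi = np.asarray([config.week_day_ranges[int(w)][1] for w in week])
    days = rng.integers(lo, hi + 1)

    table = pd.DataFrame({
        "respondent_id": np.arange(n),
        "week": week,
        TIME_COLUMN: days,
    })
    for p in config.predictors:
        table[p.name] = p.draw(n, rng)
    table["response_date"] = [
        (LAUNCH_DATE + _dt.timedelta(days=int(d))).isoformat() for d in days
    ]

    X, _ = encode_predictors(table, config.schema())
    y = np.full(n, config.true_intercept, dtype=float)
    t = days.astype(float)
    for key, effect in config.true_main_effects.items():
        y += effect * (t if key == TIME_COLUMN else X[key].to_numpy())
    for key, effect in config.true_interaction_effects.items():
        y += effect * X[key].to_numpy() * t
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=n)
    table["wemwbs"] = np.clip(np.rint(y), WEMWBS_MIN, WEMWBS_MAX).astype(int)
    cols = ["respondent_id", "response_date", "week", TIME_COLUMN] + [
        p.name for p in config.predictors
    ] + ["wemwbs"]
    return table[cols]


def truth_table(config: SimulationConfig, schema: PredictorSchema) -> pd.DataFrame:
    """Injected effects aligned to the encoded column names, zero-filled.

    Indexed by design column (time column first, then mains), with columns
    ``main`` (score units per predictor unit; per day for the time row) and
    ``interaction`` (score units per predictor unit per day; zero for the
    time row, which does not interact with itself).
    """
    cols = [TIME_COLUMN] + schema.main_columns()
    config_cols = set(config.schema().main_columns()) | {TIME_COLUMN}
    unmatched = sorted(set(cols) ^ config_cols)
    if unmatched:
        raise ConfigurationError(
            f"schema/config column mismatch; unmatched: {unmatched}"
        )
    out = pd.DataFrame(0.0, index=pd.Index(cols, name="column"),
                       columns=["main", "interaction"])
    for key, effect in config.true_main_effects.items():
        out.loc[key, "main"] = effect
    for key, effect in config.true_interaction_effects.items():
        out.loc[key, "interaction"] = effect
    return out


def truth_vector(truth: pd.DataFrame, design_columns) -> pd.Series:
    """Flatten a truth table onto full design columns (mains + interactions).

    ``<col>:days`` entries take the interaction effect; everything else the
    main effect.  Columns dropped by filtering can simply be omitted from
    ``design_columns``.
    """
    values = {}
    for c in design_columns:
        if c.endswith(f":{TIME_COLUMN}"):
            base = c[: -len(TIME_COLUMN) - 1]
            values[c] = float(truth.loc[base, "interaction"])
        else:
            values[c] = float(truth.loc[c, "main"])
    return pd.Series(values)
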