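"""Published marginal counts from the 2020 French lockdown well-being survey.

These are the printed descriptive margins of the repeated cross-sectional
survey this pipeline models: respondent arrivals per lockdown week (heavily
imbalanced, week 2 dominating), and per-week counts for a few categorical
characteristics.  They serve two purposes: the synthetic-data generator uses
them as default marginals, and descriptive-statistics code can be exercised
against a table that reproduces them exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Respondents arriving in each lockdown week (weeks 2-8 after lockdown start).
WEEK_COUNTS: dict[int, int] = {
    2: 11_194,
    3: 5_008,
    4: 629,
    5: 1_259,
    6: 394,
    7: 337,
    8: 136,
}

#: Per-week counts for selected categorical variables, keyed variable ->
#: level -> tuple of counts ordered by week (2..8).
CATEGORY_COUNTS: dict[str, dict[str, tuple[int, ...]]] = {
    "sex": {
        "male": (2_518, 1_238, 160, 297, 96, 68, 36),
        "female": (8_676, 3_770, 469, 962, 298, 269, 100),
    },
    "work": {
        "employee": (7_388, 3_415, 384, 840, 260, 212, 76),
        "self-employed": (1_165, 536, 65, 117, 25, 29, 16),
        "student": (1_390, 441, 70, 156, 65, 40, 21),
        "retired": (763, 446, 74, 94, 21, 26, 11),
        "other": (488, 170, 36, 52, 23, 30, 12),
    },
    "psych_history": {
        "none": (8_386, 3_850, 448, 898, 289, 216, 86),
        "past": (1_602, 658, 101, 199, 49, 48, 21),
        "current": (1_206, 500, 80, 162, 56, 73, 29),
    },
}


def total_sample_size() -> int:
    """Total respondents, i.e. the sum of the weekly arrival counts."""
    return int(sum(WEEK_COUNTS.values()))


def week_proportions() -> dict[int, float]:
    """Weekly arrival counts normalised to proportions."""
    n = total_sample_size()
    return {w: c / n for w, c in WEEK_COUNTS.items()}


def margins_fixture_table(variables: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Expand the printed per-week category counts into a respondent table.

    Each variable's per-week level counts are laid out independently (the
    joint distribution is unknown and irrelevant for marginal summaries), so
    the resulting table reproduces every printed count and percentage exactly.
    A placeholder well-being score column is included so downstream code that
    expects an outcome column can run.
    """
    if variables is None:
        variables = tuple(CATEGORY_COUNTS)
    unknown = [v for v in variables if v not in CATEGORY_COUNTS]
    if unknown:
        raise KeyError(f"no published margins for variables: {unknown}")

    weeks = sorted(WEEK_COUNTS)
    columns: dict[str, np.ndarray] = {
        "week": np.repeat(weeks, [WEEK_COUNTS[w] for w in weeks])
    }
    for var in variables:
        per_week: list[np.ndarray] = []
        for i, w in enumerate(weeks):
            levels = list(CATEGORY_COUNTS[var])
            counts = [CATEGORY_COUNTS[var][lv][i] for lv in levels]
            if sum(counts) != WEEK_COUNTS[w]:
                raise ValueError(
                    f"margins for {var!r} in week {w} sum to {sum(counts)}, "
                    f"expected {WEEK_COUNTS[w]}"
                )
            per_week.append(np.repeat(levels, counts))
        columns[var] = np.concatenate(per_week)
    out = pd.DataFrame(columns)
    out["wemwbs"] = 49  # placeholder outcome; margins tables are count-only
    return out
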