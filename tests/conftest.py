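import numpy as np
import pandas as pd
import pytest

from lockwell.preprocess import DesignMatrix, design_from_arrays


def prestandardized(X, y, columns=None) -> DesignMatrix:
    """Wrap arrays as a design with identity centering/scaling.

    Lets numerical oracles check the penalized solve on the matrix exactly
    as given, without the pipeline's own standardization entering.
    """
    d = design_from_arrays(X, y, columns=columns)
    d.meta["center"] = 0.0
    d.meta["scale"] = 1.0
    d.standardized = True
    d.y_center = 0.0
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_survey():
    """Tiny two-week survey table with one binary and one Likert predictor."""
    rng = np.random.default_rng(5)
    n = 400
    week = np.where(rng.random(n) < 0.7, 2, 3)
    days = np.where(week == 2, rng.integers(0, 7, n), rng.integers(7, 14, n))
    return pd.DataFrame({
        "week": week,
        "days": days,
        "flag": np.where(rng.random(n) < 0.5, "yes", "no"),
        "mood": rng.integers(1, 6, n),
        "wemwbs": rng.integers(30, 60, n),
    })
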