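"""Categorical risk-factor coding shared by the generator and the survival fits.

Factors are the established risk factors the incidence models adjust for:
smoking status, diabetes, alcohol frequency, deprivation tertile, education,
and sex-specific tertiles of BMI and height, with HRT use and parity as
optional women-only factors.  Each factor is coded as baseline-referenced
indicator columns; the baseline levels are: never smoked, no diabetes,
sometimes drink, min deprivation, degree-level education, mid BMI tertile,
min height tertile, no HRT, no children.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FACTOR_LEVELS", "FACTOR_BASELINE", "DEFAULT_FACTORS", "design_matrix", "design_column_names"]

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "smoking": ("never", "previous", "current"),
    "diabetes": ("no", "yes"),
    "alcohol": ("rarely", "sometimes", "regularly"),
    "deprivation": ("min", "mid", "max"),
    "education": ("degree", "post16", "age16"),
    "bmi": ("min", "mid", "max"),
    "height": ("min", "mid", "max"),
    "hrt": ("no", "yes"),
    "parity": ("none", "any"),
}

FACTOR_BASELINE: dict[str, str] = {
    "smoking": "never",
    "diabetes": "no",
    "alcohol": "sometimes",
    "deprivation": "min",
    "education": "degree",
    "bmi": "mid",
    "height": "min",
    "hrt": "no",
    "parity": "none",
}

#: the 7 risk factors adjusted for in both sexes (women's models may add hrt, parity)
DEFAULT_FACTORS: tuple[str, ...] = (
    "smoking",
    "diabetes",
    "alcohol",
    "deprivation",
    "education",
    "bmi",
    "height",
)


def design_column_names(factors) -> list[str]:
    """Column names ``factor[level]`` for every non-baseline level, in order."""
    names: list[str] = []
    for f in factors:
        if f not in FACTOR_LEVELS:
            raise KeyError(f"unknown risk factor {f!r}; known: {sorted(FACTOR_LEVELS)}")
        for lev in FACTOR_LEVELS[f]:
            if lev != FACTOR_BASELINE[f]:
                names.append(f"{f}[{lev}]")
    return names


def design_matrix(cohort: pd.DataFrame, factors) -> tuple[np.ndarray, list[str]]:
    """Indicator design matrix over the requested factors.

    Parameters
    ----------
    cohort : DataFrame
        One row per individual with one column per factor holding level labels.
    factors : sequence of str
        Factor names (keys of :data:`FACTOR_LEVELS`).

    Returns
    -------
    (X, names)
        ``X`` is (n, d) float with one column per non-baseline level.
    """
    cols: list[np.ndarray] = []
    names = design_column_names(factors)
    for f in factors:
        levels = FACTOR_LEVELS[f]
        vals = cohort[f].to_numpy()
        unknown = np.setdiff1d(pd.unique(vals), np.asarray(levels, dtype=object))
        if unknown.size:
            raise ValueError(f"factor {f!r} has unknown levels {list(unknown)}; expected {levels}")
        for lev in levels:
            if lev != FACTOR_BASELINE[f]:
                cols.append((vals == lev).astype(float))
    if not cols:
        return np.empty((len(cohort), 0)), names
    return np.column_stack(cols), names
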