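"""Cross-disease synthesis: the excess-risk multiplier and its diagnostics.

Each retained disease contributes one point (expected count, observed count).
Diseases whose observed first-in-chapter count differs from the prediction by
more than 4 standard deviations are excluded as outliers (under the null
~99.9% of well-modeled diseases fall within 4 sd).  A least-squares line
through the origin then estimates the excess-risk multiplier:

    b = sum x y / sum x^2,    s.e.(b) = s / sqrt(sum x^2),
    s^2 = sum (y - b x)^2 / (n - 1),
    R^2 = 1 - sum (y - b x)^2 / sum y^2   (uncentered, no-intercept form),

with a prediction interval y(x0) +/- t_{n-1} s sqrt(1 + x0^2 / sum x^2).
Equality of two slopes (or of any two MLEs with reported confidence
intervals) is tested with (b1 - b2) ~ N(0, se1^2 + se2^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiseasePoint",
    "SlopeEstimate",
    "exclude_outliers",
    "fit_through_origin",
    "slope_equality_test",
    "se_from_ci",
    "chapter_ratios",
]


@dataclass
class DiseasePoint:
    """One disease's observed-vs-expected comparison point."""

    disease_id: str
    chapter: str
    expected: float
    sd_expected: float
    observed_all: int
    observed_fic: int
    included: bool = True
    z_fic: float = np.nan
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.sd_expected < 0:
            raise ValueError("sd_expected must be >= 0")


@dataclass(frozen=True)
class SlopeEstimate:
    """Through-origin slope: the observed/expected excess multiplier."""

    coef: float
    se: float
    ci95: tuple[float, float]
    r_squared: float
    n_points: int
    resid_scale: float  # s, the residual standard deviation
    sum_x2: float

    def predict_interval(self, x0, level: float = 0.95) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fitted value and prediction band at expected count(s) ``x0``."""
        x0 = np.asarray(x0, dtype=float)
        yhat = self.coef * x0
        tq = stats.t.ppf(0.5 + level / 2.0, df=self.n_points - 1)
        half = tq * self.resid_scale * np.sqrt(1.0 + x0**2 / self.sum_x2)
        return yhat, yhat - half, yhat + half


def exclude_outliers(points: list[DiseasePoint], threshold_sd: float = 4.0) -> list[DiseasePoint]:
    """Flag points whose FIC count is > ``threshold_sd`` sd from the prediction.

    Mutates and returns the same points with ``included``, ``z_fic`` and
    ``exclusion_reason`` set.  A point with zero predicted sd is excluded
    (with its own reason) unless observed equals expected exactly.
    """
    for pt in points:
        diff = pt.observed_fic - pt.expected
        if pt.sd_expected == 0.0:
            if diff == 0.0:
                pt.included, pt.z_fic = True, 0.0
            else:
                pt.included, pt.z_fic = False, np.inf
                pt.exclusion_reason = "zero_sd"
            continue
        pt.z_fic = diff / pt.sd_expected
        pt.included = bool(abs(pt.z_fic) <= threshold_sd)
        pt.exclusion_reason = "" if pt.included else "outlier_4sd"
    return points


def fit_through_origin(points, y_series: str = "all", z: float = 1.96) -> SlopeEstimate:
    """OLS through the origin of observed on expected counts.

    ``points`` is a list of :class:`DiseasePoint` (only included ones are
    used) or a pair of arrays ``(x, y)``.  ``y_series`` selects the observed
    series ("all" total cases or "fic" first-in-chapter cases).
    """
    if isinstance(points, tuple):
        x, y = (np.asarray(v, dtype=float) for v in points)
    else:
        kept = [pt for pt in points if pt.included]
        x = np.array([pt.expected for pt in kept], dtype=float)
        y = np.array([pt.observed_all if y_series == "all" else pt.observed_fic
                      for pt in kept], dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points for a through-origin fit, got {n}")
    sum_x2 = float(np.sum(x * x))
    if sum_x2 == 0.0:
        raise ValueError("all expected counts are zero")
    coef = float(np.sum(x * y) / sum_x2)
    resid = y - coef * x
    s2 = float(np.sum(resid**2) / (n - 1))
    se = float(np.sqrt(s2 / sum_x2))
    sum_y2 = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid**2)) / sum_y2 if sum_y2 > 0 else np.nan
    return SlopeEstimate(coef=coef, se=se, ci95=(coef - z * se, coef + z * se),
                         r_squared=r2, n_points=n, resid_scale=float(np.sqrt(s2)),
                         sum_x2=sum_x2)


def se_from_ci(ci95: tuple[float, float]) -> float:
    """Recover a standard error from a reported 95% interval: (high - low)/3.92."""
    lo, hi = ci95
    if not hi > lo:
        raise ValueError(f"degenerate confidence interval {ci95}")
    return (hi - lo) / 3.92


def slope_equality_test(a: SlopeEstimate | tuple, b: SlopeEstimate | tuple,
                        z: float = 1.96) -> tuple[float, bool]:
    """Test equality of two estimates: (b1 - b2) ~ N(0, se1^2 + se2^2).

    Accepts :class:`SlopeEstimate` objects or ``(coef, (lo, hi))`` pairs of
    literature values (s.e. recovered from the printed interval).  Returns
    the z-statistic and whether |z| exceeds the 0.05-level threshold.
    """
    def _coef_se(est):
        if isinstance(est, SlopeEstimate):
            return est.coef, se_from_ci(est.ci95)
        coef, ci = est
        return float(coef), se_from_ci(tuple(ci))

    ca, sa = _coef_se(a)
    cb, sb = _coef_se(b)
    zstat = (ca - cb) / np.sqrt(sa**2 + sb**2)
    return float(zstat), bool(abs(zstat) > z)


def chapter_ratios(points: list[DiseasePoint], y_series: str = "all") -> pd.DataFrame:
    """Per-chapter excess ratios (the chapter-aggregation view).

    For each chapter: the mean over its included diseases of
    observed/expected, the pooled ratio sum(observed)/sum(expected), and the
    number of diseases N.  Chapters with no included diseases are omitted.
    """
    rows = []
    kept = [pt for pt in points if pt.included and pt.expected > 0]
    for chapter in sorted({pt.chapter for pt in kept}):
        pts = [pt for pt in kept if pt.chapter == chapter]
        obs = np.array([pt.observed_all if y_series == "all" else pt.observed_fic
                        for pt in pts], dtype=float)
        exp = np.array([pt.expected for pt in pts], dtype=float)
        rows.append({
            "chapter": chapter,
            "n_diseases": len(pts),
            "mean_ratio": float(np.mean(obs / exp)),
            "pooled_ratio": float(obs.sum() / exp.sum()),
        })
    return pd.DataFrame(rows, columns=["chapter", "n_diseases", "mean_ratio", "pooled_ratio"])
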