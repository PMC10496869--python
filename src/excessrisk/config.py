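"""Run and simulation configuration (pydantic models, JSON round-trippable).

Defaults reproduce the study conventions: QC thresholds s.e.(x)/x > 0.5 and
sum sigma^2 / N >= 0.05, the 4-sd outlier rule, and z = 1.96 intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .design import DEFAULT_FACTORS

__all__ = ["QCThresholds", "RunConfig", "SimConfig", "DEFAULT_SUBGROUPS"]

#: subgroup definitions as pandas query strings over the cohort table
#: (None = everyone).  "Smoker" means current smoker.
DEFAULT_SUBGROUPS: dict[str, Optional[str]] = {
    "Everyone": None,
    "Nonsmoker, mid-BMI": "smoking == 'never' and bmi == 'mid'",
    "Smoker, mid-BMI": "smoking == 'current' and bmi == 'mid'",
    "Nonsmoker, max-BMI": "smoking == 'never' and bmi == 'max'",
    "Smoker, max-BMI": "smoking == 'current' and bmi == 'max'",
}


class QCThresholds(BaseModel):
    """Quality-control and exclusion thresholds (study defaults)."""

    se_ratio: float = Field(0.5, gt=0, description="max s.e.(x)/x for x in {k, L}")
    sum_sigma2_ratio: float = Field(0.05, gt=0, description="max sum_i sigma_ij^2 / N_j")
    outlier_sd: float = Field(4.0, gt=0, description="|observed FIC - expected| exclusion, in sd")
    z: float = Field(1.96, gt=0, description="normal quantile for 95% intervals")


class RunConfig(BaseModel):
    """Configuration of the observed-vs-expected analysis pipeline."""

    factors: list[str] = Field(default_factory=lambda: list(DEFAULT_FACTORS))
    qc: QCThresholds = Field(default_factory=QCThresholds)
    #: keep individuals with pre-study cardiovascular disease (sensitivity analysis)
    keep_prior_cvd: bool = False
    #: keep individuals with pre-study cancer (not a study convention; for experiments)
    keep_prior_cancer: bool = False
    #: which events are treated as model-fitting events / when fit records are
    #: censored: "any" censors at the first onset of any disease (fit estimates
    #: disease-free incidence), "chapter" at the first same-chapter onset
    #: (first-in-chapter incidence), "none" at end of follow-up only.
    conditioning: Literal["any", "chapter", "none"] = "any"
    #: observed series regressed on expected counts for the headline slope
    y_series: Literal["all", "fic"] = "all"
    #: diseases with fewer fitting events than this are dropped before fitting
    min_events: int = Field(25, ge=1)
    #: minimum retained points for a through-origin fit
    min_points: int = Field(2, ge=2)
    subgroups: dict[str, Optional[str]] = Field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


class SimConfig(BaseModel):
    """Configuration of the synthetic cohort and event generator.

    The defaults define the emulated study conditions: 50,000 individuals
    entering at ages 40-70 with 10 years of follow-up, the categorical risk
    factors the incidence models adjust for, 20 diseases with Weibull onset
    hazards (shape 4-6; the scale is solved from a small cumulative hazard at
    the oldest entry age, so per-individual probabilities stay well below 1
    and the plug-in approximations the method relies on hold), and a
    multiplicative hazard inflation m = 1.5 applied to all of an individual's
    remaining diseases after their first onset.
    """

    n_individuals: int = Field(50_000, gt=0)
    n_diseases: int = Field(20, gt=0)
    entry_age_range: tuple[float, float] = (40.0, 70.0)
    followup_years: float = Field(10.0, gt=0)
    female_fraction: float = Field(0.5, ge=0, le=1)
    #: factors drawn for each individual; prevalences per level (same order as
    #: design.FACTOR_LEVELS), uniform over levels if not listed here
    factors: list[str] = Field(default_factory=lambda: list(DEFAULT_FACTORS))
    prevalences: dict[str, list[float]] = Field(default_factory=lambda: {
        "smoking": [0.55, 0.35, 0.10],
        "diabetes": [0.95, 0.05],
        "alcohol": [0.25, 0.45, 0.30],
    })
    #: per-disease Weibull shape drawn uniformly from this range
    k_range: tuple[float, float] = (4.0, 6.0)
    #: per-disease rarity: cumulative baseline hazard at the oldest entry age,
    #: drawn uniformly from this range; the scale L is solved from it so that
    #: every disease satisfies the p_ij << 1 regime the method assumes
    #: (S(entry) ~ 1, onsets concentrated in late life), whatever its shape
    cum_hazard_entry_range: tuple[float, float] = (0.002, 0.01)
    #: explicit scale range (years); overrides cum_hazard_entry_range when set
    L_range: Optional[tuple[float, float]] = None
    #: each disease receives this many nonzero covariate effects ...
    n_beta_per_disease: int = Field(3, ge=0)
    #: ... drawn N(0, beta_scale^2) on the log-rate scale
    beta_scale: float = Field(0.2, ge=0)
    #: ICD-10-style chapter labels assigned round-robin to diseases
    chapters: list[str] = Field(default_factory=lambda: ["II", "IV", "VI", "IX", "X", "XI", "XIII", "XIV"])
    #: hazard multiplier applied to all not-yet-onset diseases from the age of
    #: an individual's first disease onset (m = 1: independent diseases)
    prior_disease_multiplier: float = Field(1.5, ge=0)
    #: extra multiplicative factors on m for subgroups (pandas query -> factor)
    group_multipliers: dict[str, float] = Field(default_factory=dict)
    #: fractions flagged with pre-study cancer / serious CVD (excluded by default)
    prior_cancer_fraction: float = Field(0.03, ge=0, le=1)
    prior_cvd_fraction: float = Field(0.03, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self):
        for name in ("entry_age_range", "k_range", "cum_hazard_entry_range", "L_range"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        for f, prev in self.prevalences.items():
            if abs(sum(prev) - 1.0) > 1e-9 or min(prev) < 0:
                raise ValueError(f"prevalences for {f!r} must be a probability vector")
        return self

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A desk-scale configuration for quick experiments and tests."""
        base = dict(
            n_individuals=8_000,
            n_diseases=10,
            factors=["smoking", "bmi"],
            n_beta_per_disease=1,
            cum_hazard_entry_range=(0.004, 0.012),
            chapters=["II", "IX", "XI", "XIII", "XIV"],
        )
        base.update(overrides)
        return cls(**base)
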