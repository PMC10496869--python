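"""Seeded synthetic cohorts with a known prior-disease hazard multiplier.

The generator emulates the statistical structure the analysis assumes: a
cohort entering at ages 40-70 with ~10 years of follow-up, categorical risk
factors, per-disease Weibull onset hazards modified multiplicatively by the
covariates, and an excess-risk mechanism in which the hazards of all
not-yet-onset diseases are multiplied by a factor ``m`` from the age of an
individual's first disease onset.  With ``m = 1`` the diseases are exactly
independent, so every downstream stage can be calibrated against a known
null; with ``m = 0`` an individual can experience at most one disease.

Onset ages are drawn exactly by inversion of the (piecewise) cumulative
hazard: for disease *j* with cumulative hazard ``H_j(t) = e^{x'b}(t/L)^k``
an exponential deviate ``E`` gives a candidate age ``t0 = H_j^{-1}(E)``; the
first onset ``T1 = min_j t0_j`` is kept, and every other disease's onset is
re-solved from ``H_j(T1) + m (H_j(t) - H_j(T1)) = E``.  The age of each
individual's first onset is therefore unchanged by ``m`` -- the multiplier
only accelerates subsequent diseases (single changepoint at the first onset;
later onsets do not compound).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .design import FACTOR_LEVELS, design_column_names, design_matrix

__all__ = [
    "DiseaseTruth",
    "GroundTruth",
    "SyntheticStudy",
    "generate_disease_truths",
    "generate_cohort",
    "simulate_onsets",
    "make_study_inputs",
    "simulate_study",
]


@dataclass(frozen=True)
class DiseaseTruth:
    """True generative Weibull parameters for one disease."""

    disease_id: str
    chapter: str
    k: float
    L: float
    beta: np.ndarray  # over the design columns of the configured factors

    def to_dict(self) -> dict:
        return {
            "disease_id": self.disease_id, "chapter": self.chapter,
            "k": self.k, "L": self.L, "beta": np.asarray(self.beta).tolist(),
        }


@dataclass
class GroundTruth:
    """Everything the generator knows: parameters, multipliers, latent onsets."""

    truths: list[DiseaseTruth]
    multiplier: float
    group_multipliers: dict[str, float]
    onset_ages: np.ndarray  # (n_individuals, n_diseases), inf = never
    first_onset_age: np.ndarray  # (n_individuals,), inf = never
    seed: int

    def to_dict(self, include_onsets: bool = False) -> dict:
        d = {
            "diseases": [t.to_dict() for t in self.truths],
            "multiplier": self.multiplier,
            "group_multipliers": dict(self.group_multipliers),
            "seed": self.seed,
        }
        if include_onsets:
            d["onset_ages"] = np.where(np.isfinite(self.onset_ages), self.onset_ages, -1).tolist()
        return d


@dataclass
class SyntheticStudy:
    cohort: pd.DataFrame
    events: pd.DataFrame
    diseases: pd.DataFrame
    truth: GroundTruth


def generate_disease_truths(config: SimConfig, rng: np.random.Generator) -> list[DiseaseTruth]:
    """Draw per-disease (k, L, beta) and assign chapters round-robin."""
    names = design_column_names(config.factors)
    age_top = config.entry_age_range[1]
    truths = []
    for j in range(config.n_diseases):
        k = float(rng.uniform(*config.k_range))
        if config.L_range is not None:
            L = float(rng.uniform(*config.L_range))
        else:
            # solve (age_top / L)^k = eps: fixes disease rarity by entry age
            eps = float(rng.uniform(*config.cum_hazard_entry_range))
            L = float(age_top / eps ** (1.0 / k))
        beta = np.zeros(len(names))
        if names and config.n_beta_per_disease:
            idx = rng.choice(len(names), size=min(config.n_beta_per_disease, len(names)),
                             replace=False)
            beta[idx] = rng.normal(0.0, config.beta_scale, size=idx.size)
        chapter = config.chapters[j % len(config.chapters)]
        truths.append(DiseaseTruth(f"D{j + 1:02d}", chapter, k, L, beta))
    return truths


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Cohort table: id, sex, study window, risk factors, pre-study flags.

    Deterministic under ``config.seed``; entry ages are uniform over
    ``entry_age_range`` and exit age is entry + followup.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    entry = rng.uniform(*config.entry_age_range, size=n)
    cohort = pd.DataFrame({
        "individual_id": np.arange(1, n + 1),
        "sex": np.where(rng.random(n) < config.female_fraction, "F", "M"),
        "entry_age": np.round(entry, 3),
    })
    cohort["exit_age"] = np.round(cohort["entry_age"] + config.followup_years, 3)
    for f in config.factors:
        levels = FACTOR_LEVELS[f]
        prev = config.prevalences.get(f)
        p = np.asarray(prev, dtype=float) if prev is not None else np.full(len(levels), 1.0 / len(levels))
        if p.size != len(levels):
            raise ValueError(f"prevalences for {f!r} must have {len(levels)} entries")
        cohort[f] = rng.choice(levels, size=n, p=p)
    cohort["prior_cancer"] = rng.random(n) < config.prior_cancer_fraction
    cohort["prior_cvd"] = rng.random(n) < config.prior_cvd_fraction
    return cohort


def simulate_onsets(cohort: pd.DataFrame, truths: list[DiseaseTruth], config: SimConfig,
                    m: float | None = None, seed: int | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw event histories; returns the event table and the ground truth.

    The event table contains one row per (individual, disease) whose onset
    age is at or before the individual's exit age -- including onsets before
    study entry, which downstream risk-set construction must exclude (they
    play the role of pre-study reports).
    """
    if m is None:
        m = config.prior_disease_multiplier
    if m < 0:
        raise ValueError(f"prior-disease multiplier must be >= 0, got {m}")
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    n = len(cohort)
    J = len(truths)
    X, _ = design_matrix(cohort, config.factors)
    B = np.vstack([t.beta for t in truths]) if J else np.zeros((0, X.shape[1]))
    eta = X @ B.T if X.size else np.zeros((n, J))  # (n, J)
    k = np.array([t.k for t in truths])
    L = np.array([t.L for t in truths])

    E = rng.exponential(size=(n, J))
    # base-hazard candidate onset: t0 = L * (E / e^eta)^(1/k)
    t0 = L * (E / np.exp(eta)) ** (1.0 / k)
    T1 = t0.min(axis=1) if J else np.full(n, np.inf)

    m_i = np.full(n, float(m))
    for query, extra in config.group_multipliers.items():
        members = cohort.eval(query).to_numpy(dtype=bool)
        m_i[members] *= extra
    # piecewise cumulative hazard inversion for diseases after the first onset
    H_T1 = np.exp(eta) * (T1[:, None] / L) ** k
    with np.errstate(divide="ignore", invalid="ignore"):
        need = H_T1 + (E - H_T1) / m_i[:, None]
        t_adj = L * (need / np.exp(eta)) ** (1.0 / k)
    t_adj = np.where(m_i[:, None] > 0, t_adj, np.inf)
    later = t0 > T1[:, None]
    onset = np.where(later, t_adj, t0)

    exit_age = cohort["exit_age"].to_numpy(dtype=float)
    ids = cohort["individual_id"].to_numpy()
    ii, jj = np.nonzero(onset <= exit_age[:, None])
    events = pd.DataFrame({
        "individual_id": ids[ii],
        "disease_id": np.array([t.disease_id for t in truths], dtype=object)[jj],
        "onset_age": np.round(onset[ii, jj], 4),
        "primary": True,
    }).sort_values(["individual_id", "onset_age"], kind="mergesort").reset_index(drop=True)
    truth = GroundTruth(truths=truths, multiplier=float(m),
                        group_multipliers=dict(config.group_multipliers),
                        onset_ages=onset, first_onset_age=onset.min(axis=1) if J else T1,
                        seed=int(seed))
    return events, truth


def _synthetic_icd_codes(chapter: str, j: int) -> str:
    # fabricated ICD-10-style codes, one 3-character plus one 4-character
    letter = chr(ord("A") + (sum(ord(c) for c in chapter) % 20))
    return f"{letter}{j % 100:02d};{letter}{j % 100:02d}.0"


def disease_definition_table(truths: list[DiseaseTruth]) -> pd.DataFrame:
    return pd.DataFrame({
        "disease_id": [t.disease_id for t in truths],
        "chapter": [t.chapter for t in truths],
        "icd10_codes": [_synthetic_icd_codes(t.chapter, j) for j, t in enumerate(truths)],
    })


def simulate_study(config: SimConfig, m: float | None = None) -> SyntheticStudy:
    """Generate a full synthetic study: cohort, events, disease definitions."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    truths = generate_disease_truths(config, rng)
    cohort = generate_cohort(config)
    events, truth = simulate_onsets(cohort, truths, config, m=m)
    return SyntheticStudy(cohort=cohort, events=events,
                          diseases=disease_definition_table(truths), truth=truth)


def make_study_inputs(study: SyntheticStudy, outdir, include_onsets: bool = False) -> dict[str, Path]:
    """Write the three study-input tables plus the ground-truth document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "events": outdir / "events.csv",
        "diseases": outdir / "diseases.csv",
        "truth": outdir / "truth.json",
    }
    study.cohort.to_csv(paths["cohort"], index=False)
    study.events.to_csv(paths["events"], index=False)
    study.diseases.to_csv(paths["diseases"], index=False)
    paths["truth"].write_text(json.dumps(study.truth.to_dict(include_onsets=include_onsets), indent=2))
    return paths
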