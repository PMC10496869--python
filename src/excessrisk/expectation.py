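"""Per-disease pipeline stage: risk sets, expected counts, QC, observed counts.

For each disease the risk set is the sub-cohort eligible to experience it as
a new disease (no pre-study report of it; no disqualifying prior cancer or
serious cardiovascular disease unless a sensitivity flag retains them).  The
expected number of cases is the Poisson-Binomial mean over the risk set,

    E[N_j] = sum_i p_ij,   Var[N_j] = sum_i p_ij (1 - p_ij),

with p_ij the fitted probability of first onset inside individual i's study
window.  By the law of total variance the MLE uncertainty of the p_ij does
not inflate Var[N_j]; the delta-method variances sigma_ij^2 are instead
accumulated for quality control: a disease is excluded when s.e.(k)/k or
s.e.(L)/L exceeds 0.5, when any delta-method evaluation is non-numeric, or
when sum_i sigma_ij^2 / N_j >= 0.05.

Observed counts come in two series: all distinct individuals with the
disease as an in-window primary diagnosis ("all cases"), and those for whom
it was their first in-chapter primary diagnosis ("FIC").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .poisson_binomial import pb_interval
from .weibull import DiseaseModel, delta_method_variance, first_incidence_prob

__all__ = [
    "ExpectedCount",
    "ObservedCount",
    "QCResult",
    "build_risk_set",
    "build_fit_records",
    "expected_count",
    "qc_filter",
    "observed_counts",
    "disease_table_row",
]


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class ExpectedCount:
    """Expected count for one disease with its diagnostics."""

    disease_id: str
    expected: float
    variance: float
    ci95: tuple[float, float]
    sum_sigma2: float
    n_risk: int
    #: per-individual probabilities and delta-method variances, aligned with
    #: the risk-set individual ids (kept for subgroup re-aggregation)
    individual_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int), repr=False)
    p: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)
    sigma2: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)


@dataclass(frozen=True)
class ObservedCount:
    disease_id: str
    n_all: int
    n_fic: int

    def __post_init__(self):
        if not 0 <= self.n_fic <= self.n_all:
            raise ValueError(f"require 0 <= n_fic <= n_all, got {self.n_fic}, {self.n_all}")


def _pre_study_ids(events: pd.DataFrame, cohort: pd.DataFrame, disease_ids) -> np.ndarray:
    """Individuals with a report of any of ``disease_ids`` at or before entry."""
    ev = events[events["disease_id"].isin(disease_ids)]
    if ev.empty:
        return np.zeros(0, dtype=cohort["individual_id"].dtype)
    merged = ev.merge(cohort[["individual_id", "entry_age"]], on="individual_id", how="inner")
    pre = merged[merged["onset_age"] <= merged["entry_age"]]
    return pre["individual_id"].unique()


def build_risk_set(cohort: pd.DataFrame, events: pd.DataFrame, disease_id: str,
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Sub-cohort eligible to experience ``disease_id`` as a new disease.

    Excludes individuals with a pre-study report of this disease, and (unless
    the corresponding sensitivity flag is set) those with prior cancer or
    prior serious cardiovascular disease.
    """
    config = config or RunConfig()
    if disease_id not in set(events["disease_id"].unique()) and events.shape[0] > 0:
        # unknown ids are tolerated only if the disease simply has no events;
        # the caller validates ids against the disease-definition table
        pass
    mask = np.ones(len(cohort), dtype=bool)
    if not config.keep_prior_cancer and "prior_cancer" in cohort:
        mask &= ~cohort["prior_cancer"].to_numpy(dtype=bool)
    if not config.keep_prior_cvd and "prior_cvd" in cohort:
        mask &= ~cohort["prior_cvd"].to_numpy(dtype=bool)
    risk = cohort[mask]
    pre = _pre_study_ids(events, risk, [disease_id])
    return risk[~risk["individual_id"].isin(pre)].reset_index(drop=True)


def _first_in_window_onsets(events: pd.DataFrame, cohort: pd.DataFrame,
                            disease_ids) -> pd.DataFrame:
    """Earliest in-window onset age per (individual, disease) for the given diseases."""
    ev = events[events["disease_id"].isin(disease_ids)]
    if "primary" in ev:
        ev = ev[ev["primary"].astype(bool)]
    merged = ev.merge(cohort[["individual_id", "entry_age", "exit_age"]],
                      on="individual_id", how="inner")
    inwin = merged[(merged["onset_age"] > merged["entry_age"])
                   & (merged["onset_age"] <= merged["exit_age"])]
    return (inwin.groupby(["individual_id", "disease_id"], as_index=False)["onset_age"].min())


def build_fit_records(cohort: pd.DataFrame, events: pd.DataFrame, disease_id: str,
                      chapter_map: dict[str, str], config: RunConfig | None = None
                      ) -> pd.DataFrame:
    """Records for fitting the disease's Weibull model, with conditioning.

    Depending on ``config.conditioning`` the fitting events are restricted to
    onsets that are the individual's first overall ("any"), first within the
    disease's ICD-10 chapter ("chapter"), or simply the first onset of this
    disease ("none"); censoring ages are shortened accordingly, and
    individuals whose conditioning event pre-dates study entry contribute no
    records.  Returns columns individual_id, entry_age, exit_age (end of the
    fit record), event, event_age, plus the cohort's factor columns.
    """
    config = config or RunConfig()
    risk = build_risk_set(cohort, events, disease_id, config)
    if config.conditioning == "none":
        competitors = [disease_id]
    elif config.conditioning == "chapter":
        chapter = chapter_map[disease_id]
        competitors = [d for d, c in chapter_map.items() if c == chapter]
    else:  # "any"
        competitors = list(chapter_map.keys())
    # exclude individuals already past their conditioning event at entry
    if config.conditioning != "none":
        pre = _pre_study_ids(events, risk, competitors)
        risk = risk[~risk["individual_id"].isin(pre)]
    firsts = _first_in_window_onsets(events, risk, competitors)
    if firsts.empty:
        first_any = pd.DataFrame(columns=["individual_id", "onset_age", "disease_id"])
    else:
        first_any = firsts.loc[firsts.groupby("individual_id")["onset_age"].idxmin()]
    rec = risk.copy()
    rec = rec.merge(first_any.rename(columns={"onset_age": "first_onset",
                                              "disease_id": "first_disease"}),
                    on="individual_id", how="left")
    # ties at the exact same age: an onset of this disease at the minimum age
    # counts as an event even if another disease shares that age
    own = firsts[firsts["disease_id"] == disease_id].rename(
        columns={"onset_age": "own_onset"})[["individual_id", "own_onset"]]
    rec = rec.merge(own, on="individual_id", how="left")
    has_first = rec["first_onset"].notna()
    event = has_first & rec["own_onset"].notna() & (rec["own_onset"] <= rec["first_onset"])
    end = np.where(has_first, rec["first_onset"].to_numpy(dtype=float),
                   rec["exit_age"].to_numpy(dtype=float))
    out = rec[["individual_id", "entry_age", "exit_age"]].copy()
    out["event"] = event.to_numpy(dtype=bool)
    out["event_age"] = np.where(out["event"], rec["own_onset"].to_numpy(dtype=float), np.nan)
    out["end_age"] = end
    for f in config.factors:
        out[f] = rec[f].to_numpy()
    return out.reset_index(drop=True)


def expected_count(model: DiseaseModel, risk_set: pd.DataFrame, exog: np.ndarray | None = None,
                   z_level: float = 0.95) -> ExpectedCount:
    """Poisson-Binomial expected count over the risk set under ``model``.

    ``exog`` is the design matrix aligned with ``risk_set`` (None for a
    covariate-free model).  The per-individual probability uses the full
    study window (entry to exit age).
    """
    entry = risk_set["entry_age"].to_numpy(dtype=float)
    exit_ = risk_set["exit_age"].to_numpy(dtype=float)
    p = first_incidence_prob(model, entry, exit_, exog)
    sigma2 = delta_method_variance(model, entry, exit_, exog)
    ci = pb_interval(p, z_level)
    return ExpectedCount(
        disease_id=model.disease_id,
        expected=float(p.sum()),
        variance=float((p * (1 - p)).sum()),
        ci95=ci,
        sum_sigma2=float(np.nansum(sigma2)) if np.all(np.isfinite(sigma2)) else float("nan"),
        n_risk=len(risk_set),
        individual_ids=risk_set["individual_id"].to_numpy(),
        p=p,
        sigma2=sigma2,
    )


def qc_filter(model: DiseaseModel, ec: ExpectedCount, observed: ObservedCount,
              config: RunConfig | None = None) -> QCResult:
    """Study QC rules; returns pass/fail with reason codes.

    Reasons: ``not_converged``, ``se_ratio_k``, ``se_ratio_L``,
    ``delta_method_nonnumeric``, ``sum_sigma2_ratio``.
    The precision ratio uses the FIC observed count as N_j.
    """
    qc = (config or RunConfig()).qc
    reasons: list[str] = []
    if not model.converged:
        reasons.append("not_converged")
    if not np.isfinite(model.se_ratio_k) or model.se_ratio_k > qc.se_ratio:
        reasons.append("se_ratio_k")
    if not np.isfinite(model.se_ratio_L) or model.se_ratio_L > qc.se_ratio:
        reasons.append("se_ratio_L")
    if ec.sigma2.size and not np.all(np.isfinite(ec.sigma2)):
        reasons.append("delta_method_nonnumeric")
    elif observed.n_fic > 0 and np.isfinite(ec.sum_sigma2):
        if ec.sum_sigma2 / observed.n_fic >= qc.sum_sigma2_ratio:
            reasons.append("sum_sigma2_ratio")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def observed_counts(events: pd.DataFrame, cohort: pd.DataFrame, disease_id: str,
                    chapter_map: dict[str, str], risk_ids=None) -> ObservedCount:
    """Observed case counts for one disease (all cases and first-in-chapter).

    ``risk_ids`` restricts counting to the disease's risk set (pre-study
    cases and excluded individuals do not count); by default all individuals
    in ``cohort`` count.  Repeat admissions are deduplicated: an individual
    contributes at most once.  FIC ties (two same-chapter onsets at the same
    age) both count as FIC.
    """
    unknown = set(events["disease_id"].unique()) - set(chapter_map)
    if unknown:
        raise KeyError(f"events reference unknown disease ids: {sorted(unknown)[:5]}")
    missing = set(events["individual_id"].unique()) - set(cohort["individual_id"])
    if missing:
        raise KeyError(f"events reference unknown individuals: {sorted(missing)[:5]}")
    sub = cohort if risk_ids is None else cohort[cohort["individual_id"].isin(np.asarray(risk_ids))]
    chapter = chapter_map[disease_id]
    members = [d for d, c in chapter_map.items() if c == chapter]
    firsts = _first_in_window_onsets(events, sub, members)
    own = firsts[firsts["disease_id"] == disease_id]
    n_all = int(own["individual_id"].nunique())
    if own.empty:
        return ObservedCount(disease_id, 0, 0)
    chap_min = firsts.groupby("individual_id")["onset_age"].min().rename("chap_min")
    own = own.merge(chap_min, on="individual_id")
    n_fic = int((own["onset_age"] <= own["chap_min"]).sum())
    return ObservedCount(disease_id, n_all, n_fic)


def disease_table_row(model: DiseaseModel, ec: ExpectedCount, obs: ObservedCount,
                      qc: QCResult) -> dict:
    """One row of the per-disease results table."""
    return {
        "disease_id": model.disease_id,
        "chapter": model.chapter,
        "expected": ec.expected,
        "variance": ec.variance,
        "ci_low": ec.ci95[0],
        "ci_high": ec.ci95[1],
        "n_all": obs.n_all,
        "n_fic": obs.n_fic,
        "n_risk": ec.n_risk,
        "n_fit_events": model.n_events,
        "k": model.k,
        "L": model.L,
        "se_ratio_k": model.se_ratio_k,
        "se_ratio_L": model.se_ratio_L,
        "sum_sigma2": ec.sum_sigma2,
        "qc_pass": qc.passed,
        "qc_reasons": ";".join(qc.reasons),
    }
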