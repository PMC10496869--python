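"""Risk sets, expected counts, QC rules and observed-count series."""

import numpy as np
import pandas as pd
import pytest

from excessrisk.config import RunConfig
from excessrisk.expectation import (
    ExpectedCount,
    ObservedCount,
    build_fit_records,
    build_risk_set,
    expected_count,
    observed_counts,
    qc_filter,
)
from excessrisk.weibull import DiseaseModel


def toy_cohort():
    return pd.DataFrame({
        "individual_id": [1, 2, 3, 4, 5],
        "entry_age": [50.0, 55.0, 60.0, 45.0, 65.0],
        "exit_age": [60.0, 65.0, 70.0, 55.0, 75.0],
        "prior_cancer": [False, False, False, False, False],
        "prior_cvd": [False, False, False, False, False],
    })


def toy_events():
    # individual 1 has a pre-study report of A; individual 2 onsets in-window;
    # individual 3 has two same-chapter diseases (A at 62, B at 65);
    # individual 5 has three admissions for A (dedup to one)
    return pd.DataFrame({
        "individual_id": [1, 2, 3, 3, 5, 5, 5],
        "disease_id": ["A", "A", "A", "B", "A", "A", "A"],
        "onset_age": [49.0, 58.0, 62.0, 65.0, 70.0, 71.0, 72.5],
        "primary": [True] * 7,
    })


CHAPTERS = {"A": "IX", "B": "IX", "C": "XI"}


def truth_model(disease_id="A", k=5.0, L=150.0):
    return DiseaseModel(disease_id, CHAPTERS.get(disease_id, "IX"), k, L,
                        np.zeros(0), [], np.zeros((2, 2)), 50)


class TestRiskSet:
    def test_pre_study_case_excluded(self):
        rs = build_risk_set(toy_cohort(), toy_events(), "A", RunConfig(factors=[]))
        assert len(rs) == 4
        assert 1 not in set(rs["individual_id"])

    def test_prior_cvd_excluded_unless_sensitivity_flag(self):
        cohort = toy_cohort()
        cohort.loc[cohort["individual_id"] == 4, "prior_cvd"] = True
        rs = build_risk_set(cohort, toy_events(), "A", RunConfig(factors=[]))
        assert 4 not in set(rs["individual_id"])
        rs2 = build_risk_set(cohort, toy_events(), "A",
                             RunConfig(factors=[], keep_prior_cvd=True))
        assert 4 in set(rs2["individual_id"])

    def test_empty_cohort(self):
        rs = build_risk_set(toy_cohort().iloc[:0], toy_events().iloc[:0], "A",
                            RunConfig(factors=[]))
        assert rs.empty


class TestFitRecords:
    def test_conditioning_none_marks_own_first_onset(self):
        rec = build_fit_records(toy_cohort(), toy_events(), "A", CHAPTERS,
                                RunConfig(factors=[], conditioning="none"))
        rec = rec.set_index("individual_id")
        assert bool(rec.loc[2, "event"]) and rec.loc[2, "event_age"] == 58.0
        # individual 5's first in-window admission (70.0) is the event age
        assert rec.loc[5, "event_age"] == 70.0
        # censored individuals end at exit
        assert not rec.loc[4, "event"] and rec.loc[4, "end_age"] == 55.0

    def test_conditioning_chapter_censors_at_first_chapter_onset(self):
        rec = build_fit_records(toy_cohort(), toy_events(), "B", CHAPTERS,
                                RunConfig(factors=[], conditioning="chapter"))
        rec = rec.set_index("individual_id")
        # individual 3's chapter-IX history starts with A at 62 -> censored for B
        assert not rec.loc[3, "event"]
        assert rec.loc[3, "end_age"] == 62.0
        # individual 1 (pre-study A, same chapter) contributes no record
        assert 1 not in rec.index


class TestExpectedCount:
    def test_sums_probabilities_over_risk_set(self):
        cohort = toy_cohort()
        m = truth_model()
        ec = expected_count(m, cohort)
        from excessrisk.weibull import first_incidence_prob

        p = first_incidence_prob(m, cohort["entry_age"].to_numpy(),
                                 cohort["exit_age"].to_numpy())
        assert ec.expected == pytest.approx(p.sum(), rel=1e-12)
        assert ec.variance == pytest.approx((p * (1 - p)).sum(), rel=1e-12)
        assert ec.variance <= ec.expected
        assert ec.ci95[0] <= ec.expected <= ec.ci95[1]

    def test_doubling_risk_set_doubles_expected(self):
        cohort = toy_cohort()
        doubled = pd.concat([cohort, cohort.assign(individual_id=cohort.individual_id + 10)],
                            ignore_index=True)
        m = truth_model()
        assert expected_count(m, doubled).expected == pytest.approx(
            2 * expected_count(m, cohort).expected, rel=1e-12)

    def test_observed_within_interval_under_null(self):
        # simulate observed counts from the same probabilities as the interval
        rng = np.random.default_rng(5)
        m = truth_model(k=5.0, L=120.0)
        n = 30_000
        cohort = pd.DataFrame({
            "individual_id": np.arange(n),
            "entry_age": rng.uniform(40, 70, n),
        })
        cohort["exit_age"] = cohort["entry_age"] + 10
        ec = expected_count(m, cohort)
        hits = 0
        for _ in range(40):
            obs = (rng.random(n) < ec.p).sum()
            hits += ec.ci95[0] <= obs <= ec.ci95[1]
        assert hits >= 33  # ~95% nominal, binomial slack


class TestQCFilter:
    def ec_with(self, sum_sigma2=0.1, sigma2=None):
        return ExpectedCount("A", 100.0, 95.0, (80.0, 120.0), sum_sigma2, 1000,
                             sigma2=sigma2 if sigma2 is not None else np.full(3, 0.01))

    def model_with(self, se_k=0.1, se_L=0.0625):
        cov = np.diag([se_k**2, se_L**2])
        return DiseaseModel("A", "IX", 5.0, 150.0, np.zeros(0), [], cov, 100)

    def test_high_shape_se_fails(self):
        qc = qc_filter(self.model_with(se_k=0.6), self.ec_with(),
                       ObservedCount("A", 120, 100))
        assert not qc.passed and "se_ratio_k" in qc.reasons

    def test_good_model_passes(self):
        qc = qc_filter(self.model_with(), self.ec_with(sum_sigma2=1.0),
                       ObservedCount("A", 120, 100))
        assert qc.passed and qc.reasons == ()

    def test_nan_sigma_fails_delta_method(self):
        ec = self.ec_with(sigma2=np.array([0.01, np.nan, 0.01]))
        qc = qc_filter(self.model_with(), ec, ObservedCount("A", 120, 100))
        assert not qc.passed and "delta_method_nonnumeric" in qc.reasons

    def test_precision_ratio_threshold(self):
        qc = qc_filter(self.model_with(), self.ec_with(sum_sigma2=6.0),
                       ObservedCount("A", 120, 100))
        assert not qc.passed and "sum_sigma2_ratio" in qc.reasons


class TestObservedCounts:
    def test_repeat_admissions_deduplicated(self):
        oc = observed_counts(toy_events(), toy_cohort(), "A", CHAPTERS)
        # individuals 2, 3, 5 have in-window A onsets; 1's report is pre-study
        assert oc.n_all == 3

    def test_fic_excludes_later_same_chapter_disease(self):
        oc = observed_counts(toy_events(), toy_cohort(), "B", CHAPTERS)
        # individual 3 had chapter-IX disease A at 62 before B at 65
        assert oc.n_all == 1 and oc.n_fic == 0

    def test_simultaneous_onsets_both_count_as_fic(self):
        events = pd.DataFrame({
            "individual_id": [2, 2],
            "disease_id": ["A", "B"],
            "onset_age": [58.0, 58.0],
            "primary": [True, True],
        })
        for d in ("A", "B"):
            oc = observed_counts(events, toy_cohort(), d, CHAPTERS)
            assert oc.n_fic == 1

    def test_unknown_individual_rejected(self):
        events = toy_events()
        events.loc[0, "individual_id"] = 99
        with pytest.raises(KeyError, match="unknown individuals"):
            observed_counts(events, toy_cohort(), "A", CHAPTERS)

    def test_fic_never_exceeds_all(self):
        with pytest.raises(ValueError):
            ObservedCount("A", 2, 3)
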