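"""Weibull incidence model: likelihood, MLE, probabilities, delta method."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excessrisk.weibull import (
    DiseaseModel,
    SurvivalRecord,
    WeibullIncidenceModel,
    WeibullParams,
    delta_method_variance,
    first_incidence_prob,
    log_likelihood,
    survival,
)

from conftest import weibull_records


def params_model(k, L, beta=(), cov=None, names=None):
    beta = np.asarray(beta, dtype=float)
    d = 2 + beta.size
    return DiseaseModel("test", "IX", k, L, beta,
                        names or [f"x{i}" for i in range(beta.size)],
                        np.zeros((d, d)) if cov is None else cov, 100)


class TestSurvival:
    def test_unit_cumulative_hazard_at_scale(self):
        assert survival(80.0, WeibullParams(5, 80)) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_at_zero(self):
        assert survival(0.0, WeibullParams(5, 80)) == 1.0

    def test_reference_values(self):
        p = WeibullParams(5, 80)
        assert survival(60.0, p) == pytest.approx(0.78875, abs=1e-4)
        assert survival(70.0, p) == pytest.approx(0.59875, abs=1e-4)

    def test_covariates_shift_log_hazard(self):
        p = WeibullParams(5, 80, beta=[np.log(2.0)])
        base = survival(60.0, WeibullParams(5, 80))
        assert survival(60.0, p, x=[1.0]) == pytest.approx(base**2, rel=1e-10)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            survival(-1.0, WeibullParams(5, 80))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(1.0, 99.0), st.floats(0.5, 8.0), st.floats(50.0, 300.0))
    def test_monotone_decreasing(self, t, k, L):
        p = WeibullParams(k, L)
        assert survival(t + 1.0, p) < survival(t, p)


class TestLogLikelihood:
    def hand_loglike(self, records, k, L, beta):
        """Independent scalar evaluation, term by term."""
        total = 0.0
        for r in records:
            eta = float(np.dot(r.covariates, beta)) if len(beta) else 0.0
            w = np.exp(eta)
            def S(t):
                return np.exp(-w * (t / L) ** k)
            if r.event:
                h = w * k * r.event_age ** (k - 1) / L**k
                total += np.log(h) + np.log(S(r.event_age)) - np.log(S(r.entry_age))
            else:
                total += np.log(S(r.exit_age)) - np.log(S(r.entry_age))
        return total

    def fixture_records(self):
        return [
            SurvivalRecord(55.0, 65.0, True, 60.0, [1.0, 0.0]),
            SurvivalRecord(48.0, 58.0, False, covariates=[0.0, 1.0]),
            SurvivalRecord(62.0, 72.0, True, 71.5, [1.0, 1.0]),
            SurvivalRecord(40.0, 50.0, False, covariates=[0.0, 0.0]),
            SurvivalRecord(67.0, 77.0, False, covariates=[1.0, 0.0]),
        ]

    def test_matches_hand_evaluation(self):
        records = self.fixture_records()
        params = WeibullParams(4.5, 95.0, beta=[0.3, -0.2])
        assert log_likelihood(records, params) == pytest.approx(
            self.hand_loglike(records, 4.5, 95.0, [0.3, -0.2]), rel=1e-12)

    def test_censored_record_negative(self):
        rec = [SurvivalRecord(50.0, 60.0, False)]
        assert log_likelihood(rec, WeibullParams(5, 90)) < 0

    def test_small_entry_approaches_untruncated(self):
        # as entry -> 0 the truncation term log S(entry) -> 0
        params = WeibullParams(5, 90)
        ll = log_likelihood([SurvivalRecord(1e-6, 60.0, True, 55.0)], params)
        w = (55.0 / 90.0) ** 5
        h = 5 * 55.0**4 / 90.0**5
        assert ll == pytest.approx(np.log(h) - w, rel=1e-9)

    def test_order_invariance(self):
        records = self.fixture_records()
        params = WeibullParams(5.0, 100.0, beta=[0.1, 0.1])
        assert log_likelihood(records, params) == pytest.approx(
            log_likelihood(records[::-1], params), rel=1e-14)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            WeibullParams(-1.0, 90.0)
        with pytest.raises(ValueError):
            WeibullParams(5.0, 0.0)


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        entry, end, event, _, _ = weibull_records(rng, 80_000, k=5.0, L=80.0,
                                                  entry_range=(40.0, 70.0))
        model = WeibullIncidenceModel(entry, end, event)
        res = model.fit()
        assert res.converged
        assert model.n_events > 2000
        assert abs(np.log(res.k) - np.log(5.0)) < 3 * res.bse[0]
        assert abs(np.log(res.L) - np.log(80.0)) < 3 * res.bse[1]

    def test_covariate_recovery(self):
        rng = np.random.default_rng(22)
        entry, end, event, X, _ = weibull_records(rng, 60_000, k=5.0, L=110.0,
                                                  beta=[np.log(2.0)])
        res = WeibullIncidenceModel(entry, end, event, exog=X).fit()
        assert res.converged
        assert abs(res.beta[0] - np.log(2.0)) < 3 * res.bse[2]

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="no events"):
            WeibullIncidenceModel([50.0], [60.0], [False]).fit()

    def test_score_is_gradient_of_loglike(self):
        rng = np.random.default_rng(23)
        entry, end, event, X, _ = weibull_records(rng, 2_000, k=4.0, L=120.0, beta=[0.3])
        model = WeibullIncidenceModel(entry, end, event, exog=X)
        theta = np.array([np.log(4.2), np.log(115.0), 0.2])
        score = model.score(theta)
        for j in range(3):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (model.loglike(tp) - model.loglike(tm)) / (2 * h)
            assert score[j] == pytest.approx(fd, rel=1e-5, abs=1e-4)

    def test_parameterization_consistency(self):
        # the reported k, L are the exponentials of the internal optimum
        rng = np.random.default_rng(24)
        entry, end, event, _, _ = weibull_records(rng, 20_000, k=5.0, L=100.0)
        res = WeibullIncidenceModel(entry, end, event).fit()
        assert res.k == pytest.approx(np.exp(res.theta[0]), rel=1e-12)
        assert res.L == pytest.approx(np.exp(res.theta[1]), rel=1e-12)

    def test_ci_coverage_over_replicates(self):
        # 99% intervals for (log k, log L) should cover truth nearly always
        rng = np.random.default_rng(25)
        hits = 0
        trials = 40
        for _ in range(trials):
            entry, end, event, _, _ = weibull_records(rng, 25_000, k=5.0, L=100.0)
            res = WeibullIncidenceModel(entry, end, event).fit()
            z_k = (res.theta[0] - np.log(5.0)) / res.bse[0]
            z_L = (res.theta[1] - np.log(100.0)) / res.bse[1]
            hits += (abs(z_k) < 2.576) and (abs(z_L) < 2.576)
        # joint coverage of two 99% intervals is >= 98%; allow binomial noise
        assert hits >= trials - 4

    def test_matches_lifelines_left_truncated(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(26)
        entry, end, event, _, _ = weibull_records(rng, 30_000, k=5.0, L=95.0)
        res = WeibullIncidenceModel(entry, end, event).fit()
        wf = lifelines.WeibullFitter()
        wf.fit(durations=end, event_observed=event, entry=entry)
        assert res.k == pytest.approx(wf.rho_, rel=2e-3)
        assert res.L == pytest.approx(wf.lambda_, rel=2e-3)


class TestFirstIncidenceProb:
    def test_reference_window(self):
        m = params_model(5.0, 80.0)
        assert first_incidence_prob(m, 60.0, 70.0) == pytest.approx(0.1900, abs=2e-4)

    def test_empty_window(self):
        assert first_incidence_prob(params_model(5.0, 80.0), 60.0, 60.0) == 0.0

    def test_certain_eventual_onset(self):
        assert first_incidence_prob(params_model(5.0, 80.0), 0.0, np.inf) == pytest.approx(1.0)

    def test_entry_after_exit_rejected(self):
        with pytest.raises(ValueError):
            first_incidence_prob(params_model(5.0, 80.0), 70.0, 60.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(1.0, 80.0), st.floats(0.1, 20.0), st.floats(0.1, 20.0))
    def test_additive_over_abutting_windows(self, a, d1, d2):
        m = params_model(4.0, 120.0)
        p_ab = first_incidence_prob(m, a, a + d1)
        p_bc = first_incidence_prob(m, a + d1, a + d1 + d2)
        p_ac = first_incidence_prob(m, a, a + d1 + d2)
        assert p_ab + p_bc == pytest.approx(p_ac, abs=1e-12)


class TestDeltaMethod:
    def test_zero_covariance_gives_zero(self):
        assert delta_method_variance(params_model(5.0, 80.0), 60.0, 70.0) == 0.0

    def test_gradient_matches_finite_differences(self):
        k, L, beta = 5.0, 90.0, np.array([0.3, -0.1])
        theta = np.concatenate([[np.log(k), np.log(L)], beta])
        x = np.array([1.0, 1.0])
        entry, exit_ = 55.0, 65.0
        # extract the analytic gradient through a rank-one covariance probe:
        # with cov = e_j e_j', sigma^2 = g_j^2
        grads = []
        for j in range(4):
            cov = np.zeros((4, 4))
            cov[j, j] = 1.0
            m = params_model(k, L, beta, cov=cov)
            g2 = delta_method_variance(m, entry, exit_, covariates=x)
            grads.append(np.sqrt(g2))
        h = 1e-6
        for j in range(4):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            def p_of(th):
                mm = params_model(np.exp(th[0]), np.exp(th[1]), th[2:])
                return first_incidence_prob(mm, entry, exit_, covariates=x)
            fd = abs(p_of(tp) - p_of(tm)) / (2 * h)
            assert grads[j] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_negative_kl_correlation_shrinks_variance(self):
        full = np.array([[0.01, -0.008], [-0.008, 0.01]])
        diag = np.diag(np.diag(full))
        # build 2x2-covariance models (no covariates)
        m_full = params_model(5.0, 90.0, cov=full)
        m_diag = params_model(5.0, 90.0, cov=diag)
        v_full = delta_method_variance(m_full, 55.0, 65.0)
        v_diag = delta_method_variance(m_diag, 55.0, 65.0)
        assert v_full < v_diag
        assert v_full >= 0

    def test_nonfinite_covariance_propagates_nan(self):
        d = 2
        m = DiseaseModel("t", "IX", 5.0, 90.0, np.zeros(0), [],
                         np.full((d, d), np.nan), 10)
        assert np.isnan(delta_method_variance(m, 55.0, 65.0))


class TestRecordValidation:
    def test_entry_must_precede_exit(self):
        with pytest.raises(ValueError):
            SurvivalRecord(60.0, 50.0)

    def test_event_age_must_lie_in_window(self):
        with pytest.raises(ValueError):
            SurvivalRecord(50.0, 60.0, True, 49.0)

    def test_roundtrip_serialization(self):
        rng = np.random.default_rng(31)
        cov = rng.random((4, 4))
        cov = cov @ cov.T
        m = DiseaseModel("D01", "IX", 5.0, 90.0, np.array([0.1, -0.2]),
                         ["a", "b"], cov, 123, True, -456.7)
        m2 = DiseaseModel.from_dict(m.to_dict())
        assert m2.disease_id == m.disease_id and m2.chapter == m.chapter
        np.testing.assert_allclose(m2.cov_theta, m.cov_theta)
        np.testing.assert_allclose(m2.beta, m.beta)
        assert m2.n_events == 123
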