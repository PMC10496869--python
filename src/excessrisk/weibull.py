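"""Covariate-adjusted Weibull model for age at first incidence of a disease.

The survival function is

    S(t | x) = exp( - e^{x'beta} (t / L)^k )

with age ``t`` in years, shape ``k > 0``, scale ``L > 0`` (years), and
log-rate coefficients ``beta`` for baseline-referenced indicator covariates.
Individuals enter observation at their study-entry age (left truncation:
survival to entry is conditioned on) and are right-censored when follow-up
ends before onset.  The fit is by maximum likelihood in the internal
parameterization ``theta = (log k, log L, beta)``, which enforces positivity;
the covariance of the MLE is the inverse observed information on that scale
and is chained through the delta method when propagating to per-individual
incidence probabilities

    p_i = S(t_i^entry | x_i) - S(t_i^exit | x_i),

the probability of individual *i* first experiencing the disease during their
study window.  The negative correlation between ``k`` and ``L`` makes these
delta-method variances substantially smaller than diagonal-only propagation
would suggest, so the full covariance is always used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import design_matrix

__all__ = [
    "WeibullParams",
    "SurvivalRecord",
    "DiseaseModel",
    "WeibullIncidenceModel",
    "WeibullIncidenceResults",
    "survival",
    "log_likelihood",
    "first_incidence_prob",
    "delta_method_variance",
]


@dataclass(frozen=True)
class WeibullParams:
    """Shape ``k``, scale ``L`` (years) and covariate log-rate coefficients."""

    k: float
    L: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if not (self.k > 0 and np.isfinite(self.k)):
            raise ValueError(f"shape k must be positive and finite, got {self.k}")
        if not (self.L > 0 and np.isfinite(self.L)):
            raise ValueError(f"scale L must be positive and finite, got {self.L}")
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    @property
    def theta(self) -> np.ndarray:
        """Internal parameter vector (log k, log L, beta)."""
        return np.concatenate([[np.log(self.k), np.log(self.L)], self.beta])

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "WeibullParams":
        theta = np.asarray(theta, dtype=float)
        return cls(k=float(np.exp(theta[0])), L=float(np.exp(theta[1])), beta=theta[2:])


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's observation window for one disease.

    ``exit_age`` is the end of potential follow-up (the minimum of death age,
    cancer-censoring age and administrative study end) -- the same window that
    enters the first-incidence probability.  If ``event`` is true the onset
    was observed at ``event_age`` inside the window.
    """

    entry_age: float
    exit_age: float
    event: bool = False
    event_age: float | None = None
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if not 0.0 < self.entry_age < self.exit_age:
            raise ValueError(
                f"require 0 < entry_age < exit_age, got ({self.entry_age}, {self.exit_age})"
            )
        if self.event:
            if self.event_age is None or not (self.entry_age < self.event_age <= self.exit_age):
                raise ValueError(
                    f"event_age must lie in (entry_age, exit_age], got {self.event_age}"
                )
        object.__setattr__(
            self, "covariates", np.atleast_1d(np.asarray(self.covariates, dtype=float))
        )


def survival(t, params: WeibullParams, x=None):
    """``S(t | x) = exp(-e^{x'beta} (t/L)^k)``; ``S(0) = 1``; decreasing in t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be non-negative")
    eta = 0.0 if x is None else float(np.dot(np.atleast_1d(x), params.beta))
    out = np.exp(-np.exp(eta) * (t / params.L) ** params.k)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# internal vectorized likelihood machinery


class _Arrays:
    """Validated record arrays: entry a, end-of-record b, event flag d, design X."""

    __slots__ = ("a", "b", "d", "X", "log_a", "log_b", "n", "n_events")

    def __init__(self, entry, end, event, X):
        self.a = np.asarray(entry, dtype=float)
        self.b = np.asarray(end, dtype=float)
        self.d = np.asarray(event, dtype=bool)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1) if self.X.size == self.a.size else self.X.reshape(len(self.a), -1)
        if not (np.all(self.a > 0) and np.all(self.b > self.a)):
            raise ValueError("records require 0 < entry < end-of-record age")
        self.log_a = np.log(self.a)
        self.log_b = np.log(self.b)
        self.n = self.a.size
        self.n_events = int(self.d.sum())


def _loglike_score(arr: _Arrays, theta: np.ndarray, want_score: bool):
    lk, lL = theta[0], theta[1]
    beta = theta[2:]
    k = np.exp(lk)
    eta = arr.X @ beta if beta.size else np.zeros(arr.n)
    w = np.exp(eta)
    la = arr.log_a - lL
    lb = arr.log_b - lL
    za = np.exp(k * la)  # (a/L)^k
    zb = np.exp(k * lb)
    dz = zb - za
    d = arr.d
    ll = float(np.sum(d * (eta + lk + (k - 1.0) * arr.log_b - k * lL)) - np.sum(w * dz))
    if not want_score:
        return ll, None
    s_lk = float(np.sum(d * (1.0 + k * lb)) - k * np.sum(w * (zb * lb - za * la)))
    s_lL = float(-k * arr.n_events + k * np.sum(w * dz))
    score = np.empty(theta.size)
    score[0] = s_lk
    score[1] = s_lL
    if beta.size:
        score[2:] = arr.X.T @ (d.astype(float) - w * dz)
    return ll, score


def _hessian_fd(arr: _Arrays, theta: np.ndarray) -> np.ndarray:
    """Hessian of the log-likelihood via central differences of the analytic score."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, sp = _loglike_score(arr, tp, True)
        _, sm = _loglike_score(arr, tm, True)
        H[:, j] = (sp - sm) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public model / results objects


class WeibullIncidenceModel:
    """Weibull first-incidence model for one disease (left truncation, right censoring).

    Parameters
    ----------
    entry, end, event : array-like
        Per-record entry age, end-of-record age (event age for events,
        censoring age otherwise) and event indicator.
    exog : array-like, optional
        (n, d) indicator design matrix; omit for a covariate-free model.
    exog_names : list of str, optional
    disease_id, chapter : str, optional
        Carried through to the fitted :class:`DiseaseModel`.
    """

    def __init__(self, entry, end, event, exog=None, exog_names=None,
                 disease_id="disease", chapter=""):
        n = np.asarray(entry).size
        if exog is None:
            exog = np.zeros((n, 0))
        self._arr = _Arrays(entry, end, event, exog)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self._arr.X.shape[1])
        ]
        if len(self.exog_names) != self._arr.X.shape[1]:
            raise ValueError("exog_names length does not match design matrix")
        self.disease_id = disease_id
        self.chapter = chapter

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(cls, records, **kwargs) -> "WeibullIncidenceModel":
        """Build from a list of :class:`SurvivalRecord`."""
        records = list(records)
        if not records:
            raise ValueError("no records")
        entry = [r.entry_age for r in records]
        end = [r.event_age if r.event else r.exit_age for r in records]
        event = [r.event for r in records]
        X = np.vstack([r.covariates for r in records]) if records[0].covariates.size else None
        return cls(entry, end, event, exog=X, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors=(), entry_col="entry_age",
                       exit_col="exit_age", event_col="event", event_age_col="event_age",
                       **kwargs) -> "WeibullIncidenceModel":
        """Build from a records table, dummy-coding ``factors`` columns."""
        event = df[event_col].to_numpy(dtype=bool)
        end = np.where(event, df[event_age_col].to_numpy(dtype=float),
                       df[exit_col].to_numpy(dtype=float))
        X, names = design_matrix(df, factors) if factors else (None, None)
        return cls(df[entry_col].to_numpy(dtype=float), end, event,
                   exog=X, exog_names=names, **kwargs)

    # -- likelihood ---------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self._arr.n

    @property
    def n_events(self) -> int:
        return self._arr.n_events

    def loglike(self, theta) -> float:
        """Log-likelihood at internal parameters (log k, log L, beta)."""
        return _loglike_score(self._arr, np.asarray(theta, dtype=float), False)[0]

    def score(self, theta) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        return _loglike_score(self._arr, np.asarray(theta, dtype=float), True)[1]

    def _start_params(self) -> list[np.ndarray]:
        """Profile-likelihood starts: for each trial shape k the scale has a
        closed-form MLE (with beta = 0), giving cheap, robust initial values."""
        arr = self._arr
        if arr.n_events == 0:
            raise ValueError("cannot fit: no events in the records")
        ev_b = arr.b[arr.d]
        starts = []
        scored = []
        for k0 in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
            denom = float(np.sum(arr.b**k0 - arr.a**k0))
            if denom <= 0:
                continue
            c = arr.n_events / denom  # c = L^{-k}
            L0 = c ** (-1.0 / k0)
            theta0 = np.concatenate([[np.log(k0), np.log(L0)], np.zeros(arr.X.shape[1])])
            scored.append((self.loglike(theta0), theta0))
        scored.sort(key=lambda t: -t[0])
        starts = [t for _, t in scored[:2]]
        if not starts:  # degenerate fallback
            starts = [np.concatenate([[0.0, np.log(np.median(ev_b)) + 1.0],
                                      np.zeros(arr.X.shape[1])])]
        return starts

    def fit(self, start_params=None, gtol: float = 1e-8, maxiter: int = 500) -> "WeibullIncidenceResults":
        """Maximize the likelihood by BFGS with the analytic gradient.

        Convergence requires the score max-norm below ``1e-6`` per event (a
        scale-aware version of an absolute 1e-6 gradient tolerance).  The MLE
        covariance is the inverse of the observed information (negative
        Hessian, by central differences of the analytic score).  Failure to
        converge or a non-invertible information matrix is flagged on the
        results (such diseases are later excluded by QC), not raised.
        """
        arr = self._arr
        if arr.n_events == 0:
            raise ValueError("cannot fit: no events in the records")
        starts = [np.asarray(start_params, dtype=float)] if start_params is not None \
            else self._start_params()
        best = None
        for theta0 in starts:
            res = optimize.minimize(
                lambda th: -self.loglike(th), theta0,
                jac=lambda th: -self.score(th),
                method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            if best is None or -res.fun > -best.fun:
                best = res
        theta = best.x
        grad = self.score(theta)
        tol = 1e-6 * max(1.0, float(arr.n_events))
        converged = bool(np.max(np.abs(grad)) < tol)
        cov = None
        cov_ok = False
        if converged:
            H = _hessian_fd(arr, theta)
            try:
                cov = np.linalg.inv(-H)
                cov = 0.5 * (cov + cov.T)
                eig = np.linalg.eigvalsh(cov)
                cov_ok = bool(np.all(np.isfinite(cov)) and eig.min() > -1e-10 * max(1.0, eig.max()))
            except np.linalg.LinAlgError:
                cov_ok = False
        if cov is None or not cov_ok:
            cov = np.full((theta.size, theta.size), np.nan)
        return WeibullIncidenceResults(
            model=self, theta=theta, cov_theta=cov,
            converged=converged and cov_ok, loglik=float(-best.fun),
            score_max=float(np.max(np.abs(grad))),
        )


class WeibullIncidenceResults:
    """MLE results for a :class:`WeibullIncidenceModel`."""

    def __init__(self, model, theta, cov_theta, converged, loglik, score_max):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.cov_theta = np.asarray(cov_theta, dtype=float)
        self.converged = converged
        self.loglik = loglik
        self.score_max = score_max

    # -- parameter views ----------------------------------------------------

    @property
    def params(self) -> WeibullParams:
        return WeibullParams.from_theta(self.theta)

    @property
    def k(self) -> float:
        return float(np.exp(self.theta[0]))

    @property
    def L(self) -> float:
        return float(np.exp(self.theta[1]))

    @property
    def beta(self) -> np.ndarray:
        return self.theta[2:]

    @property
    def bse(self) -> np.ndarray:
        """Standard errors on the internal (log k, log L, beta) scale."""
        return np.sqrt(np.diag(self.cov_theta))

    @property
    def se_ratio_k(self) -> float:
        """s.e.(k)/k; equals s.e.(log k) by the delta method."""
        return float(self.bse[0])

    @property
    def se_ratio_L(self) -> float:
        return float(self.bse[1])

    def as_disease_model(self) -> "DiseaseModel":
        return DiseaseModel(
            disease_id=self.model.disease_id,
            chapter=self.model.chapter,
            k=self.k,
            L=self.L,
            beta=self.beta.copy(),
            beta_names=list(self.model.exog_names),
            cov_theta=self.cov_theta.copy(),
            n_events=self.model.n_events,
            converged=self.converged,
            loglik=self.loglik,
        )

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        names = ["log k", "log L"] + list(self.model.exog_names)
        est = self.theta
        se = self.bse
        rows = [[f"{e:.4f}", f"{s:.4f}", f"{e - 1.96 * s:.4f}", f"{e + 1.96 * s:.4f}"]
                for e, s in zip(est, se)]
        tbl = SimpleTable(rows, headers=["coef", "std err", "[0.025", "0.975]"],
                          stubs=names, title=(
                              f"Weibull incidence model: {self.model.disease_id}  "
                              f"(k={self.k:.3f}, L={self.L:.1f} y, events={self.model.n_events}, "
                              f"loglik={self.loglik:.1f}, converged={self.converged})"))
        return str(tbl)


@dataclass
class DiseaseModel:
    """Serializable fitted Weibull model for one disease.

    ``cov_theta`` is the MLE covariance over (log k, log L, beta).
    """

    disease_id: str
    chapter: str
    k: float
    L: float
    beta: np.ndarray
    beta_names: list[str]
    cov_theta: np.ndarray
    n_events: int
    converged: bool = True
    loglik: float = np.nan

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[np.log(self.k), np.log(self.L)], np.asarray(self.beta, float)])

    @property
    def se_ratio_k(self) -> float:
        return float(np.sqrt(self.cov_theta[0, 0]))

    @property
    def se_ratio_L(self) -> float:
        return float(np.sqrt(self.cov_theta[1, 1]))

    def to_dict(self) -> dict:
        return {
            "disease_id": self.disease_id,
            "chapter": self.chapter,
            "k": self.k,
            "L": self.L,
            "beta": np.asarray(self.beta, float).tolist(),
            "beta_names": list(self.beta_names),
            "cov_theta": np.asarray(self.cov_theta, float).tolist(),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
            "loglik": None if not np.isfinite(self.loglik) else float(self.loglik),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiseaseModel":
        return cls(
            disease_id=d["disease_id"], chapter=d.get("chapter", ""),
            k=float(d["k"]), L=float(d["L"]),
            beta=np.asarray(d["beta"], dtype=float),
            beta_names=list(d["beta_names"]),
            cov_theta=np.asarray(d["cov_theta"], dtype=float),
            n_events=int(d["n_events"]),
            converged=bool(d.get("converged", True)),
            loglik=float(d["loglik"]) if d.get("loglik") is not None else np.nan,
        )


# ---------------------------------------------------------------------------
# record-level public operations


def log_likelihood(records, params: WeibullParams) -> float:
    """Left-truncated, right-censored log-likelihood of ``records`` at ``params``.

    Events contribute ``log h(t_event) + log S(t_event) - log S(t_entry)``;
    censored records contribute the survival ratio only.
    """
    model = WeibullIncidenceModel.from_records(records)
    if model._arr.X.shape[1] != params.beta.size:
        raise ValueError("covariate dimension mismatch between records and params")
    return model.loglike(params.theta)


def _p_and_grad(theta, entry, exit_, X, want_grad):
    """Vectorized p_i = S(entry) - S(exit) and its gradient wrt theta."""
    lk, lL = theta[0], theta[1]
    k = np.exp(lk)
    beta = theta[2:]
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    if np.any(entry < 0) or np.any(exit_ < entry):
        raise ValueError("require 0 <= entry <= exit")
    eta = X @ beta if beta.size else np.zeros(entry.shape)
    w = np.exp(eta)
    with np.errstate(divide="ignore"):
        la = np.where(entry > 0, np.log(entry) - lL, -np.inf)
        lb = np.where(exit_ > 0, np.log(exit_) - lL, -np.inf)
    ua = w * np.exp(k * la)  # cumulative hazard at entry
    ub = w * np.exp(k * lb)
    Sa = np.exp(-ua)
    Sb = np.exp(-ub)
    p = Sa - Sb
    if not want_grad:
        return p, None
    # d p / d eta, chain to each theta component; u e^{-u} -> 0 as u -> inf
    aa = np.where(np.isinf(ua), 0.0, Sa * ua)  # S_a * u_a
    bb = np.where(np.isinf(ub), 0.0, Sb * ub)
    g_eta = bb - aa
    g_lk = k * (np.where(np.isfinite(la), la, 0.0) * -aa + np.where(np.isfinite(lb), lb, 0.0) * bb)
    g_lL = -k * g_eta
    cols = [g_lk, g_lL]
    if beta.size:
        G = np.column_stack(cols + [g_eta[:, None] * X])
    else:
        G = np.column_stack(cols)
    return p, G


def _model_theta_X(model, entry, exit_, covariates):
    theta = model.theta if isinstance(model, DiseaseModel) else model.theta
    d = theta.size - 2
    n = np.asarray(entry, dtype=float).size
    if covariates is None:
        X = np.zeros((n, d))
    else:
        X = np.asarray(covariates, dtype=float)
        X = X.reshape(n, -1)
        if X.shape[1] != d:
            raise ValueError(f"covariates have {X.shape[1]} columns, model has {d}")
    return theta, X


def first_incidence_prob(model, entry, exit_, covariates=None):
    """``p = S(entry|x) - S(exit|x)``: probability of first onset in the window.

    ``model`` may be a :class:`DiseaseModel` or :class:`WeibullIncidenceResults`.
    Accepts scalars or arrays; ``p = 0`` when ``entry == exit``.
    """
    scalar = np.isscalar(entry)
    entry = np.atleast_1d(np.asarray(entry, dtype=float))
    exit_ = np.atleast_1d(np.asarray(exit_, dtype=float))
    theta, X = _model_theta_X(model, entry, exit_, covariates)
    p, _ = _p_and_grad(theta, entry, exit_, X, False)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def delta_method_variance(model, entry, exit_, covariates=None):
    """First-order variance of ``p_hat = S(entry) - S(exit)`` from the MLE covariance.

    ``sigma^2 = g' Cov(theta) g`` with ``g`` the gradient of p with respect to
    (log k, log L, beta) at the MLE.  The full covariance, including the
    negative k-L cross term, is used.  Returns NaN per record if the model
    covariance is not finite (propagated to QC as a delta-method failure).
    """
    scalar = np.isscalar(entry)
    entry = np.atleast_1d(np.asarray(entry, dtype=float))
    exit_ = np.atleast_1d(np.asarray(exit_, dtype=float))
    theta, X = _model_theta_X(model, entry, exit_, covariates)
    cov = model.cov_theta
    _, G = _p_and_grad(theta, entry, exit_, X, True)
    if not np.all(np.isfinite(cov)):
        out = np.full(entry.shape, np.nan)
        return float(out[0]) if scalar else out
    var = np.einsum("ij,jk,ik->i", G, cov, G)
    # tiny negative values are round-off from the quadratic form
    var = np.where(var > -1e-15, np.maximum(var, 0.0), var)
    if np.any(var < 0):
        warnings.warn("negative delta-method variance; covariance not PSD", RuntimeWarning)
    return float(var[0]) if scalar else var
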