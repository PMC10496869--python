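import warnings

import numpy as np
import pytest

from excessrisk import ExcessIncidenceModel, RunConfig, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_null_study():
    """A small synthetic study with independent diseases (m = 1)."""
    cfg = SimConfig.small(seed=42, n_individuals=12_000, prior_disease_multiplier=1.0)
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def fitted_null_results(small_null_study):
    cfg, study = small_null_study
    rc = RunConfig(factors=list(cfg.factors), min_events=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ExcessIncidenceModel(study.cohort, study.events, study.diseases,
                                    config=rc).fit()


def weibull_records(rng, n, k, L, beta=(), X=None, entry_range=(40.0, 70.0), followup=10.0):
    """Simulate left-truncated, right-censored records directly from the model law.

    Individuals with onset before entry are dropped (they would be excluded
    from the risk set), mirroring how fitting data arise.
    Returns (entry, end, event, X_kept, exit).
    """
    entry = rng.uniform(*entry_range, size=n)
    exit_ = entry + followup
    beta = np.asarray(beta, dtype=float)
    if X is None and beta.size:
        X = (rng.random((n, beta.size)) < 0.5).astype(float)
    eta = X @ beta if beta.size else np.zeros(n)
    t = L * (rng.exponential(size=n) / np.exp(eta)) ** (1.0 / k)
    keep = t > entry
    entry, exit_, t = entry[keep], exit_[keep], t[keep]
    X = X[keep] if X is not None else None
    event = t <= exit_
    end = np.where(event, t, exit_)
    return entry, end, event, X, exit_
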