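"""Distribution of the number of successes of independent, non-identical Bernoulli trials.

If individual *i* experiences a given disease during the study with probability
``p_i``, and disease risks are independent across individuals, the number of
affected individuals ``N = sum_i X_i`` follows the Poisson-Binomial
distribution.  Its mean and variance have the closed forms

    E[N]   = sum_i p_i
    Var[N] = sum_i p_i (1 - p_i)

and the exact probability mass function can be computed by an iterative
convolution (dynamic programming) in O(n^2).  For small per-trial
probabilities the distribution tends to Poisson(sum_i p_i); a truncated
Poisson approximation with its total-variation error is also provided.

This module is pure and in-memory; :mod:`excessrisk.expectation` builds the
per-disease expected counts on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CountDistribution",
    "pb_mean",
    "pb_variance",
    "pb_pmf",
    "pb_generating_function",
    "pb_interval",
    "pb_quantile_interval",
    "pb_poisson_approx",
]

#: probabilities within this distance of [0, 1] are clipped (float round-off
#: in p_ij); larger violations are errors.
BOUNDARY_TOL = 1e-12

#: default upper bound on n for the exact O(n^2) PMF.
MAX_EXACT_N = 100_000


def _validate_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("probs must be a one-dimensional sequence")
    if p.size and not np.all(np.isfinite(p)):
        raise ValueError("probs contains non-finite values")
    if p.size and (p.min() < -BOUNDARY_TOL or p.max() > 1.0 + BOUNDARY_TOL):
        bad = p[(p < -BOUNDARY_TOL) | (p > 1.0 + BOUNDARY_TOL)]
        raise ValueError(
            f"probabilities outside [0, 1]: e.g. {bad[:3]!r} "
            f"(violations beyond {BOUNDARY_TOL} are errors, not round-off)"
        )
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class CountDistribution:
    """A distribution over counts 0..n.

    Attributes
    ----------
    pmf : ndarray
        ``pmf[k] = P(N = k)``.
    mean, variance : float
        Closed-form moments (not recomputed from ``pmf``).
    tv_to_exact : float or None
        For approximations, the total-variation distance to the exact PMF
        (None when the exact PMF was not computed).
    """

    pmf: np.ndarray
    mean: float
    variance: float
    tv_to_exact: float | None = None

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.pmf.size)


def pb_mean(probs) -> float:
    """Expected count ``sum_i p_i``."""
    return float(_validate_probs(probs).sum())


def pb_variance(probs) -> float:
    """Count variance ``sum_i p_i (1 - p_i)``.

    The per-individual estimation variances do not enter: by the law of total
    variance the plug-in uncertainty terms cancel, leaving the same form with
    the point estimates plugged in.
    """
    p = _validate_probs(probs)
    return float((p * (1.0 - p)).sum())


def pb_pmf(probs, max_n: int = MAX_EXACT_N) -> CountDistribution:
    """Exact PMF of the Poisson-Binomial count by convolution DP.

    The recursion after adding trial ``i`` is
    ``P_k <- P_k (1 - p_i) + P_{k-1} p_i``, i.e. iterated convolution with
    each Bernoulli factor; cost is O(n^2), exact to float round-off.

    Raises
    ------
    ValueError
        If ``len(probs) > max_n``; use :func:`pb_poisson_approx` instead.
    """
    p = _validate_probs(probs)
    n = p.size
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds the exact-PMF bound {max_n}; the O(n^2) DP would "
            "be slow -- use pb_poisson_approx for large sparse problems"
        )
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # slice RHS is evaluated before assignment, so in-place is safe
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return CountDistribution(pmf=pmf, mean=float(p.sum()), variance=float((p * (1 - p)).sum()))


def pb_generating_function(probs, s: float) -> float:
    """Moment generating function ``G(s) = prod_i (e^s p_i + 1 - p_i)``.

    ``G(0) = 1``; derivatives at ``s = 0`` give the factorial-free moments
    (``G'(0) = E[N]``).  Evaluated as ``exp(sum log)`` for numerical range.
    """
    p = _validate_probs(probs)
    if p.size == 0:
        return 1.0
    terms = np.exp(float(s)) * p + (1.0 - p)
    return float(np.exp(np.log(terms).sum()))


def pb_interval(probs, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval ``mean +/- z sqrt(variance)``.

    ``z = 1.96`` exactly at ``level = 0.95`` (the conventional reported
    value); other levels use the normal quantile.  The lower bound is floored
    at zero since counts are non-negative.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"coverage level must be in (0, 1), got {level}")
    p = _validate_probs(probs)
    mean = float(p.sum())
    sd = float(np.sqrt((p * (1 - p)).sum()))
    z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    return (max(0.0, mean - z * sd), mean + z * sd)


def pb_quantile_interval(probs, level: float = 0.95, max_n: int = MAX_EXACT_N) -> tuple[int, int]:
    """Exact equal-tailed quantile interval from the DP PMF (optional variant)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"coverage level must be in (0, 1), got {level}")
    dist = pb_pmf(probs, max_n=max_n)
    cdf = np.cumsum(dist.pmf)
    alpha = (1.0 - level) / 2.0
    lo = int(np.searchsorted(cdf, alpha))
    hi = int(np.searchsorted(cdf, 1.0 - alpha))
    return lo, min(hi, dist.pmf.size - 1)


def pb_poisson_approx(probs, compute_tv: bool | None = None) -> CountDistribution:
    """Poisson approximation with rate ``lambda = sum_i p_i``.

    Valid when every ``p_i`` is small: expanding the generating function in
    ``p_i`` gives ``G(s) -> exp((e^s - 1) lambda)``, the Poisson MGF.  The
    PMF is truncated to 0..n and renormalized.  When feasible (``compute_tv``
    true, or by default for n <= 5000) the total-variation distance to the
    exact PMF is computed so poor approximations (large ``p_i``) are visible.
    """
    p = _validate_probs(probs)
    n = p.size
    lam = float(p.sum())
    k = np.arange(n + 1)
    pmf = stats.poisson.pmf(k, lam) if n else np.array([1.0])
    total = pmf.sum()
    if total > 0:
        pmf = pmf / total
    if compute_tv is None:
        compute_tv = n <= 5000
    tv = None
    if compute_tv:
        exact = pb_pmf(p)
        tv = float(0.5 * np.abs(pmf - exact.pmf).sum())
    return CountDistribution(pmf=pmf, mean=lam, variance=float((p * (1 - p)).sum()), tv_to_exact=tv)
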