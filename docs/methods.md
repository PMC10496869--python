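# Methods

This note documents the statistical model the package implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the numerical conventions.

## The observed-vs-expected framework

The null hypothesis is that the incidence rate of each disease is the same
whether or not the individual has other, different diseases.  The analysis
proceeds in three stages.

**1. Disease-free incidence.**  For disease *j*, age at first diagnosis is
modelled by a Weibull survival function S(t|x) = exp(−e^{x'β}(t/L)^k) with
shape k, scale L (years) and log-rate coefficients β for baseline-referenced
indicator covariates.  Fits are by maximum likelihood with left truncation
at study entry (survival to entry is conditioned on, not observed) and
right censoring at the end of follow-up.  The internal parameterization is
θ = (log k, log L, β), which enforces positivity; the covariance of the MLE
is the inverse observed information on this scale, and all delta-method
propagation is chained through it.  On the log scale, s.e.(log k) equals
the quality-control ratio s.e.(k)/k exactly (first order).

**2. Expected counts.**  Each individual in disease *j*'s risk set
contributes p_ij = S(entry) − S(exit), the probability of a first onset
inside their study window, evaluated at the MLE.  The count N_j is a sum of
independent non-identical Bernoulli variables, i.e. Poisson-Binomial, with
E[N_j] = Σp_ij and Var[N_j] = Σp_ij(1−p_ij).  By the law of total variance,
the estimation variances σ_ij² of the p̂_ij cancel from Var[N_j]; they are
accumulated only for quality control.  Reported intervals are the normal
approximation mean ± 1.96·√Var (an exact quantile interval from the exact
PMF is available as an option).

**3. Cross-disease synthesis.**  Diseases failing QC (s.e.(x)/x > 0.5 for
x ∈ {k, L}; non-numeric delta-method output; Σσ²/N ≥ 0.05 — treated as a
hard exclusion; the threshold config is `QCThresholds`) are dropped, then
diseases whose observed first-in-chapter count deviates from the prediction
by more than 4·√Var are excluded as outliers (under the null, ≥99.9% of
adequately powered diseases survive this rule; the acceptance suite
verifies this).  A through-origin least-squares fit of observed on expected
counts gives the excess multiplier b = Σxy/Σx² with s.e. s/√Σx²,
s² = Σ(y−bx)²/(n−1), uncentered R² = 1 − RSS/Σy², and the prediction band
ŷ(x0) ± t_{n−1}·s·√(1+x0²/Σx²).  Subgroup multipliers recompute expected
and observed counts within the subgroup from the same fitted models.
Equality of two estimates is tested with (b₁−b₂) ~ N(0, se₁²+se₂²);
standard errors for literature values are recovered from printed 95%
intervals as (high−low)/3.92.

## The plug-in approximation and its domain of validity

p_ij = S(entry) − S(exit) is the *unconditional* probability of onset in
the window, while risk-set members are known disease-free at entry, whose
conditional risk is (S(entry)−S(exit))/S(entry).  The framework therefore
relies on S(entry) ≈ 1 — diseases must be individually rare, exactly the
p_ij ≪ 1 regime in which the Poisson-Binomial also approaches a Poisson
law.  This is an excellent approximation for individually rare hospital
diagnoses in a large cohort but degrades for common diseases: a disease
with a 2% cumulative hazard by entry age inflates observed/expected by
≈2%, which is material once slope confidence intervals are of the same
order.  The synthetic generator is therefore parameterized by rarity (see
below) so that its study conditions respect this assumption, and the null
calibration of the slope is verified under those conditions.

## Which events "estimate disease-free incidence"

The fitted models are meant to describe incidence *without prior disease*,
but fitting them to all first onsets of a disease would let them absorb
whatever excess prior disease causes, erasing the observed-vs-expected
contrast.  `RunConfig.conditioning` controls which events enter the fits:

- `"any"` (default): the fitting event for disease *j* is an onset of *j*
  that is the individual's first disease onset overall; records are
  censored at the first onset of any other disease, and individuals with
  any pre-study onset contribute no fitting records.  This realises the
  disease-free estimand exactly; under the null the censoring is
  independent, so the fit is unbiased for the marginal hazard.
- `"chapter"`: conditioning at ICD-10 chapter level — the event is a
  first-in-chapter onset, censoring at the first same-chapter onset.  This
  is the practical convention of hospital-record analyses, where a chapter
  is broad enough to proxy disease-freeness; with the generator's small
  disease-per-chapter counts it is a weak proxy and absorbs part of the
  excess.
- `"none"`: first onset of the disease itself, censored only at the end of
  follow-up — no conditioning on other diseases.

Expected and observed counts are always computed on the disease's own risk
set (no pre-study report of that disease; no prior cancer other than
non-melanoma skin cancer or serious cardiovascular disease, unless the
sensitivity flags retain them) over the full entry-to-exit window, so the
conditioning choice affects only the fitting stage.

Two observed series are always reported: all cases (distinct individuals
with an in-window primary diagnosis of the disease) and FIC cases (those
for whom it was the first in-window primary diagnosis in its chapter).  The
4-sd outlier rule uses the FIC series; the headline slope defaults to the
all-cases series (`RunConfig.y_series`).  FIC ties — two same-chapter
onsets at the same age — both count as FIC, preserving symmetry.

## The synthetic generator

`SimConfig` defaults define the emulated study: 50,000 individuals entering
at ages uniform on 40–70 with 10 years of follow-up; sex assigned 50/50;
categorical risk factors with the baselines never-smoked, no diabetes,
sometimes-drink, min deprivation, degree education, mid BMI, min height
(HRT and parity available as women-only factors); 20 diseases assigned
round-robin to 8 ICD-10-style chapters; 3% of individuals flagged with
pre-study cancer and 3% with pre-study CVD (excluded by default, retained
under the sensitivity flags).

Per-disease Weibull shapes are drawn uniformly on (4, 6).  Rarity, not the
scale, is the primitive: each disease draws a cumulative baseline hazard at
the oldest entry age uniformly on (0.002, 0.01) and the scale L is solved
from it.  This keeps every disease — whatever its shape — in the p ≪ 1,
S(entry) ≈ 1 regime the method assumes, and yields expected counts of
roughly 50–500 per disease at the default cohort size.  Covariate effects
are sparse: each disease receives `n_beta_per_disease` nonzero log-rate
coefficients drawn N(0, 0.2²).

Onset ages are sampled exactly by inversion of the cumulative hazard: an
exponential deviate E gives t0 = H⁻¹(E) per disease.  The excess mechanism
is a single multiplicative factor m on the hazards of all not-yet-onset
diseases from the age of the individual's first onset (one changepoint;
later onsets do not compound), solved by inversion of the piecewise
cumulative hazard.  Consequences, all tested: the first onset age is
pathwise unchanged by m; m = 1 reduces exactly to independent diseases;
m = 0 extinguishes all subsequent disease.  Optional group multipliers
(pandas query → factor) scale m for subgroups, which is how Table-style
subgroup contrasts are exercised.  Onsets are simulated from birth, so
onsets before entry become pre-study reports in the event table and
exercise the risk-set exclusions.

**What the generator does not emulate.**  Death and other competing risks
(follow-up is administrative only), secular and year-of-birth trends in
diagnosis, diagnostic dependence between diseases beyond the single
multiplier, medication effects, repeat admissions, and the sheer breadth of
real morbidity: with 20 rare diseases, only a small fraction of person-time
is spent after a first onset, so a generative m = 1.5 produces an
observed/expected slope of ~1.05, not 1.5.  A real cohort carrying
hundreds of candidate diseases exposes far more person-time to the
multiplier, which is how a much larger aggregate excess arises from the
same mechanism.  Passing tests therefore demonstrate calibration and
recovery of the mechanism — null slope coverage, monotonicity in m,
parameter recovery — not the magnitude of any real-world excess.

## Numerical choices

- Exact Poisson-Binomial PMF by iterative convolution DP
  (P_k ← P_k(1−p) + P_{k−1}p), O(n²), exact to round-off; guarded by a
  configurable size bound with the truncated, renormalized Poisson
  approximation (and its total-variation distance to the exact PMF) for
  large sparse problems.  Probabilities within 1e-12 of [0, 1] are clipped;
  larger violations raise.
- Weibull fits: BFGS with the analytic score, started from
  profile-likelihood initial values (for trial shapes the scale MLE is
  closed-form; the two best-scoring starts are polished).  Convergence
  requires score max-norm < 1e-6 per event; the Hessian is central
  differences of the analytic score; a non-PSD or singular information
  matrix marks the fit failed, which QC later excludes.
- Delta-method gradients of p_ij are analytic and vectorized; tiny negative
  quadratic forms (round-off) are floored at zero.
- Through-origin regression is unweighted (homoscedastic) OLS, matching the
  prediction-interval convention; a variance-weighted variant would be a
  natural extension but is not the default.  z = 1.96 exactly at the 95%
  level, by convention.
- Diseases with fewer than `min_events` (default 25) fitting events are
  skipped before fitting; fewer than 2 retained points make the slope
  unavailable rather than degenerate.
- All simulation is driven by `numpy.random.default_rng` seeds carried in
  the configs; identical seeds give byte-identical output tables.

## Problem sizes used in the test suite

Acceptance checks run at desk scale, chosen so each statistical property is
adequately powered: interval coverage over 500–1000 simulated diseases with
expected counts near 100; the 4-sd retention rate over 5,000–10,000
diseases; Weibull recovery at ≥2,000 events; null slope coverage over 100
seeded studies of 30,000 individuals and 10 diseases; multiplier
monotonicity across m ∈ {1, 1.25, 1.5, 2} with common random numbers
(pathwise monotone counts make this a sharp test).

## Known limitations

- The package fits each sex's cohort separately by restriction (pass the
  sex-filtered cohort), rather than modelling sex as a covariate.
- The `"chapter"` conditioning mode approximates the disease-free estimand
  only as well as chapters are broad; with few diseases per chapter it
  under-detects excess (documented above, by design).
- Expected counts use the plug-in unconditional p_ij; for diseases common
  by entry age this under-predicts by ≈1/S(entry) (see "domain of
  validity").
- The exact PMF is quadratic in cohort size; beyond ~10⁵ trials use the
  Poisson approximation (whose error is reported).
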