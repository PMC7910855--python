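# Methods

## The distribution family

The package is built around a single construction: wrap a baseline CDF
`G` with the logistic kernel,

    F(x) = G(x)^λ / ( G(x)^λ + (1 − G(x))^λ ),        λ > 0.

The construction preserves symmetry of the baseline and adds one shape
parameter. With the normal baseline `G = Φ((x − μ)/σ)` this is the
**logistic-normal** law LN(μ, σ, λ):

* symmetric about μ, so mean = median = μ for every λ;
* exactly N(μ, σ²) at λ = 1;
* tails behave like `exp(−λ z²/2) |z|^(λ−1)`, so λ < 1 gives heavier and
  λ > 1 lighter tails than the normal;
* for λ below roughly 0.5 the density develops two modes placed
  symmetrically about μ, with μ a local minimum.

Raising the LN CDF to a power α > 0 gives the **skew logistic-normal**
(skew-LN), which adds quantile-based skewness while keeping a closed-form
CDF and quantile; α = 1 recovers LN, λ = 1 recovers the exponentiated
(power-) normal, and α = λ = 1 the normal.

An equivalent stochastic representation drives sampling: if T follows a
logistic distribution with rate λ (density `λ e^{−λt}(1+e^{−λt})^{−2}`,
variance π²/(3λ²)), then `μ + σ Φ⁻¹(expit(T))` is LN(μ, σ, λ). Skew-LN
variates come from the closed quantile `Q(p) = Q_LN(p^{1/α})` by inverse
transform.

## Numerical evaluation

All probability arithmetic is done in log space: `log Φ` via `log_ndtr`,
and the recurring term `log(Φ^λ + (1−Φ)^λ)` as a two-term log-sum-exp of
`λ·logΦ` and `λ·log(1−Φ)`. This matters because fitted λ values in the
hundreds occur in practice (the location-scale regression drifts there on
real data), and |z| up to ~40 must not underflow. Quantiles use
`ndtri_exp(log_expit(·))` so probabilities far below the double floor of
`expit` still give finite results.

Other numerical choices:

* **Modes.** The printed stationarity condition is re-derived as
  `d/dz log f = −z + (λ−1)φ(1/Φ − 1/(1−Φ)) − 2λφ(Φ^{λ−1} − (1−Φ)^{λ−1}) /
  (Φ^λ + (1−Φ)^λ)`, evaluated on a 4001-point grid over z ∈ [−12, 12];
  down-crossings are bracketed and polished by Brent to 1e−10. z = 0 is
  always stationary; a symmetric pair of maxima is reported for the
  bimodal regime.
* **Moments.** `E[X^r] = Σ_j C(r,j) 2^{j/2} σ^j μ^{r−j} ξ_j` with
  `ξ_j = E[erfinv(tanh(T/2))^j]` for T logistic(rate λ). After the
  substitution u = F_T(t) the integral runs over (0, 1) with only
  square-root-logarithmic endpoint growth; adaptive quadrature at
  absolute tolerance 1e−10, with the reported error estimate checked.
  Odd ξ_j vanish by symmetry.
* **Shape measures.** Galton skewness `(Q₃ + Q₁ − 2Q₂)/(Q₃ − Q₁)` and
  Moors octile kurtosis `(E₇ − E₅ + E₃ − E₁)/(E₆ − E₂)` (the standard
  sign on E₁; only this form gives 1.2331 for the normal and brackets the
  skew-normal range). The Azzalini skew-normal reference family is
  evaluated through `scipy.stats.skewnorm`; its shape → ∞ limit, the
  half-normal with `Q(p) = Φ⁻¹((1+p)/2)`, is used in closed form.

## Maximum likelihood

Initial values are moment-based: μ₀ = x̄, σ₀ = s (n−1 denominator), and
λ₀ = π/(√3 s_T) where s_T is the SD of `t_i = logit(Φ((x_i − x̄)/s))` —
under the model the t_i are logistic with rate λ, so matching the
logistic variance π²/(3λ²) to the sample variance of the t_i identifies
λ₀. For the skew fit α₀ = 1.

**The λ → ∞ boundary.** The family degenerates: LN(μ, σ, λ) with
σ/λ held proportional converges to a logistic distribution. The profile
likelihood in λ therefore has a finite asymptote — the logistic-MLE
log-likelihood — and for an appreciable fraction of small-sample data
sets it climbs monotonically toward that asymptote, so no interior MLE
exists. Two consequences for the fitting policy:

1. The LN optimizer is deliberately **local**: it ascends the profile
   likelihood in log λ from λ₀ with a fixed step, brackets the first
   interior maximum, polishes it (bounded Brent, then a joint quasi-Newton
   step over all three parameters). Plain quasi-Newton from the same
   start occasionally tunnels across a shallow dip onto the flat ridge
   and reports an arbitrary stalling point on it.
2. A fitted LN counts as **converged** only if (a) the profile ascent
   bracketed an interior maximum, (b) the numeric gradient norm at the
   optimum is below 1e−5·max(1, |ℓ|), and (c) the maximized likelihood
   strictly exceeds the boundary supremum, i.e. the logistic MLE
   log-likelihood of the same sample. Condition (c) is an existence
   check: when the 3-parameter fit cannot beat the 2-parameter limit
   law, λ is not identified and the reported stationary point is not a
   global interior maximizer.

Standard errors come from the inverse central-difference Hessian of −ℓ in
the original (λ, μ, σ[, α]) parameterization (relative step 1e−4);
AIC = 2k − 2ℓ, AICC = AIC + 2k(k+1)/(n−k−1), BIC = k log n − 2ℓ.

The skew-LN univariate fit optimizes (log λ, μ, log σ, log α) by L-BFGS-B
with a deterministic multiplicative-jitter restart ladder (factor 1.5 on
the shape parameters, up to 10 restarts, best optimum kept).

The two-component normal-mixture baseline is fitted by EM
(π, μ₁, μ₂, σ₁, σ₂): a deterministic median-split start plus random-
responsibility restarts, component-collapse detection, and the
per-iteration log-likelihood trace retained for monotonicity checks.

## Monte-Carlo estimator study

The harness draws `replications` independent LN samples per design cell
(n, λ, μ, σ), fits each by the policy above, and reports per-parameter
relative bias `(mean(θ̂) − θ)/θ` and the SD of the estimates. Estimates
from non-converged fits — including λ̂ outside [1e−3, 1e3] — are dropped
and counted; a cell losing more than 20% carries a warning. All
randomness descends from one master seed through spawned per-replication
streams, so reports are byte-identical across runs and cells are
independently reproducible. The default replication count is 2,000; the
acceptance script uses exactly that with cells (n=30, λ=0.5, μ=2, σ=1)
and (n=70, λ=1.5, μ=2, σ=1); the test suite adds a 400-replication
n-column for trend checks and small smoke cells.

A caveat the study makes visible: even conditional on convergence, the
sampling distributions of λ̂ and σ̂ are strongly heavy-tailed in these
small-sample cells (interior maxima at λ̂ ~ 10–20 occur with
non-negligible probability and genuinely beat the boundary). Mean-based
relative bias and SDs are therefore themselves high-variance summaries,
and weak identifiability of λ near the logistic limit is an intrinsic
feature of the family, not an optimizer artifact — it reproduces under
independent implementations (a fresh R implementation of the same
likelihood shows identical monotone profiles).

## Location-scale regression

The model is `y_i = x_i'β + σ Z_i` with i.i.d. Z_i ~ skew-LN(0, 1, λ, α).
Freezing shapes yields the nested ladder normal (α=λ=1) ⊂ {LN (α=1),
Exp-N (λ=1)} ⊂ skew-LN, with k = p+2, p+3, p+3, p+4 free parameters.
Covariates are standardized by default (mean 0, SD 1, n−1 denominator),
the centering pairs stored so predictions are issued on the raw scale.
β and σ initialize at OLS, shapes at 1; optimization is L-BFGS-B over
(β, log σ, log λ, log α) with |log λ|, |log α| ≤ 15 — generous because
real fits put λ̂ in the hundreds — and an optimum pinned at a bound is
flagged non-converged. Wald p-values use the standard-normal reference;
LR statistics `2(ℓ_full − ℓ_reduced)` use the χ² reference with df equal
to the number of frozen shape parameters (all nulls here are interior
points, so no boundary correction is needed).

## Synthetic data

Generators mirror the model assumptions exactly: univariate LN/skew-LN
samples by inverse transform, mixtures by component indicator draws, and
regression sets with i.i.d. standard-normal covariates and
skew-LN(0,1,λ,α) errors. They emulate the distributional shape of real
use-cases (bimodality for small λ, skewed responses) but none of the
messiness of real data — dependent or discrete covariates,
heteroscedasticity, outliers, measurement error — so green tests certify
the algorithms under the model, not robustness off the model. The two
real applications this methodology targets (a bimodal environmental
series; a housing-valuation table with n = 414 and five covariates) are
external data sets the package reads from user-supplied CSV paths; the
test suite uses a synthetic stand-in of the same dimensions.

## Known limitations

* λ is weakly identified whenever the sample resembles a logistic law;
  in small samples the MLE fails to exist with appreciable probability
  (reported honestly as non-convergence).
* The mixture EM reports plain observed-information SEs, which are known
  to be optimistic near weakly separated components.
* The K-S statistic is reported descriptively with estimated parameters;
  no Lilliefors-style correction is applied.
* Moment-based skewness/kurtosis for the skew-LN are not implemented;
  the quantile-based measures cover the family's whole parameter range,
  including bimodal members.
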