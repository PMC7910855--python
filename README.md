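# logisnorm

Flexible generalizations of the normal distribution for biostatistical and
environmental data whose residuals are *not* normal: heavy- or light-tailed,
skewed, or outright bimodal. The package implements the **logistic-normal
(LN)** and **skew logistic-normal (skew-LN)** families, maximum-likelihood
fitting with honest convergence diagnostics, a Monte-Carlo harness for
estimator performance, and a **location-scale regression model with skew-LN
errors** whose nested sub-models (LN, exponentiated-normal, normal) support
likelihood-ratio tests and AIC/AICC/BIC comparison. It is aimed at applied
statisticians who would otherwise reach for mixture models or ad-hoc
transformations when a Q-Q plot goes wrong.

## The model

Wrapping a baseline CDF G with a logistic kernel gives the one-parameter
family

    F(x) = G(x)^λ / ( G(x)^λ + (1 − G(x))^λ ),   λ > 0.

With G = Φ((x−μ)/σ) this is LN(μ, σ, λ): symmetric about μ, exactly normal
at λ = 1, tails ∝ exp(−λz²/2)|z|^{λ−1}, and bimodal for λ ≲ 0.5. Raising
the LN CDF to a power α > 0 yields the skew-LN, with closed-form CDF and
quantile Q(p) = μ + σ Φ⁻¹( expit( logit(p^{1/α}) / λ ) ).

The regression model is `y_i = x_i'β + σ Z_i` with Z_i ~ skew-LN(0, 1, λ, α);
setting α = 1, λ = 1, or both recovers the LN, exponentiated-normal and
ordinary Gaussian regression models, so 2(ℓ_full − ℓ_reduced) is χ²-tested
with df equal to the number of frozen shape parameters.

See `docs/methods.md` for the numerical policies (log-space evaluation, the
λ → ∞ logistic boundary and the MLE-existence guard, quadrature choices).

## Worked example

Fit LN to a bimodal sample and compare it with a two-component normal
mixture (the classical alternative):

```python
import logisnorm as lg

x = lg.ln_rvs(500, lg.LNParams(lam=0.3, mu=10.6, sigma=0.65), seed=7)

fit = lg.fit_ln(x)
print(fit.estimates)   # {'lam': 0.2826, 'mu': 10.6157, 'sigma': 0.6112}
print(fit.std_errors)  # {'lam': 0.0570, 'mu': 0.0592, 'sigma': 0.0793}
print(round(fit.loglik, 2), round(fit.aic, 2))   # -915.05 1836.09

params = lg.LNParams(**fit.estimates)
print(round(lg.ks_statistic(x, lambda v: lg.ln_cdf(v, params)), 4))  # 0.0314
print(lg.ln_modes(params))
# ModeResult(modes=(9.4277, 11.8037), is_bimodal=True)

mix = lg.fit_normal_mixture(x, seed=0)
print(round(mix.aic, 2))  # 1839.22  -- three LN parameters beat five
```

The fitted shape λ̂ = 0.28 < 0.5 correctly identifies the bimodal regime,
the K-S statistic 0.031 indicates a close fit, and the LN wins the AIC
comparison against the five-parameter mixture (1836.1 vs 1839.2).

Estimator-style interfaces compose with scikit-learn:

```python
model = lg.SkewLNRegression(model="skew-ln").fit(X, y)   # RegressorMixin
model.coef_, model.sigma_, model.lam_, model.alpha_, model.pvalues_
```

and a CLI covers the same operations (`logisnorm sample`, `fit-dist`,
`fit-regression`, `simulate`, `shape-surface`).

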