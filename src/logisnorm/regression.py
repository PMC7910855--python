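"""Skew-LN location-scale regression and its nested sub-models.

The model is ``y_i = x_i' beta + sigma Z_i`` with i.i.d. errors
``Z_i ~ skew-LN(0, 1, lam, alpha)``.  Freezing shape parameters yields the
nested ladder

    normal (alpha = lam = 1)  <  LN (alpha = 1), Exp-N (lam = 1)  <  skew-LN,

so likelihood-ratio tests against chi-square references and AIC/AICC/BIC
comparisons are available for every pair on a chain.  Covariates are
standardized by default (mean 0, SD 1, n-1 denominator) with the centering
pairs stored so predictions can be issued on the raw scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import _numdiff
from .distributions import SkewLNParams, skew_ln_logpdf
from .errors import (
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    NotNestedError,
)
from .estimation import FitResult, information_criteria

__all__ = [
    "RegressionData",
    "RegressionFit",
    "LRTestResult",
    "ModelComparison",
    "build_regression_data",
    "regression_loglik",
    "fit_regression",
    "lr_test",
    "compare_models",
    "SkewLNRegression",
]

#: constraint map: model tag -> (lam free?, alpha free?)
MODEL_TAGS = {
    "skew-ln": (True, True),
    "ln": (True, False),
    "exp-n": (False, True),
    "normal": (False, False),
}

#: models strictly nested inside each tag (for LR tests)
_NESTED_IN = {
    "skew-ln": {"ln", "exp-n", "normal"},
    "ln": {"normal"},
    "exp-n": {"normal"},
    "normal": set(),
}

_LOG_SHAPE_BOUND = 15.0  # |log lam|, |log alpha| bound; hitting it flags failure


@dataclass(frozen=True)
class RegressionData:
    """Response vector, design matrix (intercept first) and the
    standardization (mean, SD) pairs applied to each covariate column."""

    y: np.ndarray
    X: np.ndarray
    names: tuple
    standardization: dict | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DomainError("design matrix must be n x (p+1) matching the response")
        if not np.allclose(X[:, 0], 1.0):
            raise DomainError("first design column must be the intercept (all ones)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDataError("design matrix is rank deficient")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def build_regression_data(
    frame: pd.DataFrame,
    response: str,
    covariates: list[str] | None = None,
    standardize: bool = True,
) -> RegressionData:
    """Assemble a RegressionData from a data frame, adding the intercept and
    (optionally) standardizing each covariate to mean 0, SD 1."""
    if response not in frame.columns:
        raise DomainError(f"response column {response!r} not found")
    if covariates is None:
        covariates = [c for c in frame.columns if c != response]
    y = frame[response].to_numpy(dtype=float)
    cols, scaling = [], {}
    for name in covariates:
        col = frame[name].to_numpy(dtype=float)
        if standardize:
            mean, sd = float(np.mean(col)), float(np.std(col, ddof=1))
            if sd <= 0.0:
                raise DegenerateDataError(f"covariate {name!r} is constant")
            col = (col - mean) / sd
            scaling[name] = (mean, sd)
        cols.append(col)
    X = np.column_stack([np.ones_like(y)] + cols)
    names = ("intercept", *covariates)
    return RegressionData(y=y, X=X, names=names,
                          standardization=scaling if standardize else None)


def regression_loglik(data: RegressionData, beta, sigma: float, lam: float,
                      alpha: float) -> float:
    """Log-likelihood of the skew-LN location-scale regression; identical to
    the sum of skew-LN log-densities at mu_i = x_i' beta."""
    beta = np.asarray(beta, dtype=float)
    if beta.size != data.n_coef:
        raise DomainError("beta length does not match the design matrix")
    z = (data.y - data.X @ beta) / sigma
    return float(np.sum(skew_ln_logpdf(z, SkewLNParams(lam, 0.0, 1.0, alpha))) -
                 data.n * math.log(sigma))


@dataclass(frozen=True)
class RegressionFit:
    """Fitted location-scale regression for one model tag."""

    model: str
    beta: np.ndarray
    sigma: float
    lam: float
    alpha: float
    names: tuple
    estimates: dict
    std_errors: dict | None
    pvalues: dict | None
    loglik: float
    aic: float
    aicc: float
    bic: float
    n: int
    k: int
    converged: bool
    n_restarts_used: int = 0
    message: str = ""

    def predict(self, X_design: np.ndarray) -> np.ndarray:
        return np.asarray(X_design, dtype=float) @ self.beta


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of a reduced model nested inside a full model."""

    statistic: float
    df: int
    p_value: float
    hypothesis: str


@dataclass
class ModelComparison:
    """All nested fits plus IC and LR summary tables."""

    fits: dict
    ic_table: pd.DataFrame
    lr_table: pd.DataFrame
    errors: dict = field(default_factory=dict)


def _pack(free_lam: bool, free_alpha: bool, beta, log_sigma, log_lam, log_alpha):
    theta = list(beta) + [log_sigma]
    if free_lam:
        theta.append(log_lam)
    if free_alpha:
        theta.append(log_alpha)
    return np.asarray(theta, dtype=float)


def _unpack(theta, p1, free_lam, free_alpha):
    beta = theta[:p1]
    log_sigma = theta[p1]
    idx = p1 + 1
    log_lam = theta[idx] if free_lam else 0.0
    if free_lam:
        idx += 1
    log_alpha = theta[idx] if free_alpha else 0.0
    return beta, log_sigma, log_lam, log_alpha


def fit_regression(data: RegressionData, model: str = "skew-ln",
                   n_restarts: int = 10, compute_se: bool = True) -> RegressionFit:
    """Fit one model tag by maximizing the location-scale log-likelihood.

    beta and sigma start at their ordinary-least-squares values; free shape
    parameters start at 1.  Optimization runs on (beta, log sigma, log lam,
    log alpha) with the shape logs bounded to +-15; an optimum pinned at a
    bound is reported as non-converged.
    """
    if model not in MODEL_TAGS:
        raise DomainError(f"unknown model tag {model!r}")
    free_lam, free_alpha = MODEL_TAGS[model]
    p1 = data.n_coef
    if data.n <= p1 + 3:
        raise DomainError("too few observations for the number of coefficients")

    beta_ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    resid = data.y - data.X @ beta_ols
    sigma_ols = max(float(np.std(resid, ddof=p1)), 1e-12)

    _BIG = 1e12

    def objective(theta):
        beta, ls, ll_, la_ = _unpack(theta, p1, free_lam, free_alpha)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                value = regression_loglik(data, beta, math.exp(ls), math.exp(ll_),
                                          math.exp(la_))
        except (OverflowError, FloatingPointError, ValueError):
            return _BIG
        return -value if math.isfinite(value) else _BIG

    theta0 = _pack(free_lam, free_alpha, beta_ols, math.log(sigma_ols), 0.0, 0.0)
    bounds = [(None, None)] * p1 + [(None, None)]
    bounds += [(-_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND)] * (int(free_lam) + int(free_alpha))

    best = None
    n_used = 0
    for attempt in range(n_restarts + 1):
        start = theta0.copy()
        if attempt > 0:
            shift = math.log(1.5) * (((attempt + 1) // 2) * (1 if attempt % 2 else -1))
            for j in range(p1 + 1, start.size):
                start[j] += shift
            n_used = attempt
        res = optimize.minimize(objective, start, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
        if best.success and math.isfinite(best.fun):
            break
    if best is None or not math.isfinite(best.fun):
        raise ConvergenceError(f"{model} regression failed to reach a finite optimum")

    beta, ls, ll_, la_ = _unpack(best.x, p1, free_lam, free_alpha)
    sigma, lam, alpha = math.exp(ls), math.exp(ll_), math.exp(la_)
    at_bound = any(
        abs(v) > _LOG_SHAPE_BOUND - 1e-6
        for v in best.x[p1 + 1:]
    )
    loglik = -float(best.fun)
    converged = bool(best.success) and not at_bound

    names = list(data.names) + ["sigma"]
    values = list(beta) + [sigma]
    if free_lam:
        names.append("lam")
        values.append(lam)
    if free_alpha:
        names.append("alpha")
        values.append(alpha)
    estimates = dict(zip(names, values))

    std_errors = pvalues = None
    if compute_se:
        def negll_orig(p):
            b = p[:p1]
            s = p[p1]
            idx = p1 + 1
            lam_v = p[idx] if free_lam else 1.0
            if free_lam:
                idx += 1
            alpha_v = p[idx] if free_alpha else 1.0
            if s <= 0.0 or lam_v <= 0.0 or alpha_v <= 0.0:
                return float("inf")
            try:
                return -regression_loglik(data, b, s, lam_v, alpha_v)
            except (OverflowError, FloatingPointError):
                return float("inf")

        cov = _numdiff.covariance_from_hessian(
            _numdiff.hessian(negll_orig, np.asarray(values)))
        if cov is not None:
            se = np.sqrt(np.diag(cov))
            std_errors = dict(zip(names, se))
            pvalues = dict(zip(names, 2.0 * stats.norm.sf(np.abs(np.asarray(values) / se))))

    k = p1 + 1 + int(free_lam) + int(free_alpha)
    aic, aicc, bic = information_criteria(loglik, k, data.n)
    return RegressionFit(
        model=model, beta=np.asarray(beta), sigma=sigma, lam=lam, alpha=alpha,
        names=tuple(names), estimates=estimates, std_errors=std_errors,
        pvalues=pvalues, loglik=loglik, aic=aic, aicc=aicc, bic=bic,
        n=data.n, k=k, converged=converged, n_restarts_used=n_used,
        message=str(best.message),
    )


def lr_test(full: RegressionFit, reduced: RegressionFit) -> LRTestResult:
    """Likelihood-ratio test: 2 (l_full - l_reduced) against chi-square with
    df = difference in free-parameter counts."""
    if reduced.model not in _NESTED_IN[full.model]:
        raise NotNestedError(f"{reduced.model!r} is not nested in {full.model!r}")
    if full.n != reduced.n:
        raise NotNestedError("fits were obtained on different sample sizes")
    statistic = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = full.k - reduced.k
    p_value = float(stats.chi2.sf(statistic, df))
    constraints = {
        ("skew-ln", "ln"): "alpha = 1",
        ("skew-ln", "exp-n"): "lam = 1",
        ("skew-ln", "normal"): "alpha = lam = 1",
        ("ln", "normal"): "lam = 1",
        ("exp-n", "normal"): "alpha = 1",
    }
    hypothesis = f"H0: {constraints[(full.model, reduced.model)]}"
    return LRTestResult(statistic=statistic, df=df, p_value=p_value,
                        hypothesis=hypothesis)


_LR_PAIRS = [("skew-ln", "ln"), ("skew-ln", "exp-n"), ("skew-ln", "normal"),
             ("ln", "normal")]


def compare_models(data: RegressionData,
                   models=("skew-ln", "ln", "exp-n", "normal"),
                   n_restarts: int = 10) -> ModelComparison:
    """Fit the nested model family and tabulate IC values and LR tests.

    A model whose optimization fails is recorded in ``errors`` and the
    remaining fits are still produced.
    """
    fits, errors = {}, {}
    for tag in models:
        try:
            fits[tag] = fit_regression(data, model=tag, n_restarts=n_restarts)
        except ConvergenceError as exc:
            errors[tag] = str(exc)

    ic_rows = [
        {"model": tag, "neg_loglik": -fit.loglik, "k": fit.k, "aic": fit.aic,
         "aicc": fit.aicc, "bic": fit.bic, "converged": fit.converged}
        for tag, fit in fits.items()
    ]
    lr_rows = []
    for full_tag, reduced_tag in _LR_PAIRS:
        if full_tag in fits and reduced_tag in fits:
            res = lr_test(fits[full_tag], fits[reduced_tag])
            lr_rows.append({
                "full": full_tag, "reduced": reduced_tag,
                "hypothesis": res.hypothesis, "statistic": res.statistic,
                "df": res.df, "p_value": res.p_value,
            })
    return ModelComparison(
        fits=fits,
        ic_table=pd.DataFrame(ic_rows),
        lr_table=pd.DataFrame(lr_rows),
        errors=errors,
    )


class SkewLNRegression(RegressorMixin, BaseEstimator):
    """Location-scale regression with skew-LN errors, scikit-learn style.

    ``fit(X, y)`` standardizes the covariates (optionally), maximizes the
    likelihood for the requested model tag, and exposes ``coef_``,
    ``intercept_``, ``sigma_``, ``lam_``, ``alpha_``, ``se_``, ``pvalues_``
    and the information criteria; ``predict(X)`` returns the fitted linear
    predictor on the raw covariate scale.

    Parameters
    ----------
    model : {"skew-ln", "ln", "exp-n", "normal"}
        Which member of the nested family to fit.
    standardize : center/scale covariates before fitting (coefficients are
        reported on the standardized scale, predictions on the raw scale).
    """

    def __init__(self, model: str = "skew-ln", standardize: bool = True,
                 n_restarts: int = 10, compute_se: bool = True):
        self.model = model
        self.standardize = standardize
        self.n_restarts = n_restarts
        self.compute_se = compute_se

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        names = [f"x{j + 1}" for j in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=names)
        frame["y"] = y
        self.data_ = build_regression_data(frame, "y", names,
                                           standardize=self.standardize)
        fit = fit_regression(self.data_, model=self.model,
                             n_restarts=self.n_restarts,
                             compute_se=self.compute_se)
        self.result_ = fit
        self.beta_ = fit.beta
        self.intercept_ = float(fit.beta[0])
        self.coef_ = fit.beta[1:].copy()
        self.sigma_ = fit.sigma
        self.lam_ = fit.lam
        self.alpha_ = fit.alpha
        self.se_ = fit.std_errors
        self.pvalues_ = fit.pvalues
        self.loglik_ = fit.loglik
        self.aic_, self.aicc_, self.bic_ = fit.aic, fit.aicc, fit.bic
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise DomainError("feature count differs from the fitted design")
        cols = []
        for j in range(X.shape[1]):
            col = X[:, j]
            if self.data_.standardization is not None:
                mean, sd = self.data_.standardization[f"x{j + 1}"]
                col = (col - mean) / sd
            cols.append(col)
        return np.column_stack([np.ones(X.shape[0])] + cols)

    def predict(self, X):
        return self._design(X) @ self.beta_
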