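"""Maximum-likelihood fitting of LN and skew-LN distributions to
univariate samples, plus the Kolmogorov-Smirnov statistic and a
two-component normal-mixture EM baseline.

Optimization runs unconstrained quasi-Newton (L-BFGS-B) on transformed
parameters (log lam, mu, log sigma[, log alpha]) starting from moment-based
initial values: mu0 = sample mean, sigma0 = sample SD, and lam0 obtained by
mapping the standardized sample through the logit-of-Phi transform — under
the model the transformed values follow a logistic law with rate lam and
variance pi^2 / (3 lam^2), so matching that variance to the sample variance
of the transformed values gives lam0 = pi / (sqrt(3) s_T).  Failed starts
are retried with multiplicative jitter on the shape parameters, keeping the
best optimum found.  Standard errors come from the inverse central-
difference Hessian of the negative log-likelihood in the original
parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr
from sklearn.base import BaseEstimator

from . import _numdiff
from .distributions import (
    LNParams,
    SkewLNParams,
    _ln_log_terms,
    ln_logpdf,
    ln_quantile,
    ln_rvs,
    skew_ln_logpdf,
    skew_ln_quantile,
    skew_ln_rvs,
)
from .errors import ConvergenceError, DegenerateDataError, DomainError

__all__ = [
    "FitResult",
    "InitialValues",
    "ln_loglik",
    "ln_initial_values",
    "fit_ln",
    "fit_skew_ln",
    "ks_statistic",
    "fit_normal_mixture",
    "information_criteria",
    "LogisticNormalMLE",
    "SkewLogisticNormalMLE",
    "TwoComponentNormalMixture",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """(AIC, AICC, BIC) from a maximized log-likelihood with k free parameters."""
    aic = 2.0 * k - 2.0 * loglik
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = k * math.log(n) - 2.0 * loglik
    return aic, aicc, bic


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: str
    estimates: dict
    std_errors: dict | None
    loglik: float
    aic: float
    aicc: float
    bic: float
    n: int
    k: int
    converged: bool
    n_restarts_used: int = 0
    grad_norm: float = float("nan")
    message: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "loglik": self.loglik,
            "aic": self.aic,
            "aicc": self.aicc,
            "bic": self.bic,
            "n": self.n,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class InitialValues:
    """Moment-based starting values for the likelihood optimizer."""

    lam0: float
    mu0: float
    sigma0: float
    alpha0: float | None = None


def _as_sample(sample, min_n: int = 1) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < min_n:
        raise DomainError(f"sample must contain at least {min_n} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DomainError("sample contains non-finite values")
    return x


def ln_loglik(sample, params: LNParams) -> float:
    """LN log-likelihood
    ``n log(lam/sigma) + sum log phi + (lam-1) sum [log Phi + log(1-Phi)]
    - 2 sum log(Phi^lam + (1-Phi)^lam)``; identical to the summed log-density.
    """
    x = _as_sample(sample)
    lam, sigma = params.lam, params.sigma
    z = params.standardize(x)
    lp, ln_, lse = _ln_log_terms(z, lam)
    return float(
        x.size * math.log(lam / sigma)
        + np.sum(-0.5 * z * z - _LOG_SQRT_2PI)
        + (lam - 1.0) * np.sum(lp)
        + (lam - 1.0) * np.sum(ln_)
        - 2.0 * np.sum(lse)
    )


def ln_initial_values(sample, skew: bool = False) -> InitialValues:
    """Starting values: mu0 = mean, sigma0 = SD, lam0 = pi / (sqrt(3) s_T)
    with t_i = logit(Phi((x_i - mean)/SD)); alpha0 = 1 for the skew fit."""
    x = _as_sample(sample, min_n=3)
    mu0 = float(np.mean(x))
    sigma0 = float(np.std(x, ddof=1))
    if sigma0 <= 0.0:
        raise DegenerateDataError("sample is constant; shape cannot be initialized")
    z = (x - mu0) / sigma0
    t = log_ndtr(z) - log_ndtr(-z)  # logit(Phi(z)), stable in both tails
    s_t = float(np.std(t, ddof=1))
    if s_t <= 0.0:
        raise DegenerateDataError("transformed sample is constant")
    lam0 = math.pi / (math.sqrt(3.0) * s_t)
    return InitialValues(lam0=lam0, mu0=mu0, sigma0=sigma0, alpha0=1.0 if skew else None)


# ---------------------------------------------------------------------------
# Univariate likelihood optimization
# ---------------------------------------------------------------------------

_LOG_SHAPE_BOUND = 30.0  # |log lam|, |log alpha| cap merely guards overflow


_BIG = 1e12  # finite penalty keeps quasi-Newton line searches well-behaved


def _univariate_negloglik(theta: np.ndarray, x: np.ndarray, skew: bool) -> float:
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            lam = math.exp(theta[0])
            mu = theta[1]
            sigma = math.exp(theta[2])
            if skew:
                ll = float(np.sum(skew_ln_logpdf(x, SkewLNParams(lam, mu, sigma, math.exp(theta[3])))))
            else:
                ll = ln_loglik(x, LNParams(lam, mu, sigma))
    except (OverflowError, FloatingPointError, ValueError):
        return _BIG
    return -ll if math.isfinite(ll) else _BIG


def _profile_ascent(x: np.ndarray, u0: float, inner0: np.ndarray,
                    step: float = 0.25,
                    u_lim: tuple = (math.log(5e-4), math.log(2e3))):
    """Climb the profile log-likelihood in u = log(lam) from u0 to the first
    local maximum; returns (u*, inner*, ll*, bracketed?).

    The inner (mu, log sigma) problem is re-optimized at each u, warm-started
    from its neighbour.  A march that leaves [u_lim] without ever bracketing
    a maximum signals a boundary supremum (lam -> 0 or the logistic lam ->
    inf ridge) and is reported as not bracketed.
    """

    def prof(u, start):
        res = optimize.minimize(
            lambda t: _univariate_negloglik(np.array([u, t[0], t[1]]), x, False),
            start, method="L-BFGS-B",
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 200},
        )
        return -float(res.fun), res.x

    l0, in0 = prof(u0, inner0)
    lp, inp = prof(u0 + step, in0)
    lm, inm = prof(u0 - step, in0)
    if l0 >= lp and l0 >= lm:
        a, c = u0 - step, u0 + step
        u_best, in_best = u0, in0
    else:
        if lp >= lm:
            d, u_prev, l_prev = step, u0, l0
            u_cur, l_cur, in_cur = u0 + step, lp, inp
        else:
            d, u_prev, l_prev = -step, u0, l0
            u_cur, l_cur, in_cur = u0 - step, lm, inm
        while True:
            u_next = u_cur + d
            if not u_lim[0] <= u_next <= u_lim[1]:
                return u_cur, in_cur, l_cur, False
            l_next, in_next = prof(u_next, in_cur)
            if l_next < l_cur:
                break
            u_prev, l_prev = u_cur, l_cur
            u_cur, l_cur, in_cur = u_next, l_next, in_next
        a, c = min(u_prev, u_next), max(u_prev, u_next)
        u_best, in_best = u_cur, in_cur

    res = optimize.minimize_scalar(
        lambda u: -prof(u, in_best)[0], bounds=(a, c), method="bounded",
        options={"xatol": 1e-4},  # the joint polish afterwards refines further
    )
    u_star = float(res.x)
    ll_star, in_star = prof(u_star, in_best)
    return u_star, in_star, ll_star, True


def _fit_univariate(
    sample,
    skew: bool,
    n_restarts: int = 10,
    compute_se: bool = True,
    jitter: float = 1.5,
) -> FitResult:
    min_n = 5 if skew else 4
    x = _as_sample(sample, min_n=min_n)
    init = ln_initial_values(x, skew=skew)
    theta0 = [math.log(init.lam0), init.mu0, math.log(init.sigma0)]
    if skew:
        theta0.append(0.0)  # alpha0 = 1
    theta0 = np.asarray(theta0, dtype=float)

    bounds = [(-_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND), (None, None), (None, None)]
    if skew:
        bounds.append((-_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND))

    def objective(theta):
        return _univariate_negloglik(theta, x, skew)

    best = None
    n_used = 0
    marched_to_boundary = False
    if not skew:
        # The lam direction is treacherous: for some samples the likelihood
        # rises monotonically toward the logistic lam -> inf ridge and no
        # interior MLE exists.  A profile ascent from the moment initializer
        # keeps the fit in the basin the initial values select, exactly the
        # behaviour of a warm-started local trust-region routine.
        u_star, inner, ll_star, bracketed = _profile_ascent(
            x, theta0[0], theta0[1:].copy()
        )
        start = np.array([u_star, inner[0], inner[1]])
        lam_bracket = (u_star - 0.5, u_star + 0.5) if bracketed else (
            u_star - 1e-9, u_star + 1e-9)
        best = optimize.minimize(
            objective, start, method="L-BFGS-B",
            bounds=[lam_bracket, (None, None), (None, None)],
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
        )
        marched_to_boundary = not bracketed
    else:
        # deterministic jitter ladder on the shape parameters: *1.5, /1.5, ...
        for attempt in range(n_restarts + 1):
            start = theta0.copy()
            if attempt > 0:
                shift = jitter ** (((attempt + 1) // 2) * (1 if attempt % 2 else -1))
                start[0] += math.log(shift)
                start[3] += math.log(shift) * (-1) ** attempt
                n_used = attempt
            res = optimize.minimize(
                objective, start, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.success and math.isfinite(best.fun):
                break

    if best is None or not math.isfinite(best.fun):
        raise ConvergenceError("all optimizer restarts failed to produce a finite optimum")

    theta = best.x
    lam, mu, sigma = math.exp(theta[0]), float(theta[1]), math.exp(theta[2])
    names = ["lam", "mu", "sigma"]
    values = [lam, mu, sigma]
    if skew:
        names.append("alpha")
        values.append(math.exp(theta[3]))
    estimates = dict(zip(names, values))

    loglik = -float(best.fun)
    grad = _numdiff.gradient(objective, theta)
    grad_norm = float(np.linalg.norm(grad))
    # a stationary point is what matters; L-BFGS-B may end with an "abnormal"
    # line search once f changes are at rounding level, which is still success
    converged = (not marched_to_boundary
                 and grad_norm < 1e-5 * max(1.0, abs(loglik)))
    std_errors = None
    message = str(best.message)
    if marched_to_boundary:
        message += "; profile ascent left the lam search range (boundary supremum)"

    # MLE-existence guard: as lam -> inf with sigma/lam fixed the LN family
    # collapses onto a logistic distribution, and for some samples the
    # likelihood climbs monotonically toward (or above) that boundary, so the
    # interior stationary point is not the global maximizer and the MLE does
    # not exist.  A converged fit must beat the boundary supremum, which is
    # exactly the logistic MLE log-likelihood.
    if not skew:
        from scipy import stats as _stats

        loc_l, scale_l = _stats.logistic.fit(x)
        ll_boundary = float(np.sum(_stats.logistic.logpdf(x, loc_l, scale_l)))
        if ll_boundary >= loglik:
            converged = False
            message += "; likelihood supremum on the logistic boundary (lam -> inf)"
    if compute_se:
        def negll_orig(p):
            t = np.array([math.log(p[0]), p[1], math.log(p[2])] +
                         ([math.log(p[3])] if skew else []))
            return _univariate_negloglik(t, x, skew)

        cov = _numdiff.covariance_from_hessian(
            _numdiff.hessian(negll_orig, np.asarray(values)))
        if cov is not None:
            std_errors = dict(zip(names, np.sqrt(np.diag(cov))))
        else:
            message += "; observed information not positive definite"

    k = len(names)
    aic, aicc, bic = information_criteria(loglik, k, x.size)
    return FitResult(
        model="skew-ln" if skew else "ln",
        estimates=estimates,
        std_errors=std_errors,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
        bic=bic,
        n=int(x.size),
        k=k,
        converged=converged,
        n_restarts_used=n_used,
        grad_norm=grad_norm,
        message=message,
    )


def fit_ln(sample, n_restarts: int = 10, compute_se: bool = True) -> FitResult:
    """Fit LN(mu, sigma, lam) by maximum likelihood."""
    return _fit_univariate(sample, skew=False, n_restarts=n_restarts, compute_se=compute_se)


def fit_skew_ln(sample, n_restarts: int = 10, compute_se: bool = True) -> FitResult:
    """Fit skew-LN(mu, sigma, lam, alpha) by maximum likelihood."""
    return _fit_univariate(sample, skew=True, n_restarts=n_restarts, compute_se=compute_se)


def ks_statistic(sample, cdf) -> float:
    """One-sample Kolmogorov-Smirnov statistic against a fitted CDF."""
    x = np.sort(_as_sample(sample))
    n = x.size
    f = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - f, f - (i - 1) / n)))


# ---------------------------------------------------------------------------
# Two-component normal mixture (EM baseline)
# ---------------------------------------------------------------------------

def _mixture_loglik(x, w, m1, m2, s1, s2):
    l1 = math.log(w) - 0.5 * ((x - m1) / s1) ** 2 - math.log(s1) - _LOG_SQRT_2PI
    l2 = math.log1p(-w) - 0.5 * ((x - m2) / s2) ** 2 - math.log(s2) - _LOG_SQRT_2PI
    return np.logaddexp(l1, l2)


def _em_run(x, w, m1, m2, s1, s2, max_iter=500, tol=1e-10):
    """One EM run; returns (params, loglik trace) or None on degeneracy."""
    scale_floor = 1e-8 * max(np.std(x), 1e-12)
    trace = []
    ll_old = -np.inf
    for _ in range(max_iter):
        l1 = math.log(w) - 0.5 * ((x - m1) / s1) ** 2 - math.log(s1) - _LOG_SQRT_2PI
        l2 = math.log1p(-w) - 0.5 * ((x - m2) / s2) ** 2 - math.log(s2) - _LOG_SQRT_2PI
        ltot = np.logaddexp(l1, l2)
        ll = float(np.sum(ltot))
        trace.append(ll)
        r1 = np.exp(l1 - ltot)
        n1 = r1.sum()
        if n1 < 1e-10 or x.size - n1 < 1e-10:
            return None
        w = n1 / x.size
        m1 = float(np.sum(r1 * x) / n1)
        m2 = float(np.sum((1 - r1) * x) / (x.size - n1))
        s1 = math.sqrt(max(np.sum(r1 * (x - m1) ** 2) / n1, 0.0))
        s2 = math.sqrt(max(np.sum((1 - r1) * (x - m2) ** 2) / (x.size - n1), 0.0))
        if s1 < scale_floor or s2 < scale_floor:
            return None
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return (w, m1, m2, s1, s2), trace


def fit_normal_mixture(sample, k: int = 2, seed=None, n_restarts: int = 10,
                       compute_se: bool = True) -> FitResult:
    """Fit a two-component normal mixture (pi, mu1, mu2, sigma1, sigma2) by EM.

    The first start splits the sorted sample at its median; further starts
    use random responsibilities.  Runs that collapse a component are
    discarded and restarted; the per-iteration log-likelihood trace of the
    winning run is stored in ``extra['loglik_trace']``.
    """
    if k != 2:
        raise DomainError("only the two-component mixture is supported")
    x = _as_sample(sample, min_n=6)
    rng = np.random.default_rng(seed)

    lo, hi = x[x <= np.median(x)], x[x > np.median(x)]
    s_floor = max(1e-3 * float(np.std(x)), 1e-12)
    best = None
    n_used = 0
    n_ok = 0
    for attempt in range(n_restarts + 1):
        if attempt == 0:  # deterministic start: split at the median
            start = (0.5, float(lo.mean()), float(hi.mean()),
                     max(float(lo.std()), s_floor), max(float(hi.std()), s_floor))
        else:  # random responsibilities
            r = rng.uniform(size=x.size)
            start = (0.5,
                     float(np.sum(r * x) / np.sum(r)),
                     float(np.sum((1 - r) * x) / np.sum(1 - r)),
                     float(np.std(x)), float(np.std(x)))
            n_used = attempt
        out = _em_run(x, *start)
        if out is None:
            continue
        n_ok += 1
        params, trace = out
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace)
        if n_ok >= 3:  # deterministic start plus two clean random restarts
            break
    if best is None:
        raise ConvergenceError("EM collapsed a component in every restart")

    (w, m1, m2, s1, s2), trace = best
    names = ["w1", "mu1", "mu2", "sigma1", "sigma2"]
    values = [w, m1, m2, s1, s2]
    loglik = trace[-1]

    std_errors = None
    if compute_se:
        def negll(p):
            if not (0.0 < p[0] < 1.0) or p[3] <= 0.0 or p[4] <= 0.0:
                return float("inf")
            return -float(np.sum(_mixture_loglik(x, *p)))

        cov = _numdiff.covariance_from_hessian(_numdiff.hessian(negll, np.asarray(values)))
        if cov is not None:
            std_errors = dict(zip(names, np.sqrt(np.diag(cov))))

    aic, aicc, bic = information_criteria(loglik, 5, x.size)
    return FitResult(
        model="normal-mixture",
        estimates=dict(zip(names, values)),
        std_errors=std_errors,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
        bic=bic,
        n=int(x.size),
        k=5,
        converged=True,
        n_restarts_used=n_used,
        extra={"loglik_trace": trace},
    )


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

def _column_or_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise DomainError("expected a 1-d sample or a single-column 2-d array")
    return x


class LogisticNormalMLE(BaseEstimator):
    """Maximum-likelihood estimator of the LN(mu, sigma, lam) distribution.

    Follows the scikit-learn estimator protocol: ``fit(X)`` on a univariate
    sample sets ``lam_``, ``mu_``, ``sigma_``, ``loglik_``, ``aic_``,
    ``aicc_``, ``bic_``, ``se_`` and ``converged_``; ``score_samples``
    returns per-observation log-densities and ``sample`` draws new data.

    Parameters
    ----------
    n_restarts : maximum number of jittered optimizer restarts.
    compute_se : whether to invert the observed information for SEs.
    """

    _skew = False

    def __init__(self, n_restarts: int = 10, compute_se: bool = True):
        self.n_restarts = n_restarts
        self.compute_se = compute_se

    def fit(self, X, y=None):
        x = _column_or_1d(X)
        self.result_ = _fit_univariate(
            x, skew=self._skew, n_restarts=self.n_restarts, compute_se=self.compute_se
        )
        est = self.result_.estimates
        self.lam_ = est["lam"]
        self.mu_ = est["mu"]
        self.sigma_ = est["sigma"]
        if self._skew:
            self.alpha_ = est["alpha"]
        self.se_ = self.result_.std_errors
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        self.aicc_ = self.result_.aicc
        self.bic_ = self.result_.bic
        self.converged_ = self.result_.converged
        self.n_features_in_ = 1
        return self

    def _params(self):
        if self._skew:
            return SkewLNParams(self.lam_, self.mu_, self.sigma_, self.alpha_)
        return LNParams(self.lam_, self.mu_, self.sigma_)

    def score_samples(self, X):
        x = _column_or_1d(X)
        if self._skew:
            return np.asarray(skew_ln_logpdf(x, self._params()))
        return np.asarray(ln_logpdf(x, self._params()))

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def cdf(self, X):
        from .distributions import ln_cdf, skew_ln_cdf

        x = _column_or_1d(X)
        fn = skew_ln_cdf if self._skew else ln_cdf
        return np.asarray(fn(x, self._params()))

    def quantile(self, p):
        fn = skew_ln_quantile if self._skew else ln_quantile
        return fn(p, self._params())

    def sample(self, n: int, random_state=None):
        fn = skew_ln_rvs if self._skew else ln_rvs
        return fn(n, self._params(), seed=random_state)


class SkewLogisticNormalMLE(LogisticNormalMLE):
    """Maximum-likelihood estimator of the skew-LN(mu, sigma, lam, alpha)
    distribution; the ``alpha_`` attribute carries the skewness exponent."""

    _skew = True


class TwoComponentNormalMixture(BaseEstimator):
    """EM estimator of a two-component normal mixture, kept as the baseline
    the LN distribution is compared against on bimodal data."""

    def __init__(self, n_restarts: int = 10, compute_se: bool = True, random_state=None):
        self.n_restarts = n_restarts
        self.compute_se = compute_se
        self.random_state = random_state

    def fit(self, X, y=None):
        x = _column_or_1d(X)
        self.result_ = fit_normal_mixture(
            x, seed=self.random_state, n_restarts=self.n_restarts,
            compute_se=self.compute_se,
        )
        est = self.result_.estimates
        self.weights_ = np.array([est["w1"], 1.0 - est["w1"]])
        self.means_ = np.array([est["mu1"], est["mu2"]])
        self.scales_ = np.array([est["sigma1"], est["sigma2"]])
        self.loglik_ = self.result_.loglik
        self.loglik_trace_ = list(self.result_.extra["loglik_trace"])
        self.converged_ = self.result_.converged
        self.n_features_in_ = 1
        return self

    def score_samples(self, X):
        x = _column_or_1d(X)
        est = self.result_.estimates
        return _mixture_loglik(x, est["w1"], est["mu1"], est["mu2"],
                               est["sigma1"], est["sigma2"])

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def cdf(self, X):
        from scipy.stats import norm

        x = _column_or_1d(X)
        est = self.result_.estimates
        return est["w1"] * norm.cdf(x, est["mu1"], est["sigma1"]) + (
            1.0 - est["w1"]
        ) * norm.cdf(x, est["mu2"], est["sigma2"])
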