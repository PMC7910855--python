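"""Synthetic-data generators and reproducible file fixtures.

Every generator is driven by a single seed and mirrors the data-generating
assumptions of the methods in this package: univariate LN / skew-LN samples
by inverse transform, two-component normal mixtures for the bimodal
baseline, and regression datasets ``y = X beta + sigma Z`` with independent
standard-normal covariates and skew-LN(0, 1, lam, alpha) errors.
``generate_fixture`` writes the dataset as CSV together with a JSON sidecar
recording the generator, parameters and seed needed to regenerate it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import LNParams, SkewLNParams, ln_rvs, skew_ln_rvs
from .errors import ConfigError

__all__ = [
    "FixtureSpec",
    "make_ln_sample",
    "make_skew_ln_sample",
    "make_normal_mixture_sample",
    "make_regression_dataset",
    "generate_fixture",
]

_GENERATORS = ("ln", "skew-ln", "normal-mixture", "regression")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: generator name, its parameters, size and seed."""

    generator: str
    parameters: dict
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.generator not in _GENERATORS:
            raise ConfigError(f"unknown generator {self.generator!r}; "
                              f"expected one of {_GENERATORS}")
        if self.n < 1:
            raise ConfigError("fixture size n must be >= 1")


def make_ln_sample(n: int, params: LNParams, seed=None) -> np.ndarray:
    return ln_rvs(n, params, seed=seed)


def make_skew_ln_sample(n: int, params: SkewLNParams, seed=None) -> np.ndarray:
    return skew_ln_rvs(n, params, seed=seed)


def make_normal_mixture_sample(n: int, w1: float, mu1: float, mu2: float,
                               sigma1: float, sigma2: float, seed=None) -> np.ndarray:
    if not 0.0 < w1 < 1.0 or sigma1 <= 0.0 or sigma2 <= 0.0:
        raise ConfigError("mixture needs 0 < w1 < 1 and positive scales")
    rng = np.random.default_rng(seed)
    pick = rng.uniform(size=n) < w1
    draws = np.where(pick, rng.normal(mu1, sigma1, size=n),
                     rng.normal(mu2, sigma2, size=n))
    return draws


def make_regression_dataset(n: int, beta, sigma: float, lam: float = 1.0,
                            alpha: float = 1.0, seed=None) -> pd.DataFrame:
    """Regression dataset with iid standard-normal covariates and skew-LN
    errors; ``beta[0]`` is the intercept."""
    beta = np.asarray(beta, dtype=float)
    if beta.size < 1:
        raise ConfigError("beta must contain at least the intercept")
    if sigma <= 0.0:
        raise ConfigError("sigma must be positive")
    rng = np.random.default_rng(seed)
    p = beta.size - 1
    X = rng.standard_normal(size=(n, p))
    z = skew_ln_rvs(n, SkewLNParams(lam, 0.0, 1.0, alpha), seed=rng)
    y = beta[0] + X @ beta[1:] + sigma * z
    frame = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    frame.insert(0, "y", y)
    return frame


def _fixture_frame(spec: FixtureSpec) -> pd.DataFrame:
    p = dict(spec.parameters)
    try:
        if spec.generator == "ln":
            params = LNParams(p["lam"], p.get("mu", 0.0), p.get("sigma", 1.0))
            return pd.DataFrame({"x": make_ln_sample(spec.n, params, seed=spec.seed)})
        if spec.generator == "skew-ln":
            params = SkewLNParams(p["lam"], p.get("mu", 0.0), p.get("sigma", 1.0),
                                  p.get("alpha", 1.0))
            return pd.DataFrame({"x": make_skew_ln_sample(spec.n, params, seed=spec.seed)})
        if spec.generator == "normal-mixture":
            return pd.DataFrame({"x": make_normal_mixture_sample(
                spec.n, p["w1"], p["mu1"], p["mu2"], p["sigma1"], p["sigma2"],
                seed=spec.seed)})
        return make_regression_dataset(
            spec.n, p["beta"], p["sigma"], p.get("lam", 1.0), p.get("alpha", 1.0),
            seed=spec.seed)
    except KeyError as exc:
        raise ConfigError(f"missing parameter {exc} for generator {spec.generator!r}")


def generate_fixture(spec: FixtureSpec, path) -> tuple[Path, Path]:
    """Write the dataset CSV and its JSON metadata sidecar; returns both paths."""
    path = Path(path)
    frame = _fixture_frame(spec)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = {
        "generator": spec.generator,
        "parameters": spec.parameters,
        "n": spec.n,
        "seed": spec.seed,
        "columns": list(frame.columns),
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path, meta_path
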