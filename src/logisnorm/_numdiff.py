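"""Central-difference gradient and Hessian for smooth scalar objectives.

Step sizes are relative (``h_i = step * max(1, |x_i|)``), which keeps the
truncation/rounding trade-off sensible both for coefficients of order one
and for shape parameters in the hundreds.
"""

from __future__ import annotations

import numpy as np


def gradient(f, x, step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = step * np.maximum(1.0, np.abs(x))
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def hessian(f, x, step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / (4.0 * h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fpq = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmq = f(x - ei + ej)
            fm2 = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpq - fpm - fmq + fm2) / (4.0 * h[i] * h[j])
    return hess


def covariance_from_hessian(hess: np.ndarray) -> np.ndarray | None:
    """Invert an observed-information matrix; None if not positive definite."""
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0.0):
        return None
    return cov
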