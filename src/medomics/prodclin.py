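"""Distribution-of-the-product confidence intervals for indirect effects.

The indirect effect α·β is estimated by the product of two regression
coefficients. Treating the estimators as independent normals
A ~ N(a, se_a²), B ~ N(b, se_b²), the exact distribution of A·B is neither
normal nor symmetric; its quantiles give better-calibrated intervals than
the Sobel normal approximation. The CDF is evaluated by numerical
integration over A and inverted by bisection.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, optimize, stats

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _product_cdf(t: float, a: float, se_a: float, b: float, se_b: float) -> float:
    """P(A·B <= t) for independent A ~ N(a, se_a²), B ~ N(b, se_b²)."""

    def integrand(z: float) -> float:
        A = a + se_a * z
        phi = math.exp(-0.5 * z * z) / _SQRT2PI
        if A > 0:
            return phi * stats.norm.cdf((t / A - b) / se_b)
        if A < 0:
            return phi * stats.norm.sf((t / A - b) / se_b)
        return phi if t >= 0 else 0.0

    # breakpoints: sign change of A, and the location where t/A crosses b
    # (the CDF factor switches fastest there — critical when se_b is tiny)
    pts = [-a / se_a]
    if abs(b) > 1e-300:
        pts.append((t / b - a) / se_a)
    pts = sorted(p for p in pts if -12.0 < p < 12.0)
    val, _ = integrate.quad(integrand, -12.0, 12.0, points=pts or None,
                            limit=200, epsabs=1e-11, epsrel=1e-10)
    return min(1.0, max(0.0, val))


def prodclin_ci(
    a: float, se_a: float, b: float, se_b: float, conf: float = 0.95
) -> tuple[float, float]:
    """Quantile CI for the product of two independent normal estimates.

    Returns the (lower, upper) ``conf``-level equal-tailed interval of A·B
    with A ~ N(a, se_a²), B ~ N(b, se_b²), by numerical CDF inversion.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    mean = a * b
    sd = math.sqrt(a * a * se_b**2 + b * b * se_a**2 + se_a**2 * se_b**2)
    q_lo, q_hi = (1 - conf) / 2, 1 - (1 - conf) / 2

    def invert(q: float) -> float:
        lo, hi = mean - 12 * sd, mean + 12 * sd
        # expand until the bracket certainly covers the quantile
        while _product_cdf(lo, a, se_a, b, se_b) > q:
            lo -= 10 * sd
        while _product_cdf(hi, a, se_a, b, se_b) < q:
            hi += 10 * sd
        return optimize.brentq(
            lambda t: _product_cdf(t, a, se_a, b, se_b) - q,
            lo, hi, xtol=1e-10 * max(1.0, sd), rtol=8.9e-16,
        )

    return invert(q_lo), invert(q_hi)


def prodclin_ci_mc(
    a: float, se_a: float, b: float, se_b: float, conf: float = 0.95,
    n_draws: int = 10_000_000, seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo reference for :func:`prodclin_ci` (simulation quantiles)."""
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2
    # chunked to bound memory
    draws = np.empty(n_draws)
    step = 2_000_000
    for start in range(0, n_draws, step):
        m = min(step, n_draws - start)
        draws[start:start + m] = (
            rng.normal(a, se_a, m) * rng.normal(b, se_b, m)
        )
    lo, hi = np.quantile(draws, [lo_q, hi_q])
    return float(lo), float(hi)
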