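"""Exact binomial confidence intervals."""

from __future__ import annotations

from scipy.stats import beta


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI on a proportion, via beta quantiles.

    Returns (lower, upper) for ``k`` successes in ``n`` trials.  The limits
    are 0 at k=0 and 1 at k=n by convention.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def wilson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (configurable alternative to the exact CI)."""
    from scipy.stats import norm

    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    z = float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
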