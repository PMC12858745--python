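"""Simultaneous confidence intervals for multinomial proportions.

Implements the Sison-Glaz procedure: the joint probability that every count
stays within +/- c of its observed value is approximated through truncated
Poisson distributions with an Edgeworth-corrected normalisation, the
smallest integer c achieving the nominal level is located, and a linear
interpolation term delta refines the upper limits. Intervals share one
half-width c/N (plus 2*delta/N on top), which is what produces the constant
margins seen in category tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import pdtr

__all__ = ["MultinomialCI", "sison_glaz_ci"]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def _ppois(k: np.ndarray | float, lam: np.ndarray | float) -> np.ndarray:
    """Poisson CDF with P(X <= k) = 0 for k < 0, vectorised."""
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.where(k >= 0, pdtr(np.maximum(k, 0), lam), 0.0)
    return out


def _truncated_poisson_central_moments(
    c: int, lam: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """First four central moments (and the truncation mass) of a Poisson(lam)
    variable truncated to [lam - c, lam + c], per category.

    Factorial moments of the truncated distribution are
    E[X(X-1)...(X-r+1)] = lam^r * P(b - r <= Y <= a - r) / P(b <= Y <= a)
    for Y ~ Poisson(lam), a = lam + c, b = max(lam - c, 0); they are then
    converted to central moments.
    """
    lam = np.asarray(lam, dtype=float)
    a = lam + c
    b = np.maximum(lam - c, 0.0)
    den = _ppois(a, lam) - _ppois(b - 1.0, lam)
    fact = []
    for r in (1, 2, 3, 4):
        num = _ppois(a - r, lam) - _ppois(b - r - 1.0, lam)
        fact.append(lam ** r * num / den)
    f1, f2, f3, f4 = fact
    m1 = f1
    m2 = f2 + f1 - f1 ** 2
    m3 = f3 + f2 * (3.0 - 3.0 * f1) + (f1 - 3.0 * f1 ** 2 + 2.0 * f1 ** 3)
    m4 = (
        f4
        + f3 * (6.0 - 4.0 * f1)
        + f2 * (7.0 - 12.0 * f1 + 6.0 * f1 ** 2)
        + f1
        - 4.0 * f1 ** 2
        + 6.0 * f1 ** 3
        - 3.0 * f1 ** 4
    )
    return m1, m2, m4 - 3.0 * m2 ** 2, m3, den


def _joint_prob(c: int, counts: np.ndarray) -> float:
    """Edgeworth-corrected P(all counts within +/- c), the Sison-Glaz nu(c)."""
    n = counts.sum()
    m1, m2, m4c, m3, den = _truncated_poisson_central_moments(c, counts)
    s1, s2, s3, s4 = m1.sum(), m2.sum(), m3.sum(), m4c.sum()
    if s2 <= 0:
        return 1.0
    z = (n - s1) / np.sqrt(s2)
    g1 = s3 / s2 ** 1.5
    g2 = s4 / s2 ** 2
    poly = (
        1.0
        + g1 * (z ** 3 - 3.0 * z) / 6.0
        + g2 * (z ** 4 - 6.0 * z ** 2 + 3.0) / 24.0
        + g1 ** 2 * (z ** 6 - 15.0 * z ** 4 + 45.0 * z ** 2 - 15.0) / 72.0
    )
    f = poly * np.exp(-(z ** 2) / 2.0) / _SQRT_2PI
    prob_n = 1.0 / (_ppois(n, n) - _ppois(n - 1.0, n))
    return float(prob_n * np.prod(den) * f / np.sqrt(s2))


@dataclass(frozen=True)
class MultinomialCI:
    proportions: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c: int
    delta: float
    alpha: float

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.lower, self.upper])


def sison_glaz_ci(counts, alpha: float = 0.05) -> MultinomialCI:
    """Simultaneous (1 - alpha) confidence intervals for all k categories.

    ``counts`` are nonnegative category counts with a positive total. Each
    interval is [p_i - c/N, p_i + c/N + 2*delta/N] clipped to [0, 1].
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    p = counts / n
    if counts.size == 1:
        one = np.ones(1)
        return MultinomialCI(p, one.copy(), one.copy(), 0, 0.0, alpha)

    target = 1.0 - alpha
    # nu(c) is nondecreasing in c: bracket then bisect for the smallest
    # integer c with nu(c) >= 1 - alpha.
    lo, hi = 0, 1
    while _joint_prob(hi, counts) < target and hi < n:
        lo, hi = hi, min(int(n), hi * 2)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _joint_prob(mid, counts) >= target:
            hi = mid
        else:
            lo = mid
    c = hi
    nu_c = _joint_prob(c, counts)
    nu_prev = _joint_prob(c - 1, counts) if c > 0 else 0.0
    delta = (target - nu_prev) / (nu_c - nu_prev) if nu_c > nu_prev else 0.0
    lower = np.clip(p - c / n, 0.0, 1.0)
    upper = np.clip(p + c / n + 2.0 * delta / n, 0.0, 1.0)
    return MultinomialCI(p, lower, upper, c, float(delta), alpha)
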