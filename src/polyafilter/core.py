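"""Beta-Binomial (Pólya urn) null model for link weights.

A node of degree k and strength s is modelled as distributing its strength
over its links by a Pólya urn: the urn starts with one red ball (the focal
link) and k-1 black balls, each draw returns the ball plus ``a`` extra balls
of the drawn colour, and the weight on the focal link is the number of red
draws in s attempts.  The resulting null is Beta-Binomial,

    P(w | k, s, a) = C(s, w) B(1/a + w, (k-1)/a + s - w) / B(1/a, (k-1)/a),

with the Binomial(s, 1/k) limit at a = 0 and a point mass governed only by
1/k as a -> infinity.  All beta/binomial terms are computed as sums of
log-gamma values so that strengths of order 1e6 do not overflow, and survival
sums always accumulate the numerically smaller tail.

The module also provides the large-strength approximation of the p-value, its
further reduction to a function of the ratio r = w k / s alone, the disparity
filter p-value (1 - w/s)^(k-1) -- the a = 1 large-strength limit -- and the
null moments of r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import betaln, gamma as _gamma_fn, gammaln, logsumexp

from .errors import DomainError

__all__ = [
    "polya_pmf",
    "polya_logpmf",
    "polya_pvalue",
    "polya_pvalue_approx",
    "polya_pvalue_ratio",
    "disparity_pvalue",
    "ratio_r",
    "null_ratio_moments",
    "RatioStats",
]

_WHOLE_TOL = 1e-9


def _as_arrays(*args):
    arrs = np.broadcast_arrays(*[np.asarray(x, dtype=np.float64) for x in args])
    return arrs


def _check_whole(x, name):
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.abs(x - np.round(x)) <= _WHOLE_TOL):
        raise DomainError(f"{name} must be a whole number for the exact test; "
                          "use the approximate mode for real-valued weights")


def polya_logpmf(x, k, s, a: float):
    """Log of the Beta-Binomial pmf; vectorized over x, k, s.

    ``a`` is a non-negative scalar.  k = 1 is a point mass at x = s (the urn
    holds no black balls); a = 0 is the Binomial(s, 1/k) limit.
    """
    if a < 0:
        raise DomainError(f"reinforcement parameter a must be >= 0, got {a}")
    x, k, s = _as_arrays(x, k, s)
    if np.any(k < 1):
        raise DomainError("degree k must be >= 1")
    if np.any((x < 0) | (x > s)):
        raise DomainError("count x must satisfy 0 <= x <= s")
    out = np.full(x.shape, -np.inf)
    point = k == 1
    if np.any(point):
        out[point] = np.where(x[point] == s[point], 0.0, -np.inf)
    rest = ~point
    if np.any(rest):
        xr, kr, sr = x[rest], k[rest], s[rest]
        # below a*s ~ 1e-10 the Beta-Binomial is numerically indistinguishable
        # from its binomial limit while the log-beta difference loses all
        # precision, so the limit is used directly
        if a == 0 or a * float(np.max(sr)) <= 1e-10:
            out[rest] = stats.binom.logpmf(xr, sr, 1.0 / kr)
        else:
            al = 1.0 / a
            be = (kr - 1.0) / a
            out[rest] = (
                gammaln(sr + 1.0) - gammaln(xr + 1.0) - gammaln(sr - xr + 1.0)
                + betaln(xr + al, sr - xr + be) - betaln(al, be)
            )
    return out if out.shape else float(out)


def polya_pmf(x, k, s, a: float):
    """Beta-Binomial probability mass P(x | k, s, a), Pólya urn null.

    Parameters
    ----------
    x : count of red draws (weight on the focal link), 0 <= x <= s
    k : viewpoint degree (urn starts with 1 red, k-1 black balls)
    s : viewpoint strength (number of draws)
    a : reinforcement parameter, >= 0
    """
    return np.exp(polya_logpmf(x, k, s, a))


def _pvalue_exact_scalar(w: float, k: float, s: float, a: float) -> float:
    # preconditions already validated; w >= 1, k >= 2 whole numbers
    w = int(round(w))
    s = int(round(s))
    n_upper = s - w + 1
    if n_upper <= w:
        xs = np.arange(w, s + 1, dtype=np.float64)
        p = float(np.exp(logsumexp(polya_logpmf(xs, k, s, a))))
    else:
        xs = np.arange(0, w, dtype=np.float64)
        p = 1.0 - float(np.exp(logsumexp(polya_logpmf(xs, k, s, a))))
    return min(max(p, 0.0), 1.0)


def polya_pvalue(w, k, s, a: float):
    """Exact survival p-value P(X >= w) under the Beta-Binomial null.

    Sums the numerically smaller tail and complements if needed, so tiny
    p-values on the upper tail keep full relative precision.  ``w = 0``
    returns 1 (the whole support is favourable); ``k = 1`` returns 1 (point
    mass at s, and w <= s always).  Exact mode requires whole-number w and s.
    """
    if a < 0:
        raise DomainError(f"reinforcement parameter a must be >= 0, got {a}")
    w_arr, k_arr, s_arr = _as_arrays(w, k, s)
    scalar = w_arr.shape == ()
    w_arr, k_arr, s_arr = np.atleast_1d(w_arr, k_arr, s_arr)
    if np.any((w_arr < 0) | (w_arr > s_arr)):
        raise DomainError("weight w must satisfy 0 <= w <= s")
    if np.any(k_arr < 1):
        raise DomainError("degree k must be >= 1")
    _check_whole(w_arr, "w")
    _check_whole(s_arr, "s")
    out = np.ones(w_arr.shape)
    live = (w_arr >= 1) & (k_arr > 1)
    if a == 0 or (live.any() and a * float(np.max(s_arr[live])) <= 1e-10):
        out[live] = stats.binom.sf(w_arr[live] - 1.0, np.round(s_arr[live]), 1.0 / k_arr[live])
    else:
        for idx in np.flatnonzero(live):
            out.flat[idx] = _pvalue_exact_scalar(
                w_arr.flat[idx], k_arr.flat[idx], s_arr.flat[idx], a
            )
    return float(out[0]) if scalar else out


def polya_pvalue_approx(w, k, s, a: float):
    """Large-strength approximation of the Pólya p-value, clipped to [0, 1].

    Valid for s >> k/a and w >> 1, and the route for real-valued weights:

        pi_P ~ (1 - w/s)^((k-1)/a) * (w k / (s a))^(1/a - 1) / Gamma(1/a).

    At a = 1 this reduces exactly (bit-for-bit) to the disparity filter
    formula (1 - w/s)^(k-1).  k = 1 returns 1 (degenerate urn).
    """
    if a <= 0:
        raise DomainError("approximate p-value requires a > 0; use the exact "
                          "binomial at a = 0")
    w_arr, k_arr, s_arr = _as_arrays(w, k, s)
    if np.any(w_arr > s_arr):
        raise DomainError("weight w must satisfy w <= s")
    if np.any(w_arr <= 0):
        raise DomainError("approximate p-value requires w > 0")
    if np.any(k_arr < 1):
        raise DomainError("degree k must be >= 1")
    base = 1.0 - w_arr / s_arr
    with np.errstate(divide="ignore", over="ignore"):
        val = np.power(base, (k_arr - 1.0) / a) * (
            np.power(w_arr * k_arr / (s_arr * a), 1.0 / a - 1.0) / _gamma_fn(1.0 / a)
        )
    val = np.where(k_arr == 1, 1.0, val)
    out = np.clip(val, 0.0, 1.0)
    return out if out.shape else float(out)


def polya_pvalue_ratio(r, a: float):
    """p-value as a function of the ratio r = w k / s alone, clipped to [0, 1].

    The small-w/s expansion of the large-strength approximation:

        pi_P ~ exp(-r/a) (r/a)^(1/a - 1) / Gamma(1/a),

    which makes explicit the soft dependence of the filter on r.
    """
    if a <= 0:
        raise DomainError("ratio p-value requires a > 0")
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr <= 0):
        raise DomainError("ratio r must be > 0")
    with np.errstate(divide="ignore", over="ignore"):
        val = np.exp(-r_arr / a) * np.power(r_arr / a, 1.0 / a - 1.0) / _gamma_fn(1.0 / a)
    out = np.clip(val, 0.0, 1.0)
    return out if out.shape else float(out)


def disparity_pvalue(w, k, s):
    """Disparity-filter p-value (1 - w/s)^(k-1).

    The disparity filter is the large-strength limit of the Pólya filter at
    a = 1; it is kept as the built-in reference filter.
    """
    w_arr, k_arr, s_arr = _as_arrays(w, k, s)
    if np.any((w_arr < 0) | (w_arr > s_arr)):
        raise DomainError("weight w must satisfy 0 <= w <= s")
    if np.any(k_arr < 1):
        raise DomainError("degree k must be >= 1")
    out = np.power(1.0 - w_arr / s_arr, k_arr - 1.0)
    return out if out.shape else float(out)


def ratio_r(w, k, s):
    """Ratio r = w k / s: the link weight relative to the node's mean weight."""
    w_arr, k_arr, s_arr = _as_arrays(w, k, s)
    if np.any(s_arr <= 0):
        raise DomainError("strength s must be > 0")
    out = w_arr * k_arr / s_arr
    return out if out.shape else float(out)


@dataclass(frozen=True)
class RatioStats:
    """Null mean and variance of the ratio r = w k / s."""

    mu_r: float
    var_r: float

    @property
    def sd_r(self) -> float:
        return float(np.sqrt(self.var_r))


def null_ratio_moments(k, s, a: float) -> RatioStats:
    """Moments of r under the Pólya null.

    The mean is identically 1 for every (k, s, a); the variance is

        var(r) = (k-1)/s * (k + a s) / (a + k),

    which reduces to (k-1)/s at a = 0 (rescaled binomial variance) and grows
    with the reinforcement a.
    """
    if a < 0:
        raise DomainError("reinforcement parameter a must be >= 0")
    k = float(k)
    s = float(s)
    if k < 1 or s <= 0:
        raise DomainError("need k >= 1 and s > 0")
    var = (k - 1.0) / s * (k + a * s) / (a + k)
    return RatioStats(mu_r=1.0, var_r=float(var))
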