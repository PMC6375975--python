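"""Calibration of the reinforcement parameter a.

Three criteria are provided for fixing the free parameter of the filter:

* **sweeping** -- exploit the monotone shrinkage of backbones in a to find
  the smallest a reaching a target sparsity (:func:`sweep_a`);
* **maximum likelihood** -- find the Pólya process most likely to have
  generated the observed weight allocation, i.e. the "nullest" member of the
  family (:func:`fit_a_ml`);
* **salience optimality** -- handled in :mod:`polyafilter.salience`.

Two likelihood compositions are available.  The *composite* likelihood is the
plain sum of log Beta-Binomial masses over every (link, viewpoint) test, one
urn per viewpoint node; degree-1 viewpoints are point masses and contribute
zero.  The *truncated* likelihood (the default for fitting) additionally
conditions each viewpoint node's Dirichlet-multinomial allocation on every
observed link receiving at least one unit of weight -- in an observed network
a link exists precisely because its weight is positive, and ignoring that
conditioning systematically underestimates a on heterogeneous networks (the
more so the larger a, since strongly reinforced urns starve many links to
zero).  The truncation constant P(all cells >= 1) is computed by
inclusion-exclusion over forced-zero cells, entirely in log space.

The equivalence scaling c(a1, d, k, s) quantifies how raising a from a1 to
d*a1 can be traded against a tighter significance region of the ratio r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln, logsumexp

from .core import polya_logpmf
from .errors import DegenerateLikelihoodError, DomainError, UnreachableTargetError
from .filtering import backbone_summary, extract_backbone
from .network import INTEGER, WeightedNetwork, node_stats

__all__ = [
    "LikelihoodProfile",
    "log_likelihood",
    "truncated_log_likelihood",
    "fit_a_ml",
    "sweep_a",
    "equivalence_scale",
    "EquivalenceScale",
]

DEFAULT_BRACKET = (1e-4, 1e3)


def _viewpoint_observations(net: WeightedNetwork):
    """Flattened (w, k, s, node_id) arrays over all k >= 2 viewpoint urns.

    Each viewpoint node (both endpoints if undirected; out-view of sources
    and in-view of targets if directed) contributes one observation per
    incident link, carrying that node's (k, s).
    """
    stats = node_stats(net)
    lk = net.links
    if net.directed:
        groups = [
            (lk["source"], stats["k_out"], stats["s_out"], "out:"),
            (lk["target"], stats["k_in"], stats["s_in"], "in:"),
        ]
    else:
        groups = [
            (lk["source"], stats["k"], stats["s"], ""),
            (lk["target"], stats["k"], stats["s"], ""),
        ]
    w_parts, k_parts, s_parts, id_parts = [], [], [], []
    for nodes, kcol, scol, tag in groups:
        k = kcol.reindex(nodes).to_numpy(dtype=float)
        s = scol.reindex(nodes).to_numpy(dtype=float)
        keep = k >= 2
        w_parts.append(lk["weight"].to_numpy()[keep])
        k_parts.append(k[keep])
        s_parts.append(s[keep])
        id_parts.append((tag + nodes[keep]).to_numpy())
    w = np.concatenate(w_parts)
    k = np.concatenate(k_parts)
    s = np.concatenate(s_parts)
    ids = np.concatenate(id_parts)
    if len(w) == 0:
        raise DegenerateLikelihoodError(
            "no viewpoint with degree >= 2: the likelihood carries no "
            "information about a"
        )
    return w, k, s, ids


def _composite_ll(w, k, s, a: float, integer: bool) -> float:
    if integer:
        return float(np.sum(polya_logpmf(w, k, s, a)))
    # real weights: log Beta(1/a, (k-1)/a) density of the rate w/s --
    # the large-strength law of the weight fraction (pseudo-likelihood)
    al = 1.0 / a
    be = (k - 1.0) / a
    x = w / s
    return float(np.sum((al - 1.0) * np.log(x) + (be - 1.0) * np.log1p(-x) - betaln(al, be)))


def _log_trunc_constants(ks, ss, c: float) -> np.ndarray:
    """log P(all k cells >= 1) for DirMult(k, s, conc c), one per (k, s) row.

    Inclusion-exclusion over the number j of forced-zero cells:
        P = sum_j (-1)^j C(k, j) Gamma(kc) Gamma(s + (k-j)c)
                  / (Gamma(s + kc) Gamma((k-j)c)).
    """
    out = np.empty(len(ks))
    cache: dict[tuple, float] = {}
    for i, (k, s) in enumerate(zip(ks, ss)):
        key = (k, s)
        if key not in cache:
            j = np.arange(int(k))
            logterm = (
                gammaln(k + 1.0) - gammaln(j + 1.0) - gammaln(k - j + 1.0)
                + gammaln(s + (k - j) * c) + gammaln(k * c)
                - gammaln(s + k * c) - gammaln((k - j) * c)
            )
            val, sign = logsumexp(logterm, b=(-1.0) ** j, return_sign=True)
            cache[key] = val if sign > 0 else -np.inf
        out[i] = cache[key]
    return out


def _truncated_ll(w, k, s, ids, a: float, integer: bool) -> float:
    if not integer:
        # positive real weights are never "zero"; no truncation correction
        return _composite_ll(w, k, s, a, integer=False)
    c = 1.0 / a
    # per-observation Dirichlet-multinomial factors
    per_obs = float(np.sum(gammaln(w + c) - gammaln(c) - gammaln(w + 1.0)))
    # per-viewpoint-node factors (each node counted once)
    _, first = np.unique(ids, return_index=True)
    kn = k[first]
    sn = s[first]
    per_node = float(
        np.sum(gammaln(sn + 1.0) + gammaln(kn * c) - gammaln(sn + kn * c))
    )
    log_z = float(np.sum(_log_trunc_constants(kn, sn, c)))
    return per_obs + per_node - log_z


def log_likelihood(net: WeightedNetwork, a: float) -> float:
    """Composite Pólya log-likelihood: sum of log pmf over all viewpoint tests.

    Degree-1 viewpoints contribute 0 (point mass at w = s).  Real-valued
    weights are scored with the Beta density of the rate w/s instead of the
    Beta-Binomial mass (pseudo-likelihood).
    """
    if a < 0:
        raise DomainError("reinforcement parameter a must be >= 0")
    w, k, s, _ = _viewpoint_observations(net)
    return _composite_ll(w, k, s, a, integer=net.weight_kind == INTEGER)


def truncated_log_likelihood(net: WeightedNetwork, a: float) -> float:
    """Zero-truncated Dirichlet-multinomial log-likelihood.

    Each k >= 2 viewpoint node's weight vector is scored under the
    Dirichlet-multinomial allocation with concentration 1/a, conditioned on
    every observed link receiving weight >= 1.  This is the consistent
    choice on observed networks, where link existence is informative.
    """
    if a <= 0:
        raise DomainError("truncated likelihood requires a > 0")
    w, k, s, ids = _viewpoint_observations(net)
    return _truncated_ll(w, k, s, ids, a, integer=net.weight_kind == INTEGER)


@dataclass
class LikelihoodProfile:
    """Result of a 1-D maximum-likelihood fit of a.

    Attributes
    ----------
    a_ml : float
        Maximizer of the chosen log-likelihood on the bracket.
    log_likelihood_ml : float
    grid : pandas.DataFrame
        Columns ``a``, ``log_likelihood``: the profile on a log-spaced grid.
    at_bracket_edge : bool
        True when the maximum sits at (or hugs) a bracket end; the estimate
        is then a bound, not an interior optimum.
    pseudo : bool
        True when the network has real-valued weights and the Beta-density
        pseudo-likelihood was used.
    """

    a_ml: float
    log_likelihood_ml: float
    grid: pd.DataFrame = field(repr=False)
    likelihood: str
    bracket: tuple
    n_tests: int
    iterations: int
    at_bracket_edge: bool
    pseudo: bool


def fit_a_ml(
    net: WeightedNetwork,
    bracket: tuple = DEFAULT_BRACKET,
    likelihood: str = "truncated",
    grid_points: int = 41,
) -> LikelihoodProfile:
    """Maximum-likelihood estimate of the reinforcement parameter a.

    Bounded 1-D maximization (Brent) on log a with ~1e-3 relative tolerance.
    ``likelihood`` is ``"truncated"`` (default, see
    :func:`truncated_log_likelihood`) or ``"composite"``
    (:func:`log_likelihood`).  A maximum at a bracket edge raises a warning
    and sets ``at_bracket_edge``.
    """
    low, high = bracket
    if not (0 < low < high):
        raise DomainError("bracket must satisfy 0 < low < high")
    if likelihood not in ("truncated", "composite"):
        raise DomainError("likelihood must be 'truncated' or 'composite'")
    w, k, s, ids = _viewpoint_observations(net)
    integer = net.weight_kind == INTEGER
    if likelihood == "truncated":
        def ll(a):
            return _truncated_ll(w, k, s, ids, a, integer)
    else:
        def ll(a):
            return _composite_ll(w, k, s, a, integer)

    res = minimize_scalar(
        lambda u: -ll(np.exp(u)),
        bounds=(np.log(low), np.log(high)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    a_ml = float(np.exp(res.x))
    grid_a = np.geomspace(low, high, grid_points)
    grid = pd.DataFrame({"a": grid_a, "log_likelihood": [ll(a) for a in grid_a]})
    at_edge = a_ml <= low * 1.1 or a_ml >= high / 1.1
    if at_edge:
        warnings.warn(
            f"a_ml = {a_ml:.4g} sits at the edge of the bracket {bracket}; "
            "treat it as a bound, not an interior maximum",
            stacklevel=2,
        )
    return LikelihoodProfile(
        a_ml=a_ml,
        log_likelihood_ml=float(-res.fun),
        grid=grid,
        likelihood=likelihood,
        bracket=(float(low), float(high)),
        n_tests=len(w),
        iterations=int(res.nfev),
        at_bracket_edge=at_edge,
        pseudo=not integer,
    )


def sweep_a(
    net: WeightedNetwork,
    metric: str = "links",
    target_fraction: float = 0.05,
    alpha_u: float = 0.05,
    correction: str = "bonferroni",
    mode: str = "auto",
    a_range: tuple = (1e-2, 1e3),
) -> float:
    """Smallest a (on a 0.01-decade log grid, plus a = 0) whose backbone is
    at most ``target_fraction`` of the parent by the chosen metric.

    Exploits the monotone non-increase of all three retention fractions in a
    to binary-search the grid.  ``metric`` is one of ``links``, ``nodes``,
    ``strength``.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise DomainError("target_fraction must be in (0, 1]")
    if metric not in ("links", "nodes", "strength"):
        raise DomainError("metric must be 'links', 'nodes' or 'strength'")
    idx = ("links", "nodes", "strength").index(metric)

    def value(a: float) -> float:
        summ = backbone_summary(
            extract_backbone(net, a, alpha_u=alpha_u, correction=correction, mode=mode)
        )
        return summ[idx]

    low, high = a_range
    grid = np.concatenate(
        [[0.0], 10 ** np.arange(np.log10(low), np.log10(high) + 1e-12, 0.01)]
    )
    if value(grid[0]) <= target_fraction:
        return 0.0
    v_high = value(grid[-1])
    if v_high > target_fraction:
        raise UnreachableTargetError(
            f"{metric} fraction is {v_high:.4f} > target {target_fraction} even "
            f"at a = {grid[-1]:.4g}; widen a_range or relax the target"
        )
    lo, hi = 0, len(grid) - 1  # value(lo) > target >= value(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if value(grid[mid]) <= target_fraction:
            hi = mid
        else:
            lo = mid
    return float(grid[hi])


@dataclass(frozen=True)
class EquivalenceScale:
    """Scaling c making the (a1, alpha) and (d*a1, tighter-alpha) nulls match."""

    a1: float
    d: float
    k: float
    s: float
    c: float


def equivalence_scale(a1: float, d: float, k: float, s: float) -> float:
    """Shrinkage c of the null compatibility region when a1 is scaled to d*a1.

        c = sqrt( (a1 + k/d)/(a1 + k) * (a1 s + k)/(a1 s + k/d) )

    c = 1 at d = 1 and decreases monotonically in d: a larger reinforcement
    parameter is equivalent to a smaller a with a stricter significance.
    """
    if a1 <= 0:
        raise DomainError("a1 must be > 0")
    if d < 1:
        raise DomainError("d must be >= 1 (a2 = d * a1 >= a1)")
    if k < 1 or s <= 0:
        raise DomainError("need k >= 1 and s > 0")
    return float(np.sqrt((a1 + k / d) / (a1 + k) * (a1 * s + k) / (a1 * s + k / d)))
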