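"""Per-link hypothesis tests, multiple-testing correction, backbone extraction.

Every link is tested twice: for an undirected network from the viewpoint of
each endpoint (using that node's degree k and strength s), for a directed
network from the source's out-urn (k_out, s_out) and the target's in-urn
(k_in, s_in).  The family of tests therefore has size L = 2 x number of
links.  A link enters the backbone when at least one of its p-values beats
the corrected threshold; viewpoints of degree 1 carry p = 1 (their urn is
degenerate), which automatically realizes the degree-1 rule: such viewpoints
never validate a link, and a link between two degree-1 nodes is never
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .core import (
    disparity_pvalue,
    polya_pvalue,
    polya_pvalue_approx,
    polya_pvalue_ratio,
    ratio_r,
)
from .errors import DomainError, ModeError
from .network import INTEGER, WeightedNetwork, node_stats

__all__ = [
    "TestTable",
    "Backbone",
    "BackboneSummary",
    "link_pvalues",
    "extract_backbone",
    "backbone_summary",
    "top_b_jaccard",
]

#: exact summation is used in "auto" mode only up to this per-observation strength
AUTO_EXACT_MAX_S = 100_000

CORRECTIONS = ("bonferroni", "fdr", "none")
MODES = ("auto", "exact", "approx", "ratio")


@dataclass(frozen=True)
class TestTable:
    """All per-(link, viewpoint) tests of a network at a fixed a.

    ``frame`` has one row per test with columns: ``link_id`` (position in the
    parent's link table), ``source``, ``target``, ``viewpoint``, ``w``, ``k``,
    ``s``, ``r``, ``p_value``, ``mode``.  ``L`` is the family size
    (2 x links).
    """

    frame: pd.DataFrame = field(repr=False)
    L: int
    directed: bool
    a: float

    def min_pvalues(self) -> pd.Series:
        """Per-link minimum of the two viewpoint p-values (indexed by link_id)."""
        return self.frame.groupby("link_id")["p_value"].min()


def _viewpoint_rows(net: WeightedNetwork) -> pd.DataFrame:
    """Two test rows per link carrying the relevant viewpoint (k, s)."""
    stats = node_stats(net)
    lk = net.links
    base = pd.DataFrame(
        {
            "link_id": np.arange(len(lk)),
            "source": lk["source"].to_numpy(),
            "target": lk["target"].to_numpy(),
            "w": lk["weight"].to_numpy(),
        }
    )
    if net.directed:
        out_view = base.assign(
            viewpoint=base["source"],
            k=stats["k_out"].reindex(base["source"]).to_numpy(),
            s=stats["s_out"].reindex(base["source"]).to_numpy(),
        )
        in_view = base.assign(
            viewpoint=base["target"],
            k=stats["k_in"].reindex(base["target"]).to_numpy(),
            s=stats["s_in"].reindex(base["target"]).to_numpy(),
        )
        rows = pd.concat([out_view, in_view], ignore_index=True)
    else:
        src_view = base.assign(
            viewpoint=base["source"],
            k=stats["k"].reindex(base["source"]).to_numpy(),
            s=stats["s"].reindex(base["source"]).to_numpy(),
        )
        tgt_view = base.assign(
            viewpoint=base["target"],
            k=stats["k"].reindex(base["target"]).to_numpy(),
            s=stats["s"].reindex(base["target"]).to_numpy(),
        )
        rows = pd.concat([src_view, tgt_view], ignore_index=True)
    rows["k"] = rows["k"].astype(int)
    return rows


def link_pvalues(net: WeightedNetwork, a: float, mode: str = "auto") -> TestTable:
    """Assign the two per-link p-values of the Pólya filter.

    Parameters
    ----------
    a : float
        Reinforcement parameter (>= 0).
    mode : {"auto", "exact", "approx", "ratio"}
        ``exact`` sums the Beta-Binomial tail (whole-number weights only);
        ``approx`` uses the large-strength form (mandatory for real weights);
        ``ratio`` uses the r-only form; ``auto`` picks exact for integer
        weights with per-observation strength <= 1e5, approx otherwise.
    """
    if a < 0:
        raise DomainError("reinforcement parameter a must be >= 0")
    if mode not in MODES:
        raise ModeError(f"unknown mode {mode!r}; choose from {MODES}")
    integer = net.weight_kind == INTEGER
    if mode == "exact" and not integer:
        raise ModeError("exact mode requires integer weights; use mode='approx' "
                        "(the p-value is then assigned to the rate w/s)")
    if not integer and a == 0 and mode in ("auto", "approx", "ratio"):
        raise DomainError("a = 0 with real-valued weights is not defined: the "
                          "binomial limit needs whole numbers and the "
                          "approximation needs a > 0")
    rows = _viewpoint_rows(net)
    w = rows["w"].to_numpy()
    k = rows["k"].to_numpy(dtype=float)
    s = rows["s"].to_numpy()
    p = np.ones(len(rows))
    used = np.array(["degenerate"] * len(rows), dtype=object)
    live = k > 1  # degree-1 viewpoints keep p = 1
    if mode == "auto":
        exact_sel = live & integer & (s <= AUTO_EXACT_MAX_S) if integer else np.zeros_like(live)
        approx_sel = live & ~exact_sel
    elif mode == "exact":
        exact_sel = live
        approx_sel = np.zeros_like(live)
    else:
        exact_sel = np.zeros_like(live)
        approx_sel = live
    if np.any(exact_sel):
        p[exact_sel] = np.atleast_1d(polya_pvalue(w[exact_sel], k[exact_sel], s[exact_sel], a))
        used[exact_sel] = "exact"
    if np.any(approx_sel):
        if mode == "ratio":
            p[approx_sel] = np.atleast_1d(
                polya_pvalue_ratio(ratio_r(w[approx_sel], k[approx_sel], s[approx_sel]), a)
            )
            used[approx_sel] = "ratio"
        else:
            p[approx_sel] = np.atleast_1d(
                polya_pvalue_approx(w[approx_sel], k[approx_sel], s[approx_sel], a)
            )
            used[approx_sel] = "approx"
    rows["r"] = ratio_r(w, k, s)
    rows["p_value"] = p
    rows["mode"] = used
    frame = rows[
        ["link_id", "source", "target", "viewpoint", "w", "k", "s", "r", "p_value", "mode"]
    ]
    return TestTable(frame=frame, L=len(frame), directed=net.directed, a=float(a))


@dataclass(frozen=True)
class Backbone:
    """Subnetwork retained at (a, alpha_u, correction), with provenance.

    ``links`` has columns ``source``, ``target``, ``weight``,
    ``p_value_min``; weights are unchanged from the parent.
    """

    parent: WeightedNetwork = field(repr=False)
    links: pd.DataFrame = field(repr=False)
    a: float
    alpha_u: float
    correction: str
    L: int

    @property
    def n_links(self) -> int:
        return len(self.links)

    def node_set(self) -> set:
        """Endpoints of retained links."""
        return set(self.links["source"]) | set(self.links["target"])

    def link_keys(self) -> set:
        if self.parent.directed:
            return set(zip(self.links["source"], self.links["target"]))
        return {tuple(sorted(p)) for p in zip(self.links["source"], self.links["target"])}

    def to_network(self) -> WeightedNetwork:
        return WeightedNetwork.from_links(
            self.links[["source", "target", "weight"]].itertuples(index=False),
            directed=self.parent.directed,
        )


def extract_backbone(
    net: WeightedNetwork,
    a: float,
    alpha_u: float = 0.05,
    correction: str = "bonferroni",
    mode: str = "auto",
) -> Backbone:
    """Extract the backbone of statistically significant links.

    A link is retained when at least one of its two viewpoint p-values is
    significant: strictly below ``alpha_u / L`` under Bonferroni, accepted by
    the Benjamini-Hochberg step-up on the family of L tests under ``fdr``, or
    strictly below ``alpha_u`` with no correction.
    """
    if not (0.0 < alpha_u < 1.0):
        raise DomainError(f"alpha_u must be in (0, 1), got {alpha_u}")
    if correction not in CORRECTIONS:
        raise DomainError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    tt = link_pvalues(net, a, mode=mode)
    pmin = tt.min_pvalues()
    if correction == "bonferroni":
        keep_ids = pmin.index[pmin < alpha_u / tt.L]
    elif correction == "none":
        keep_ids = pmin.index[pmin < alpha_u]
    else:  # BH step-up over all L tests; keep links with >= 1 accepted test
        adj = false_discovery_control(tt.frame["p_value"].to_numpy(), method="bh")
        accepted = tt.frame.loc[adj <= alpha_u, "link_id"].unique()
        keep_ids = pd.Index(sorted(accepted))
    kept = net.links.iloc[np.asarray(keep_ids, dtype=int)].copy()
    kept["p_value_min"] = pmin.reindex(keep_ids).to_numpy()
    kept = kept.reset_index(drop=True)
    return Backbone(
        parent=net,
        links=kept,
        a=float(a),
        alpha_u=float(alpha_u),
        correction=correction,
        L=tt.L,
    )


class BackboneSummary(NamedTuple):
    fraction_links: float
    fraction_nodes: float
    fraction_strength: float


def backbone_summary(b: Backbone) -> BackboneSummary:
    """Fractions of links, nodes and total strength retained in a backbone.

    All three are monotonically non-increasing in a at fixed alpha_u.  The
    node fraction counts endpoints of retained links over all parent nodes.
    """
    parent = b.parent
    if parent.n_links == 0:
        return BackboneSummary(0.0, 0.0, 0.0)
    f_links = b.n_links / parent.n_links
    f_nodes = len(b.node_set()) / parent.n_nodes if parent.n_nodes else 0.0
    f_strength = float(b.links["weight"].sum()) / parent.total_weight
    return BackboneSummary(f_links, f_nodes, f_strength)


def top_b_jaccard(net: WeightedNetwork, b: Backbone) -> float:
    """Jaccard similarity between the backbone's links and the B heaviest links.

    B is the backbone size; the comparison set is the top-B links of the
    parent by weight (ties broken lexicographically for determinism).  This
    measures how different the backbone is from naive weight thresholding:
    1 means pure thresholding, small values mean a heterogeneous backbone.
    An empty backbone returns 0 by convention.
    """
    B = b.n_links
    if B == 0:
        return 0.0
    order = net.links.sort_values(
        by=["weight", "source", "target"], ascending=[False, True, True], kind="mergesort"
    ).head(B)
    if net.directed:
        top = set(zip(order["source"], order["target"]))
    else:
        top = {tuple(sorted(p)) for p in zip(order["source"], order["target"])}
    kept = b.link_keys()
    union = kept | top
    return len(kept & top) / len(union)
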