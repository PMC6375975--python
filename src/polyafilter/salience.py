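"""Link salience and the salience-based optimality criteria O1/O2.

The salience of a link is the fraction of per-node weighted shortest-path
trees that contain it.  Link weights are proximities, so path lengths use the
standard conversion distance = 1/w (heavier links are shorter).  One tree is
grown per reference node over its reachable set; predecessors are chosen
deterministically, breaking distance ties by the smallest node index in the
network's canonical (first-appearance) ordering.

The optimality criteria balance the salience a backbone retains against how
much of the network it throws away:

    O1(a) = J(W, P_a) * <S(a)>,    O2(a) = F_n(a) * <S(a)>,

where <S(a)> is the mean parent-network salience of retained links, J is the
weighted Jaccard similarity between the parent's and the backbone's weight
assignments (the backbone's weights being a subset, this equals the retained
strength fraction), and F_n is the fraction of nodes retained.  Both
typically rise and then fall in a, giving an interior optimum a*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .filtering import backbone_summary, extract_backbone
from .network import WeightedNetwork

__all__ = [
    "SalienceTable",
    "OptimalityReport",
    "OptimalityScan",
    "link_salience",
    "optimality_measures",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class SalienceTable:
    """Per-link salience values.

    ``frame`` has columns ``source``, ``target``, ``weight``, ``salience``
    aligned with the parent's link table; ``n_reference`` is the number of
    reference nodes (all nodes of the network).
    """

    frame: pd.DataFrame = field(repr=False)
    n_reference: int

    def values(self) -> np.ndarray:
        return self.frame["salience"].to_numpy()


def link_salience(net: WeightedNetwork) -> SalienceTable:
    """Fraction of weighted shortest-path trees each link participates in."""
    n = net.n_nodes
    m = net.n_links
    frame = net.links[["source", "target", "weight"]].copy()
    if m == 0 or n == 0:
        frame["salience"] = np.zeros(m)
        return SalienceTable(frame=frame, n_reference=n)
    node_ix = {node: i for i, node in enumerate(net.nodes)}
    src = net.links["source"].map(node_ix).to_numpy()
    tgt = net.links["target"].map(node_ix).to_numpy()
    length = 1.0 / net.links["weight"].to_numpy()
    if net.directed:
        eu, ev, el, eid = src, tgt, length, np.arange(m)
    else:
        eu = np.concatenate([src, tgt])
        ev = np.concatenate([tgt, src])
        el = np.concatenate([length, length])
        eid = np.concatenate([np.arange(m), np.arange(m)])
    graph = csr_matrix((el, (eu, ev)), shape=(n, n))
    dist = dijkstra(graph, directed=True, indices=None)
    # pre-sort directed edges by (head, tail-index): the first candidate per
    # head is then the minimum-index predecessor
    order = np.lexsort((eu, ev))
    eu, ev, el, eid = eu[order], ev[order], el[order], eid[order]
    counts = np.zeros(m)
    for i in range(n):
        d = dist[i]
        du = d[eu]
        dv = d[ev]
        with np.errstate(invalid="ignore"):
            on_tree = (
                np.isfinite(du)
                & np.isfinite(dv)
                & (ev != i)
                & (np.abs(du + el - dv) <= _REL_TOL * np.maximum(1.0, dv))
            )
        sel = np.flatnonzero(on_tree)
        if len(sel) == 0:
            continue
        _, first = np.unique(ev[sel], return_index=True)
        counts[eid[sel[first]]] += 1.0
    frame["salience"] = counts / n
    return SalienceTable(frame=frame, n_reference=n)


@dataclass(frozen=True)
class OptimalityReport:
    """Salience-optimality components of one backbone."""

    a: float
    mean_salience: float
    jaccard: float
    fraction_nodes: float
    O1: float
    O2: float
    n_links: int


@dataclass(frozen=True)
class OptimalityScan:
    """O1/O2 evaluated over a grid of a, with the argmax of each."""

    reports: tuple
    a_star_O1: float
    a_star_O2: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.reports])


def optimality_measures(
    net: WeightedNetwork,
    alpha_u: float = 0.05,
    correction: str = "bonferroni",
    a_grid=(0.2, 0.5, 1.0, 2.0, 4.0, 7.0),
    mode: str = "auto",
) -> OptimalityScan:
    """Evaluate O1 and O2 over a grid of the reinforcement parameter.

    Salience is computed once on the parent network; backbones are extracted
    per grid value.  Empty backbones score <S> = O1 = O2 = 0.
    """
    sal = link_salience(net)
    sal_values = sal.values()
    reports = []
    for a in a_grid:
        b = extract_backbone(net, a, alpha_u=alpha_u, correction=correction, mode=mode)
        summ = backbone_summary(b)
        if b.n_links == 0:
            mean_s = 0.0
        else:
            mean_s = float(np.mean(sal_values[_kept_positions(net, b)]))
        jac = summ.fraction_strength  # weighted Jaccard of nested weight sets
        f_n = summ.fraction_nodes
        reports.append(
            OptimalityReport(
                a=float(a),
                mean_salience=mean_s,
                jaccard=jac,
                fraction_nodes=f_n,
                O1=jac * mean_s,
                O2=f_n * mean_s,
                n_links=b.n_links,
            )
        )
    best1 = max(reports, key=lambda r: r.O1)
    best2 = max(reports, key=lambda r: r.O2)
    return OptimalityScan(reports=tuple(reports), a_star_O1=best1.a, a_star_O2=best2.a)


def _kept_positions(net: WeightedNetwork, b) -> np.ndarray:
    """Positions in the parent link table of the backbone's links."""
    if net.directed:
        keys = pd.MultiIndex.from_arrays([net.links["source"], net.links["target"]])
        kept = pd.MultiIndex.from_arrays([b.links["source"], b.links["target"]])
    else:
        def canon(df):
            lo = np.minimum(df["source"], df["target"])
            hi = np.maximum(df["source"], df["target"])
            return pd.MultiIndex.from_arrays([lo, hi])

        keys = canon(net.links)
        kept = canon(b.links)
    pos = keys.get_indexer(kept)
    return pos[pos >= 0]
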