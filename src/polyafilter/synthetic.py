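"""Seeded synthetic networks whose weight allocation follows the Pólya null.

Each viewpoint node allocates an integer strength s over k links by a
symmetric Dirichlet-multinomial with concentration 1/a per category.  This is
the exchangeable Pólya allocation: the marginal weight on any single link is
exactly the Beta-Binomial null of the filter, so every stage of the pipeline
(p-values, backbones, likelihood fits) can be tested against known ground
truth without external data.  a = 0 degenerates to an equal-probability
multinomial.

Cells drawn as zero are emitted as absent links (a zero weight means no
link), so a node's realized degree can be below k when a is large; the
weights of the emitted links still sum exactly to s.  Planted signal links
overwrite the drawn weight and the remainder of the strength is reallocated
over the remaining links, preserving the per-node total.

Two topologies are supported: ``out_stubs`` (directed; each source allocates
s over its own k targets, which have in-degree 1) and ``star`` (undirected;
each hub allocates over its own leaves, which have degree 1).  Leaves and
stub targets are degenerate viewpoints, so all statistical structure sits in
the allocating nodes -- exactly the regime the null describes.  A joint
undirected generative model consistent from both endpoints of every link is
not defined by the null and is deliberately not invented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .network import WeightedNetwork

__all__ = [
    "SyntheticSpec",
    "generate_polya_network",
    "sample_null_weights",
    "fig1_fixture",
]

TOPOLOGIES = ("out_stubs", "star")


def sample_null_weights(k: int, s: int, a: float, size: int, rng) -> np.ndarray:
    """Draws from the Beta-Binomial null: weight on one link of a (k, s) node.

    Implemented as the beta-binomial compound p ~ Beta(1/a, (k-1)/a),
    w ~ Binomial(s, p); at a = 0, w ~ Binomial(s, 1/k); at k = 1, w = s.
    """
    if k < 1 or s < 0 or a < 0:
        raise DomainError("need k >= 1, s >= 0, a >= 0")
    if k == 1:
        return np.full(size, s, dtype=np.int64)
    if a == 0:
        return rng.binomial(s, 1.0 / k, size=size)
    p = rng.beta(1.0 / a, (k - 1.0) / a, size=size)
    return rng.binomial(s, p)


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic Pólya-null network.

    ``k`` and ``s`` may be scalars (all viewpoint nodes alike) or sequences
    of length ``n_viewpoints``.  ``signal_links`` maps (source, target) node
    names -- following the generator's naming scheme, see
    :func:`generate_polya_network` -- to forced integer weights.  Given a
    seed the output is bit-reproducible.
    """

    topology: str = "out_stubs"
    n_viewpoints: int = 100
    k: object = 10
    s: object = 1000
    a_true: float = 1.0
    signal_links: dict = field(default_factory=dict)
    seed: int | None = None

    def generate(self) -> WeightedNetwork:
        return generate_polya_network(
            self.n_viewpoints,
            self.k,
            self.s,
            self.a_true,
            topology=self.topology,
            signal_links=self.signal_links,
            seed=self.seed,
        )

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        signal = {tuple(k.split("|")): int(v) for k, v in raw.pop("signal_links", {}).items()}
        return cls(signal_links=signal, **raw)


def _viewpoint_name(topology: str, i: int) -> str:
    return f"{'S' if topology == 'out_stubs' else 'H'}{i:05d}"


def _stub_name(topology: str, i: int, j: int) -> str:
    return f"{_viewpoint_name(topology, i)}{'T' if topology == 'out_stubs' else 'L'}{j:03d}"


def _allocate(k: int, s: int, a: float, rng) -> np.ndarray:
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    if k == 1:
        return np.array([s], dtype=np.int64)
    if a == 0:
        return rng.multinomial(s, np.full(k, 1.0 / k))
    p = rng.dirichlet(np.full(k, 1.0 / a))
    return rng.multinomial(s, p)


def generate_polya_network(
    n_viewpoints: int,
    k,
    s,
    a_true: float,
    topology: str = "out_stubs",
    signal_links: dict | None = None,
    seed: int | None = None,
    rng=None,
) -> WeightedNetwork:
    """Generate a network whose weight allocation follows the Pólya null.

    Viewpoint node ``i`` is named ``S00000``-style (``H`` for star hubs) and
    its j-th potential neighbour ``S00000T000`` (``L`` for leaves).  Each
    viewpoint allocates its strength over its k potential links by a
    Dirichlet-multinomial with concentration 1/a_true; zero cells become
    absent links.  ``signal_links`` entries force the weight on a named
    potential link; the remaining strength is reallocated over the other
    cells of that viewpoint, so per-node totals are preserved.
    """
    if topology not in TOPOLOGIES:
        raise DomainError(f"unsupported topology {topology!r}; choose from {TOPOLOGIES} "
                          "(a joint undirected non-star null is not defined)")
    if a_true < 0:
        raise DomainError("a_true must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ks = np.broadcast_to(np.asarray(k, dtype=np.int64), (n_viewpoints,))
    ss = np.broadcast_to(np.asarray(s, dtype=np.int64), (n_viewpoints,))
    signal = dict(signal_links or {})
    triples = []
    nodes = []
    for i in range(n_viewpoints):
        vp = _viewpoint_name(topology, i)
        ki, si = int(ks[i]), int(ss[i])
        stubs = [_stub_name(topology, i, j) for j in range(ki)]
        forced = {j: int(signal.pop((vp, stub))) for j, stub in enumerate(stubs)
                  if (vp, stub) in signal}
        w = np.zeros(ki, dtype=np.int64)
        if forced:
            total_forced = sum(forced.values())
            if total_forced > si:
                raise DomainError(f"planted weights on {vp} exceed its strength {si}")
            free = [j for j in range(ki) if j not in forced]
            w[free] = _allocate(len(free), si - total_forced, a_true, rng)
            for j, wf in forced.items():
                w[j] = wf
        else:
            w = _allocate(ki, si, a_true, rng)
        nodes.append(vp)
        for j, stub in enumerate(stubs):
            nodes.append(stub)
            if w[j] > 0:
                triples.append((vp, stub, float(w[j])))
    if signal:
        raise DomainError(f"signal_links refer to unknown links: {sorted(signal)}")
    return WeightedNetwork.from_links(
        triples, directed=topology == "out_stubs", nodes=nodes
    )


def fig1_fixture() -> WeightedNetwork:
    """The worked-example star: hub A with links A-B (w=2), A-C (1), A-D (1).

    Node A has degree k = 3 and strength s = 4; at a = 1 the p-value of the
    A-B link from A's viewpoint is exactly 0.4.
    """
    return WeightedNetwork.from_links(
        [("A", "B", 2.0), ("A", "C", 1.0), ("A", "D", 1.0)], directed=False
    )
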