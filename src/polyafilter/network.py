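"""Weighted-network container and plain-text edge-list I/O.

The in-memory representation is deliberately small: an ordered node list, a
pandas DataFrame of links (``source``, ``target``, ``weight``), a directedness
flag and a weight-kind flag.  A zero or absent weight means "no link"; weights
must be strictly positive.  Node identifiers are opaque, case-sensitive
strings.

Edge lists are delimiter-separated text with columns source/target/weight.
``#`` lines are comments, a header row is auto-detected, and the delimiter is
sniffed (comma if present, otherwise any run of whitespace).  Output always
uses tabs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .filtering import Backbone

__all__ = [
    "WeightedNetwork",
    "NodeStats",
    "read_edgelist",
    "write_backbone",
    "node_stats",
]

INTEGER = "integer"
REAL = "real"


@dataclass(frozen=True)
class WeightedNetwork:
    """A validated weighted network.

    Attributes
    ----------
    nodes : tuple of str
        Node identifiers in first-appearance order.  May include isolated
        nodes only if they were listed explicitly by the caller.
    links : pandas.DataFrame
        Columns ``source``, ``target``, ``weight`` (float64).  For undirected
        networks each unordered pair is stored once.
    directed : bool
    weight_kind : {"integer", "real"}
        ``integer`` iff every weight is a whole number.
    """

    nodes: tuple
    links: pd.DataFrame = field(repr=False)
    directed: bool
    weight_kind: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def total_weight(self) -> float:
        return float(self.links["weight"].sum())

    def link_keys(self) -> list:
        """Canonical hashable key per link (unordered pair if undirected)."""
        out = []
        for s, t in zip(self.links["source"], self.links["target"]):
            out.append((s, t) if self.directed else tuple(sorted((s, t))))
        return out

    @classmethod
    def from_links(
        cls,
        links: Iterable[tuple],
        directed: bool,
        nodes: Sequence | None = None,
    ) -> "WeightedNetwork":
        """Build and validate a network from ``(source, target, weight)`` triples.

        Undirected inputs containing both ``(u, v)`` and ``(v, u)`` must carry
        equal weights and are stored once.  Duplicate links are an error, not
        aggregated.
        """
        seen: dict[tuple, float] = {}
        order: list[tuple] = []
        node_order: dict = {}
        if nodes is not None:
            for n in nodes:
                node_order.setdefault(str(n), None)
        for i, (src, tgt, w) in enumerate(links):
            src, tgt = str(src), str(tgt)
            w = float(w)
            if src == tgt:
                raise FormatError(f"link {i}: self-loop on node {src!r}")
            if not math.isfinite(w) or w <= 0:
                raise FormatError(f"link {i} ({src!r}-{tgt!r}): non-positive weight {w!r}")
            key = (src, tgt) if directed else tuple(sorted((src, tgt)))
            if key in seen:
                if directed or seen[key] != w:
                    raise FormatError(
                        f"link {i}: duplicate link {src!r}-{tgt!r} "
                        f"with weight {w!r} (existing weight {seen[key]!r})"
                    )
                continue  # symmetric duplicate with equal weight: keep once
            seen[key] = w
            order.append((src, tgt, w))
            node_order.setdefault(src, None)
            node_order.setdefault(tgt, None)
        frame = pd.DataFrame(order, columns=["source", "target", "weight"])
        frame["weight"] = frame["weight"].astype(np.float64)
        kind = INTEGER if bool((frame["weight"] % 1 == 0).all()) else REAL
        return cls(
            nodes=tuple(node_order),
            links=frame,
            directed=bool(directed),
            weight_kind=kind,
        )


@dataclass(frozen=True)
class NodeStats:
    """Degree/strength record for a single node (directed: out/in variants)."""

    node: str
    k: int = 0
    s: float = 0.0
    k_out: int = 0
    s_out: float = 0.0
    k_in: int = 0
    s_in: float = 0.0


def node_stats(net: WeightedNetwork) -> pd.DataFrame:
    """Per-node degree and strength table.

    Returns a DataFrame indexed by node: columns ``k``, ``s`` for undirected
    networks, ``k_out``, ``s_out``, ``k_in``, ``s_in`` for directed ones.
    Isolated nodes appear with zeros.
    """
    idx = pd.Index(net.nodes, name="node")
    lk = net.links
    if net.directed:
        out = pd.DataFrame(
            {
                "k_out": lk.groupby("source").size(),
                "s_out": lk.groupby("source")["weight"].sum(),
                "k_in": lk.groupby("target").size(),
                "s_in": lk.groupby("target")["weight"].sum(),
            }
        )
        out = out.reindex(idx).fillna(0.0)
        out[["k_out", "k_in"]] = out[["k_out", "k_in"]].astype(int)
        return out
    ends = pd.concat(
        [
            lk[["source", "weight"]].rename(columns={"source": "node"}),
            lk[["target", "weight"]].rename(columns={"target": "node"}),
        ]
    )
    out = pd.DataFrame(
        {"k": ends.groupby("node").size(), "s": ends.groupby("node")["weight"].sum()}
    )
    out = out.reindex(idx).fillna(0.0)
    out["k"] = out["k"].astype(int)
    return out


def _sniff_fields(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_edgelist(path, directed: bool) -> WeightedNetwork:
    """Read a delimited edge list into a :class:`WeightedNetwork`.

    Columns are source, target, weight (extra columns are ignored, so backbone
    files written by :func:`write_backbone` can be re-read).  ``#`` lines are
    comments; an optional header row is detected by a non-numeric third field.
    """
    triples: list[tuple] = []
    header_allowed = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _sniff_fields(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}")
            try:
                w = float(fields[2])
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
            header_allowed = False
            if not math.isfinite(w) or w <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive weight {fields[2]!r}")
            triples.append((fields[0], fields[1], w))
    try:
        return WeightedNetwork.from_links(triples, directed=directed)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def _fmt_weight(w: float, kind: str) -> str:
    if kind == INTEGER:
        return str(int(round(w)))
    return repr(float(w))


def write_backbone(backbone: "Backbone", path) -> None:
    """Write a backbone as a tab-delimited edge list with provenance header.

    Columns: source, target, weight, p_value_min.  The ``#`` header records
    the reinforcement parameter ``a``, the univariate significance level, the
    correction, and the number of tests ``L``.
    """
    kind = backbone.parent.weight_kind
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# polyafilter backbone\n")
        fh.write(
            f"# a={backbone.a!r} alpha_u={backbone.alpha_u!r} "
            f"correction={backbone.correction} L={backbone.L}\n"
        )
        fh.write("source\ttarget\tweight\tp_value_min\n")
        for row in backbone.links.itertuples(index=False):
            fh.write(
                f"{row.source}\t{row.target}\t{_fmt_weight(row.weight, kind)}\t"
                f"{row.p_value_min!r}\n"
            )
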