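"""Markov state networks on a one-dimensional scaffold.

A :class:`StochasticNetwork` is a continuous-time Markov chain whose states
carry an integer horizontal coordinate ``x`` (the axis along which probability
currents are counted) and an internal ``row`` index.  Each directed edge
carries a positive rate and an integer displacement ``disp`` recording how far
the jump moves along the horizontal axis.  The displacement is stored
explicitly rather than derived from coordinates so that a hop across a
periodic seam counts as +1 or -1, never as the raw coordinate difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "StateNode",
    "RateEdge",
    "StochasticNetwork",
    "NetworkError",
    "NODE_TAGS",
]

NODE_TAGS = frozenset({"bulk_L", "bulk_R", "interface", "vacuum_boundary"})

ALLOWED_DISPS = (-1, 0, 1)


class NetworkError(ValueError):
    """Raised when a network violates its structural invariants."""


@dataclass(frozen=True)
class StateNode:
    """A mesoscopic state with a horizontal coordinate and internal row."""

    id: str
    x: int
    row: int = 0
    tag: str = "bulk_L"

    def __post_init__(self) -> None:
        if self.tag not in NODE_TAGS:
            raise NetworkError(
                f"node {self.id!r}: unknown tag {self.tag!r}; "
                f"expected one of {sorted(NODE_TAGS)}"
            )


@dataclass(frozen=True)
class RateEdge:
    """Directed transition src -> dst with rate > 0 and displacement.

    ``disp`` is the winding-corrected horizontal displacement counted by the
    current functional: +1 for a rightward hop, -1 for leftward, 0 for a
    purely internal (vertical) transition.
    """

    src: str
    dst: str
    rate: float
    disp: int = 0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise NetworkError(
                f"edge {self.src!r}->{self.dst!r}: rate must be positive, "
                f"got {self.rate}"
            )
        if self.disp not in ALLOWED_DISPS:
            raise NetworkError(
                f"edge {self.src!r}->{self.dst!r}: disp {self.disp} is not "
                f"supported (allowed: -1, 0, +1; larger hops are reserved)"
            )


class StochasticNetwork:
    """Directed rate graph of a continuous-time Markov chain.

    Parameters
    ----------
    nodes:
        Ordered collection of :class:`StateNode`.  The node order fixes the
        index order of every matrix built from the network.
    edges:
        Collection of :class:`RateEdge`.  At most one edge per ordered node
        pair; no self-edges.
    boundary:
        ``"periodic"`` or ``"open"`` along the horizontal axis.
    metadata:
        Free-form provenance map (builder name, parameters, disorder seed).

    Raises
    ------
    NetworkError
        If ids are duplicated, edges dangle or repeat, or the graph is not
        strongly connected (the error names the disconnected components).
    """

    def __init__(
        self,
        nodes: Iterable[StateNode],
        edges: Iterable[RateEdge],
        boundary: str = "open",
        metadata: Mapping | None = None,
    ) -> None:
        self.nodes: tuple[StateNode, ...] = tuple(nodes)
        self.edges: tuple[RateEdge, ...] = tuple(edges)
        if boundary not in ("periodic", "open"):
            raise NetworkError(f"boundary must be 'periodic' or 'open', got {boundary!r}")
        self.boundary = boundary
        self.metadata: dict = dict(metadata) if metadata else {}
        self._index: dict[str, int] = {}
        self._validate()

    # -- invariants -------------------------------------------------------

    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate node ids: {dupes}")
        self._index = {n.id: k for k, n in enumerate(self.nodes)}
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.src not in self._index or e.dst not in self._index:
                raise NetworkError(f"edge {e.src!r}->{e.dst!r} references unknown node")
            if e.src == e.dst:
                raise NetworkError(f"self-edge on node {e.src!r} is not allowed")
            pair = (e.src, e.dst)
            if pair in seen_pairs:
                raise NetworkError(f"duplicate edge {e.src!r}->{e.dst!r}")
            seen_pairs.add(pair)
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        g.add_edges_from((e.src, e.dst) for e in self.edges)
        if not nx.is_strongly_connected(g):
            comps = [sorted(c) for c in nx.strongly_connected_components(g)]
            comps.sort(key=len)
            raise NetworkError(
                f"network is reducible: {len(comps)} strongly connected "
                f"components, e.g. {comps[0]}"
            )

    # -- lookups ----------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.nodes)

    def index(self, node_id: str) -> int:
        """Position of ``node_id`` in the node order."""
        return self._index[node_id]

    def node(self, node_id: str) -> StateNode:
        return self.nodes[self._index[node_id]]

    def columns(self) -> list[int]:
        """Sorted distinct horizontal coordinates present in the network."""
        return sorted({n.x for n in self.nodes})

    def with_rates(self, rates: Iterable[float], metadata: Mapping | None = None
                   ) -> "StochasticNetwork":
        """Copy of the network with edge rates replaced (same edge order)."""
        rates = list(rates)
        if len(rates) != len(self.edges):
            raise NetworkError("rate list length does not match edge count")
        new_edges = [
            RateEdge(e.src, e.dst, r, e.disp) for e, r in zip(self.edges, rates)
        ]
        md = dict(self.metadata)
        if metadata:
            md.update(metadata)
        return StochasticNetwork(self.nodes, new_edges, self.boundary, md)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StochasticNetwork({self.n_states} states, {len(self.edges)} edges, "
            f"boundary={self.boundary!r})"
        )
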