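"""Signed weighted directed network container shared across the pipeline.

The adjacency convention follows the rate-equation orientation used
throughout the package: ``A[i, j]`` is the signed influence of source node
``j`` on target node ``i`` (positive = activation, negative = inhibition,
zero = no interaction).  The diagonal holds self-degradation terms and is
excluded from edge bookkeeping unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

#: Canonical node order for the nine aggregate cytokine functional sets.
AGGREGATE_NODES: tuple[str, ...] = (
    "MK1A",
    "MK1B",
    "MK2",
    "MK6",
    "MK15",
    "MK23",
    "CK1",
    "CK2",
    "CK17",
)


@dataclass
class SignedWeightedDigraph:
    """A directed signed weighted network over a fixed node set.

    Parameters
    ----------
    node_names:
        Ordered node labels; defines row/column order of ``A``.
    A:
        Square adjacency matrix, ``A[i, j]`` = influence of ``node_names[j]``
        on ``node_names[i]``.
    """

    node_names: tuple[str, ...]
    A: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.node_names)
        if self.A.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match "
                f"{n} node names"
            )

    # -- construction ------------------------------------------------------
    @classmethod
    def empty(cls, node_names: Sequence[str]) -> "SignedWeightedDigraph":
        n = len(node_names)
        return cls(tuple(node_names), np.zeros((n, n)))

    @classmethod
    def from_edges(
        cls,
        node_names: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
    ) -> "SignedWeightedDigraph":
        """Build from ``(source, target, weight)`` triples."""
        g = cls.empty(node_names)
        idx = g.index
        for src, tgt, w in edges:
            g.A[idx[tgt], idx[src]] = w
        return g

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.node_names)}

    def edges(self, include_diagonal: bool = False) -> Iterator[
        tuple[str, str, float]
    ]:
        """Yield ``(source, target, weight)`` for nonzero entries."""
        for i, tgt in enumerate(self.node_names):
            for j, src in enumerate(self.node_names):
                if i == j and not include_diagonal:
                    continue
                w = self.A[i, j]
                if w != 0.0:
                    yield (src, tgt, w)

    def edge_set(self, signed: bool = False) -> set[tuple]:
        """Directed edge set: ``(source, target)`` or ``(source, target, sign)``."""
        if signed:
            return {(s, t, int(np.sign(w))) for s, t, w in self.edges()}
        return {(s, t) for s, t, _ in self.edges()}

    def n_edges(self) -> int:
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))

    def weight(self, source: str, target: str) -> float:
        idx = self.index
        return float(self.A[idx[target], idx[source]])

    def copy(self) -> "SignedWeightedDigraph":
        return SignedWeightedDigraph(self.node_names, self.A.copy())

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` with ``weight``/``sign`` attrs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for src, tgt, w in self.edges():
            g.add_edge(src, tgt, weight=abs(w), sign=int(np.sign(w)), length=1.0 / abs(w))
        return g

    def reorder(self, node_names: Sequence[str]) -> "SignedWeightedDigraph":
        """Return a copy with rows/columns permuted to the given node order."""
        if set(node_names) != set(self.node_names):
            raise ValueError("node sets differ")
        perm = [self.index[n] for n in node_names]
        return SignedWeightedDigraph(
            tuple(node_names), self.A[np.ix_(perm, perm)]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedWeightedDigraph):
            return NotImplemented
        return self.node_names == other.node_names and np.array_equal(
            self.A, other.A
        )


def check_same_nodes(*graphs: SignedWeightedDigraph) -> None:
    names = graphs[0].node_names
    for g in graphs[1:]:
        if g.node_names != names:
            raise ValueError("graphs have mismatched node sets/orders")
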