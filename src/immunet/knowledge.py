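"""Literature-informed reference network construction.

Builds the 9-node reference network of aggregate cytokine-set signaling:
immune-cell intermediates are collapsed out of a mixed cytokine/cell
signed digraph (sign of a cytokine->cell->cytokine path is the product of
the two edge signs; only direct and second-neighbour links are kept),
cytokines are mapped onto their functional sets, imported interaction
tables are filtered by confidence, and networks are merged by union with
overlap accounting.

The packaged 9-node, 50-edge reference edge list is a synthetic stand-in
with plausible signs; see ``data/reference_network_synthetic.tsv``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .aggregates import functional_set_map
from .graph import AGGREGATE_NODES, SignedWeightedDigraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignedEdge:
    """A directed signed interaction with optional confidence/provenance."""

    source: str
    target: str
    sign: int
    weight: float = 1.0
    confidence: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):  # 0 marks an ambiguous-sign edge
            raise ValueError("sign must be -1, 0 (ambiguous) or +1")


@dataclass
class ReferenceNetwork:
    """Union reference network over the nine aggregate sets."""

    node_names: tuple[str, ...]
    edges: dict[tuple[str, str], SignedEdge]
    source_tally: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self, signed: bool = False) -> set[tuple]:
        if signed:
            return {(e.source, e.target, e.sign) for e in self.edges.values()}
        return set(self.edges)

    def to_graph(self) -> SignedWeightedDigraph:
        """Signed weighted adjacency (ambiguous-sign edges carry weight 0)."""
        g = SignedWeightedDigraph.empty(self.node_names)
        idx = g.index
        for (src, tgt), e in self.edges.items():
            g.A[idx[tgt], idx[src]] = e.sign * abs(e.weight)
        return g


# ---------------------------------------------------------------------------
# Cell-node collapse

def collapse_intermediates(
    graph: nx.DiGraph, cell_nodes: Iterable[str]
) -> nx.DiGraph:
    """Collapse cytokine->cell->cytokine paths into signed direct edges.

    Keeps existing cytokine->cytokine edges; for each length-2 path through
    a single cell node adds an edge whose sign is the product of the two
    path signs.  Longer paths (e.g. through two cells) are not traversed.
    Parallel derivations of one edge with conflicting signs are resolved to
    an ambiguous sign 0.
    """
    cells = set(cell_nodes)
    unlabeled = set(graph.nodes) - cells
    out = nx.DiGraph()
    out.add_nodes_from(unlabeled)
    derived: dict[tuple[str, str], set[int]] = {}
    for u, v, data in graph.edges(data=True):
        sign = int(data["sign"])
        if u in cells or v in cells:
            continue
        derived.setdefault((u, v), set()).add(sign)
    for cell in cells:
        for u in graph.predecessors(cell):
            if u in cells:
                continue
            s_in = int(graph[u][cell]["sign"])
            for v in graph.successors(cell):
                if v in cells or v == u:
                    continue
                s_out = int(graph[cell][v]["sign"])
                derived.setdefault((u, v), set()).add(s_in * s_out)
    for (u, v), signs in derived.items():
        if len(signs) == 1:
            out.add_edge(u, v, sign=signs.pop())
        else:
            logger.info("conflicting derived signs for %s->%s; ambiguous", u, v)
            out.add_edge(u, v, sign=0)
    return out


# ---------------------------------------------------------------------------
# Cytokine -> aggregate-set mapping

def map_to_aggregate_sets(
    cyt_net: nx.DiGraph,
    set_map: Mapping[str, str] | None = None,
) -> list[SignedEdge]:
    """Lift a cytokine-level signed digraph to the aggregate-set level.

    Edges between cytokines become edges between their sets; within-set
    edges are dropped; duplicates collapse by union.  Because MK1 is scored
    as two patterns, every edge incident to the MK1 block is emitted for
    both MK1A and MK1B.  Duplicate aggregate edges with conflicting signs
    resolve to the sign with the larger summed confidence (tie: ambiguous
    sign 0), logged.
    """
    set_map = dict(set_map) if set_map is not None else functional_set_map()
    votes: dict[tuple[str, str], dict[int, float]] = {}
    for u, v, data in cyt_net.edges(data=True):
        try:
            su, sv = set_map[u], set_map[v]
        except KeyError as exc:
            raise ValueError(f"cytokine {exc.args[0]} not mappable") from None
        if su == sv:
            continue
        sign = int(data["sign"])
        conf = float(data.get("confidence", 1.0) or 1.0)
        sources = ("MK1A", "MK1B") if su == "MK1" else (su,)
        targets = ("MK1A", "MK1B") if sv == "MK1" else (sv,)
        for a in sources:
            for b in targets:
                votes.setdefault((a, b), {}).setdefault(sign, 0.0)
                votes[(a, b)][sign] += conf
    out = []
    for (a, b), by_sign in sorted(votes.items()):
        if len(by_sign) == 1:
            (sign, conf), = by_sign.items()
        else:
            ranked = sorted(by_sign.items(), key=lambda kv: kv[1], reverse=True)
            if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
                logger.info("sign tie for %s->%s; marked ambiguous", a, b)
                sign, conf = 0, ranked[0][1]
            else:
                sign, conf = ranked[0]
                logger.info(
                    "sign conflict for %s->%s resolved to %+d", a, b, sign
                )
        out.append(SignedEdge(a, b, sign=sign, confidence=conf))
    return out


# ---------------------------------------------------------------------------
# Confidence filtering and union merge

def filter_by_confidence(
    edges: Sequence[SignedEdge], min_conf: float = 0.80
) -> list[SignedEdge]:
    """Retain edges with confidence >= ``min_conf`` (boundary inclusive)."""
    if any(e.confidence is None for e in edges):
        raise ValueError("all edges must carry a confidence score")
    kept = [e for e in edges if e.confidence >= min_conf]
    logger.info("confidence filter kept %d of %d edges", len(kept), len(edges))
    return kept


def _as_edge_dict(
    edges: Sequence[SignedEdge] | ReferenceNetwork,
) -> dict[tuple[str, str], SignedEdge]:
    if isinstance(edges, ReferenceNetwork):
        return dict(edges.edges)
    out = {}
    for e in edges:
        if (e.source, e.target) in out:
            raise ValueError(f"duplicate edge {e.source}->{e.target}")
        out[(e.source, e.target)] = e
    return out


def merge_networks(
    a: Sequence[SignedEdge] | ReferenceNetwork,
    b: Sequence[SignedEdge] | ReferenceNetwork,
    node_names: Sequence[str] = AGGREGATE_NODES,
) -> tuple[ReferenceNetwork, dict[str, int]]:
    """Union of two aggregate-level networks with overlap accounting.

    Overlap = edges sharing source, target and direction.  A shared edge
    with opposite signs is kept with ambiguous sign 0 and counted as a
    conflict.  Returns the merged network and a report with |a|, |b|,
    |overlap|, |union| and conflict count.
    """
    ea, eb = _as_edge_dict(a), _as_edge_dict(b)
    nodes = set(node_names)
    for e in list(ea.values()) + list(eb.values()):
        if e.source not in nodes or e.target not in nodes:
            raise ValueError(f"edge {e.source}->{e.target} outside node set")
    merged: dict[tuple[str, str], SignedEdge] = {}
    tally: dict[tuple[str, str], str] = {}
    conflicts = 0
    for key in set(ea) | set(eb):
        if key in ea and key in eb:
            tally[key] = "both"
            x, y = ea[key], eb[key]
            if x.sign == y.sign:
                merged[key] = x
            else:
                conflicts += 1
                logger.info("sign conflict on shared edge %s->%s", *key)
                merged[key] = SignedEdge(
                    key[0], key[1], sign=0,
                    confidence=max(
                        x.confidence or 0.0, y.confidence or 0.0
                    ) or None,
                    provenance="sign-conflict",
                )
        elif key in ea:
            merged[key], tally[key] = ea[key], "a"
        else:
            merged[key], tally[key] = eb[key], "b"
    report = {
        "n_a": len(ea),
        "n_b": len(eb),
        "n_overlap": sum(1 for v in tally.values() if v == "both"),
        "n_union": len(merged),
        "n_sign_conflicts": conflicts,
    }
    net = ReferenceNetwork(
        node_names=tuple(node_names), edges=merged, source_tally=tally
    )
    return net, report


# ---------------------------------------------------------------------------
# Edge-list I/O and the packaged reference fixture

def read_edge_list(path) -> list[SignedEdge]:
    """Read a ``source target sign weight confidence provenance`` TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"source", "target", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge list misses column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        conf = row.get("confidence")
        out.append(
            SignedEdge(
                source=str(row["source"]),
                target=str(row["target"]),
                sign=int(row["sign"]),
                weight=float(row.get("weight", 1.0)),
                confidence=None if pd.isna(conf) else float(conf),
                provenance=str(row.get("provenance", "")),
            )
        )
    return out


def write_edge_list(edges: Sequence[SignedEdge], path) -> str:
    df = pd.DataFrame(
        [
            {
                "source": e.source, "target": e.target, "sign": e.sign,
                "weight": e.weight, "confidence": e.confidence,
                "provenance": e.provenance,
            }
            for e in edges
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return str(path)


def load_reference_network() -> ReferenceNetwork:
    """Load the packaged synthetic 9-node, 50-edge reference network."""
    path = resources.files("immunet.data").joinpath(
        "reference_network_synthetic.tsv"
    )
    with resources.as_file(path) as p:
        edges = read_edge_list(p)
    return ReferenceNetwork(
        node_names=AGGREGATE_NODES,
        edges={(e.source, e.target): e for e in edges},
    )
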