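"""In-silico receptor blockade as graph editing.

A blockade of a mediator's receptors is modelled by removing all outgoing
edges of that network node (the node remains a regulatable target).  The
search evaluates every single node and unordered pair of nodes, scoring
each candidate by the graph edit distance between the edited source
network(s) and the target network(s) — e.g. an ill-group circuit against
the healthy-control circuit — and ranks candidates by ascending mean GED.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import SignedWeightedDigraph
from .netmetrics import graph_edit_distance


def apply_blockade(
    g: SignedWeightedDigraph, nodes: Sequence[str] | set[str]
) -> SignedWeightedDigraph:
    """Zero all outgoing edges of the blocked nodes (columns of A).

    Incoming edges and the self-degradation diagonal are untouched; the
    input graph is not modified.  Idempotent and commutative over node
    sets.
    """
    idx = g.index
    unknown = [n for n in nodes if n not in idx]
    if unknown:
        raise ValueError(f"unknown node(s): {unknown}")
    out = g.copy()
    for name in nodes:
        j = idx[name]
        diag = out.A[j, j]
        out.A[:, j] = 0.0
        out.A[j, j] = diag
    return out


@dataclass(frozen=True)
class InterventionResult:
    blocked_nodes: tuple[str, ...]
    ged_mean: float
    ged_se: float
    rank: int
    baseline_ged_mean: float

    @property
    def reduction_pct(self) -> float:
        if self.baseline_ged_mean == 0:
            return 0.0
        return 100.0 * (1.0 - self.ged_mean / self.baseline_ged_mean)


def _as_list(
    x: SignedWeightedDigraph | Sequence[SignedWeightedDigraph],
) -> list[SignedWeightedDigraph]:
    if isinstance(x, SignedWeightedDigraph):
        return [x]
    return list(x)


def rank_blockades(
    source: SignedWeightedDigraph | Sequence[SignedWeightedDigraph],
    target: SignedWeightedDigraph | Sequence[SignedWeightedDigraph],
    max_combo: int = 2,
    normalize: bool = True,
) -> list[InterventionResult]:
    """Exhaustive single/paired blockade search minimising GED to the target.

    For ensembles the GED mean and standard error are taken over all
    source x target cross pairs.  Results are sorted ascending by mean GED
    with lexicographic tie-breaking on node names; the no-blockade
    baseline is included as the empty candidate.
    """
    sources = _as_list(source)
    targets = _as_list(target)
    names = sources[0].node_names
    if max_combo > len(names):
        raise ValueError("max_combo exceeds the number of nodes")

    def mean_se(blocked: tuple[str, ...]) -> tuple[float, float]:
        edited = [apply_blockade(s, blocked) for s in sources]
        geds = [
            graph_edit_distance(e, t, normalize=normalize)
            for e in edited
            for t in targets
        ]
        arr = np.asarray(geds)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), se

    baseline_mean, baseline_se = mean_se(())
    candidates: list[tuple[tuple[str, ...], float, float]] = [
        ((), baseline_mean, baseline_se)
    ]
    for size in range(1, max_combo + 1):
        for combo in itertools.combinations(names, size):
            m, se = mean_se(combo)
            candidates.append((combo, m, se))
    candidates.sort(key=lambda c: (c[1], c[0]))
    return [
        InterventionResult(
            blocked_nodes=blocked,
            ged_mean=m,
            ged_se=se,
            rank=r + 1,
            baseline_ged_mean=baseline_mean,
        )
        for r, (blocked, m, se) in enumerate(candidates)
    ]
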