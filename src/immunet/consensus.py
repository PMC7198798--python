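"""Two-level consensus networks from repeated subject subsampling.

Level one: 100 random subsets of 10 subjects are drawn from each group;
within each subset an edge enters the consensus network when at least 6 of
the 10 subject networks carry it (majority rule on direction; sign by
majority among supporters, ties dropped; weight = median supporting weight
of the majority sign).  Level two: the "characteristic" network keeps only
edges present in every one of the 100 consensus networks (unanimity).
Concordance with a reference network is summarised as recall/PPV
distributions per consensus level.

Subject networks do not depend on the subsample they appear in, so they
are inferred once and cached; the subsampling then amounts to
edge-frequency analysis over subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import SignedWeightedDigraph, check_same_nodes
from .inference import edge_fscore
from .knowledge import ReferenceNetwork

logger = logging.getLogger(__name__)


def subject_subsamples(
    subject_ids: Sequence[str],
    subset_size: int = 10,
    n_subsamples: int = 100,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Random subject subsets, each drawn without replacement.

    Distinct draws may coincide (with 11 subjects and size 10 there are
    only 11 possible subsets).  Deterministic per seed; subjects are
    sorted before drawing so the result is order-independent.
    """
    ids = sorted(subject_ids)
    if subset_size > len(ids):
        raise ValueError(
            f"subset_size {subset_size} exceeds group size {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subsamples):
        pick = rng.choice(len(ids), size=subset_size, replace=False)
        out.append(tuple(ids[i] for i in np.sort(pick)))
    return out


def majority_consensus(
    networks: Sequence[SignedWeightedDigraph],
    quorum: int = 6,
) -> SignedWeightedDigraph:
    """Majority-rule consensus of subject networks.

    An edge is retained when present (nonzero, same direction) in at least
    ``quorum`` networks; its sign is the majority sign among supporters
    (tie: edge dropped, logged) and its weight the median signed weight of
    the majority-sign supporters.
    """
    if not networks:
        raise ValueError("empty network list")
    check_same_nodes(*networks)
    names = networks[0].node_names
    n = len(names)
    stack = np.stack([g.A for g in networks])        # nets x targets x sources
    out = SignedWeightedDigraph.empty(names)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = stack[:, i, j]
            support = w != 0.0
            if support.sum() < quorum:
                continue
            pos, neg = w[w > 0], w[w < 0]
            if pos.size == neg.size:
                logger.info(
                    "sign tie for edge %s->%s; dropped", names[j], names[i]
                )
                continue
            out.A[i, j] = (
                float(np.median(pos)) if pos.size > neg.size
                else float(np.median(neg))
            )
    return out


@dataclass
class NetworkEnsemble:
    """Consensus networks from repeated subsampling, with edge support."""

    group: str
    consensus_networks: list[SignedWeightedDigraph]
    subsamples: list[tuple[str, ...]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.consensus_networks:
            raise ValueError("an ensemble needs at least one network")
        check_same_nodes(*self.consensus_networks)

    @property
    def node_names(self) -> tuple[str, ...]:
        return self.consensus_networks[0].node_names

    def support_counts(self) -> dict[tuple[str, str], int]:
        """Edge -> number of consensus networks containing it."""
        counts: dict[tuple[str, str], int] = {}
        for g in self.consensus_networks:
            for edge in g.edge_set():
                counts[edge] = counts.get(edge, 0) + 1
        return counts


def build_ensemble(
    subject_networks: Mapping[str, SignedWeightedDigraph],
    group: str,
    subset_size: int = 10,
    n_subsamples: int = 100,
    quorum: int = 6,
    seed: int = 0,
) -> NetworkEnsemble:
    """Subsample subjects and form one consensus network per subsample."""
    subsamples = subject_subsamples(
        sorted(subject_networks), subset_size, n_subsamples, seed
    )
    nets = [
        majority_consensus([subject_networks[s] for s in sub], quorum=quorum)
        for sub in subsamples
    ]
    return NetworkEnsemble(
        group=group, consensus_networks=nets, subsamples=subsamples, seed=seed
    )


def unanimity_characteristic(
    ensemble: NetworkEnsemble | Sequence[SignedWeightedDigraph],
) -> SignedWeightedDigraph:
    """Edges present in ALL consensus networks; majority sign, median weight."""
    nets = (
        ensemble.consensus_networks
        if isinstance(ensemble, NetworkEnsemble)
        else list(ensemble)
    )
    if not nets:
        raise ValueError("empty ensemble")
    check_same_nodes(*nets)
    names = nets[0].node_names
    n = len(names)
    stack = np.stack([g.A for g in nets])
    out = SignedWeightedDigraph.empty(names)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = stack[:, i, j]
            if np.any(w == 0.0):
                continue
            pos, neg = w[w > 0], w[w < 0]
            if pos.size == neg.size:
                logger.info(
                    "sign tie for unanimity edge %s->%s; dropped",
                    names[j], names[i],
                )
                continue
            out.A[i, j] = (
                float(np.median(pos)) if pos.size > neg.size
                else float(np.median(neg))
            )
    if out.n_edges() == 0:
        logger.warning("unanimity network is empty")
    return out


def ensemble_concordance(
    levels: Mapping[str, Sequence[SignedWeightedDigraph]],
    reference: ReferenceNetwork | SignedWeightedDigraph,
) -> dict[str, dict]:
    """Recall/PPV distributions against a reference, per consensus level.

    ``levels`` maps a level label (e.g. ``subject``, ``consensus``,
    ``characteristic``) to the networks at that level.  Returns per level
    the recall/PPV lists, their medians, and the edge-count distribution.
    """
    out: dict[str, dict] = {}
    for label, nets in levels.items():
        recalls, ppvs, counts = [], [], []
        for g in nets:
            r, p, _ = edge_fscore(g, reference)
            recalls.append(r)
            ppvs.append(p)
            counts.append(g.n_edges())
        out[label] = {
            "recall": recalls,
            "ppv": ppvs,
            "edge_counts": counts,
            "median_recall": float(np.median(recalls)) if recalls else np.nan,
            "median_ppv": float(np.median(ppvs)) if ppvs else np.nan,
            "median_edges": float(np.median(counts)) if counts else np.nan,
        }
    return out


# ---------------------------------------------------------------------------
# In-paper arithmetic helpers

def partition_sizes(
    shared: int, unique_a: int, unique_b: int
) -> tuple[int, int, int]:
    """Characteristic-motif sizes and total from a shared/unique partition.

    Returns ``(size_a, size_b, total)`` = (shared + unique_a,
    shared + unique_b, shared + unique_a + unique_b).
    """
    return shared + unique_a, shared + unique_b, shared + unique_a + unique_b


def connection_density(
    n_edges: int, n_nodes: int, include_self_loops: bool = False
) -> float:
    """Fraction of possible directed edges realised (self-loops excluded
    by default, matching reference-network conventions)."""
    possible = n_nodes * n_nodes if include_self_loops else n_nodes * (
        n_nodes - 1
    )
    return n_edges / possible
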