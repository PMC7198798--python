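"""Topological comparison and characterisation of signed weighted digraphs.

* Weighted graph edit distance: the elementwise sum of absolute edge-weight
  differences between two adjacency matrices — the cost of the edit
  operations transforming one network into the other.  The normalised
  default rescales each network by its largest off-diagonal magnitude and
  divides by the number of ordered node pairs, so values are comparable
  across ensembles; the raw mode is the literal sum.
* Centralities: weighted in/out degree, betweenness (normalised), harmonic
  in/out closeness (unnormalised) with edge length 1/|weight|, and HITS
  hub/authority scores by L1-normalised power iteration.
* Motifs: feedforward loops classified coherent/incoherent type 1-4 by the
  Mangan–Alon sign convention, and short feedback loops signed by the
  product of member edge signs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import SignedWeightedDigraph, check_same_nodes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Graph edit distance

def graph_edit_distance(
    a: SignedWeightedDigraph | np.ndarray,
    b: SignedWeightedDigraph | np.ndarray,
    normalize: bool = True,
    include_diagonal: bool = False,
) -> float:
    """Sum of |a_ij - b_ij| over (off-diagonal) adjacency entries.

    With ``normalize`` each matrix is first scaled by its own max
    off-diagonal magnitude and the sum divided by N(N-1), bounding the
    result by 2.
    """
    A = a.A if isinstance(a, SignedWeightedDigraph) else np.asarray(a, float)
    B = b.A if isinstance(b, SignedWeightedDigraph) else np.asarray(b, float)
    if (
        isinstance(a, SignedWeightedDigraph)
        and isinstance(b, SignedWeightedDigraph)
    ):
        check_same_nodes(a, b)
    if A.shape != B.shape:
        raise ValueError("adjacency dimension mismatch")
    A = A.copy()
    B = B.copy()
    if not include_diagonal:
        np.fill_diagonal(A, 0.0)
        np.fill_diagonal(B, 0.0)
    if normalize:
        n = A.shape[0]
        ma = np.abs(A).max()
        mb = np.abs(B).max()
        if ma > 0:
            A = A / ma
        if mb > 0:
            B = B / mb
        return float(np.abs(A - B).sum() / (n * (n - 1)))
    return float(np.abs(A - B).sum())


def ged_significance(
    ensemble1: Sequence[SignedWeightedDigraph],
    ensemble2: Sequence[SignedWeightedDigraph],
    n_draws: int | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> dict:
    """Intra/inter GED distributions and two-sample tests.

    Computes pairwise GEDs within each ensemble and across them (randomly
    subsampled to ``n_draws`` pairs per distribution when set), then tests
    inter vs pooled-intra and intra1 vs intra2 with the two-sample t test
    and the Wilcoxon rank-sum test.
    """
    if len(ensemble1) < 2 or len(ensemble2) < 2:
        raise ValueError("intra distances need >= 2 networks per ensemble")
    rng = np.random.default_rng(seed)

    def sample_pairs(pairs: list) -> list:
        if n_draws is not None and len(pairs) > n_draws:
            idx = rng.choice(len(pairs), size=n_draws, replace=False)
            return [pairs[i] for i in np.sort(idx)]
        return pairs

    intra1 = [
        graph_edit_distance(ensemble1[i], ensemble1[j], normalize)
        for i, j in sample_pairs(
            list(itertools.combinations(range(len(ensemble1)), 2))
        )
    ]
    intra2 = [
        graph_edit_distance(ensemble2[i], ensemble2[j], normalize)
        for i, j in sample_pairs(
            list(itertools.combinations(range(len(ensemble2)), 2))
        )
    ]
    inter = [
        graph_edit_distance(ensemble1[i], ensemble2[j], normalize)
        for i, j in sample_pairs(
            list(
                itertools.product(
                    range(len(ensemble1)), range(len(ensemble2))
                )
            )
        )
    ]
    pooled = intra1 + intra2

    def tests(x, y):
        x, y = np.asarray(x), np.asarray(y)
        both = np.concatenate([x, y])
        if np.allclose(both, both[0]):
            return 1.0, 1.0
        return (
            float(stats.ttest_ind(x, y, equal_var=False).pvalue),
            float(stats.ranksums(x, y).pvalue),
        )

    t_inter, rs_inter = tests(inter, pooled)
    t_intra, rs_intra = tests(intra1, intra2)
    return {
        "intra1": intra1,
        "intra2": intra2,
        "pooled_intra": pooled,
        "inter": inter,
        "inter_mean": float(np.mean(inter)),
        "pooled_intra_mean": float(np.mean(pooled)),
        "t_p_inter_vs_intra": t_inter,
        "ranksum_p_inter_vs_intra": rs_inter,
        "t_p_intra1_vs_intra2": t_intra,
        "ranksum_p_intra1_vs_intra2": rs_intra,
        "direction": (
            "inter>intra"
            if np.mean(inter) >= np.mean(pooled)
            else "intra>inter"
        ),
    }


# ---------------------------------------------------------------------------
# Centralities

def hits_scores(
    g: SignedWeightedDigraph, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """HITS hub/authority scores on absolute weights.

    Power iteration with uniform start and L1 normalisation each step:
    authority(i) = sum over incoming sources j of |w_ji| * hub(j);
    hub(j) = sum over targets i of |w_ij| * authority(i).
    """
    B = np.abs(g.A.copy())
    np.fill_diagonal(B, 0.0)
    n = B.shape[0]
    if B.sum() == 0.0:
        logger.warning("graph has no edges; HITS scores are zero")
        return np.zeros(n), np.zeros(n)
    hub = np.full(n, 1.0 / n)
    auth = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new_auth = B @ hub
        new_auth /= new_auth.sum()
        new_hub = B.T @ new_auth
        new_hub /= new_hub.sum()
        if (
            np.abs(new_auth - auth).sum() < tol
            and np.abs(new_hub - hub).sum() < tol
        ):
            auth, hub = new_auth, new_hub
            break
        auth, hub = new_auth, new_hub
    return hub, auth


def node_centralities(g: SignedWeightedDigraph) -> pd.DataFrame:
    """Per-node centrality table.

    Weighted degrees sum absolute weights; shortest-path metrics use edge
    length 1/|weight| (signs ignored); betweenness is normalised by
    (N-1)(N-2); closeness is the unnormalised harmonic sum of inverse
    distances over reachable nodes, with in and out variants.
    """
    names = g.node_names
    absA = np.abs(g.A.copy())
    np.fill_diagonal(absA, 0.0)
    indeg = absA.sum(axis=1)          # row i: incoming weight to target i
    outdeg = absA.sum(axis=0)         # column j: outgoing weight of source j
    G = g.to_networkx()
    if G.number_of_edges():
        btw = nx.betweenness_centrality(G, weight="length", normalized=True)
        incl = nx.harmonic_centrality(G, distance="length")
        outcl = nx.harmonic_centrality(G.reverse(copy=True), distance="length")
    else:
        btw = {n: 0.0 for n in names}
        incl = {n: 0.0 for n in names}
        outcl = {n: 0.0 for n in names}
    hub, auth = hits_scores(g)
    return pd.DataFrame(
        {
            "indegree": indeg,
            "outdegree": outdeg,
            "betweenness": [btw[n] for n in names],
            "incloseness": [incl[n] for n in names],
            "outcloseness": [outcl[n] for n in names],
            "hub": hub,
            "authority": auth,
        },
        index=list(names),
    )


def centrality_medians(
    networks: Sequence[SignedWeightedDigraph],
) -> pd.DataFrame:
    """Per-node medians of each centrality across an ensemble."""
    tables = [node_centralities(g) for g in networks]
    stacked = pd.concat(tables, keys=range(len(tables)))
    return stacked.groupby(level=1, sort=False).median().loc[
        list(networks[0].node_names)
    ]


# ---------------------------------------------------------------------------
# Motifs

#: Mangan-Alon feedforward-loop types by the sign triple
#: (X->Y, Y->Z, X->Z).  C* are coherent (indirect sign product equals the
#: direct sign), I* incoherent.
FFL_TYPES: dict[tuple[int, int, int], str] = {
    (1, 1, 1): "C1",
    (-1, 1, -1): "C2",
    (1, -1, -1): "C3",
    (-1, -1, 1): "C4",
    (1, -1, 1): "I1",
    (-1, 1, 1): "I2",
    (1, 1, -1): "I3",
    (-1, -1, -1): "I4",
}


@dataclass(frozen=True)
class MotifRecord:
    kind: str                      # "ffl", "feedback_2cycle", "feedback_cycle"
    nodes: tuple[str, ...]         # FFL roles (X, Y, Z); cycle member order
    signs: tuple[int, ...]
    classification: str            # C1..C4 / I1..I4 for FFLs, else sign label


def classify_ffls(g: SignedWeightedDigraph) -> list[MotifRecord]:
    """All feedforward loops X->Y->Z with direct X->Z, typed by signs.

    Triples containing an ambiguous (zero-sign) edge are skipped.
    """
    names = g.node_names
    sign = np.sign(g.A)
    idx = range(len(names))
    out = []
    for x, y, z in itertools.permutations(idx, 3):
        s_xy = sign[y, x]
        s_yz = sign[z, y]
        s_xz = sign[z, x]
        if s_xy == 0 or s_yz == 0 or s_xz == 0:
            continue
        triple = (int(s_xy), int(s_yz), int(s_xz))
        out.append(
            MotifRecord(
                kind="ffl",
                nodes=(names[x], names[y], names[z]),
                signs=triple,
                classification=FFL_TYPES[triple],
            )
        )
    return out


def find_feedback_loops(
    g: SignedWeightedDigraph, max_len: int = 3
) -> list[MotifRecord]:
    """Simple cycles up to ``max_len``, labelled by their sign product."""
    G = g.to_networkx()
    idx = g.index
    out = []
    for cycle in nx.simple_cycles(G, length_bound=max_len):
        if len(cycle) < 2:
            continue  # self-loops are not circuit feedback
        signs = []
        for u, v in zip(cycle, cycle[1:] + cycle[:1]):
            signs.append(int(np.sign(g.A[idx[v], idx[u]])))
        product = int(np.prod(signs))
        out.append(
            MotifRecord(
                kind="feedback_2cycle" if len(cycle) == 2 else "feedback_cycle",
                nodes=tuple(cycle),
                signs=tuple(signs),
                classification="positive" if product > 0 else "negative",
            )
        )
    return out
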