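"""Aggregation of the 16 panel cytokines into 9 functional-set scores.

Cytokines are grouped by predominant cell of origin and mode of action:
monokine sets (MK*) from monocytes/dendritic cells and cytokine sets
(CK*) from lymphocytes.  Multi-cytokine sets are scored by principal
components of the pooled (both groups, all subjects, all recovery time
points) mean-centred log2 fold-change block, so both groups share one
coordinate system.  The four-cytokine MK1 block is scored as two
co-expression patterns, MK1A (PC1) and MK1B (PC2); a second component is
deemed necessary whenever PC1 captures less than ``second_pc_threshold``
(default 80 %) of the block variance.  Singleton sets bypass PCA and use
the centred log2 fold-change directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import AGGREGATE_NODES
from .panel import UniformSeries

logger = logging.getLogger(__name__)

#: Fixed functional-set membership.  MK1A and MK1B share the MK1 block.
SET_MEMBERS: dict[str, tuple[str, ...]] = {
    "MK1A": ("IL-1a", "IL-1b", "IL-8", "IL-12"),
    "MK1B": ("IL-1a", "IL-1b", "IL-8", "IL-12"),
    "MK2": ("IL-10",),
    "MK6": ("IL-6",),
    "MK15": ("IL-15",),
    "MK23": ("IL-23",),
    "CK1": ("IL-2", "IFNg", "TNFa", "TNFb"),
    "CK2": ("IL-4", "IL-5", "IL-13"),
    "CK17": ("IL-17",),
}

#: Blocks actually fitted by PCA (MK1 feeds both MK1A and MK1B).
PCA_BLOCKS: dict[str, tuple[str, ...]] = {
    "MK1": SET_MEMBERS["MK1A"],
    "CK1": SET_MEMBERS["CK1"],
    "CK2": SET_MEMBERS["CK2"],
}


def functional_set_map() -> dict[str, str]:
    """Cytokine -> functional-set name (MK1 constituents map to 'MK1')."""
    out: dict[str, str] = {}
    for set_name, members in SET_MEMBERS.items():
        key = "MK1" if set_name in ("MK1A", "MK1B") else set_name
        for cyt in members:
            out.setdefault(cyt, key)
    return out


@dataclass
class BlockModel:
    """Fitted principal components of one multi-cytokine block."""

    block: str
    cytokines: tuple[str, ...]
    means: np.ndarray                 # pooled log2 fold-change means
    loadings: np.ndarray              # components x cytokines
    variance_fractions: np.ndarray    # per component, non-increasing
    n_retained: int

    def scores(self, log2_block: np.ndarray) -> np.ndarray:
        """Project a cytokine x time log2 fold-change block onto the loadings."""
        centred = log2_block - self.means[:, None]
        return self.loadings @ centred


@dataclass
class AggregateModel:
    """Pooled-cohort aggregation model: PCA blocks + singleton centring."""

    blocks: dict[str, BlockModel]
    singleton_means: dict[str, float]
    second_pc_threshold: float

    def variance_table(self) -> list[dict]:
        rows = []
        for name, bm in self.blocks.items():
            for k in range(bm.loadings.shape[0]):
                rows.append(
                    {
                        "block": name,
                        "component": k + 1,
                        "variance_fraction": float(bm.variance_fractions[k]),
                        **{
                            cyt: float(bm.loadings[k, i])
                            for i, cyt in enumerate(bm.cytokines)
                        },
                    }
                )
        return rows


@dataclass
class AggregateTimeCourse:
    """Nine functional-set scores on the uniform recovery grid, one subject."""

    subject_id: str
    group: str
    node_names: tuple[str, ...]
    times: np.ndarray
    scores: np.ndarray  # node x time

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.node_names), self.times.size):
            raise ValueError("scores shape does not match nodes x times")


def _series_lookup(
    series: Sequence[UniformSeries],
) -> dict[str, dict[str, UniformSeries]]:
    """subject -> cytokine -> series; checks grid consistency per subject."""
    out: dict[str, dict[str, UniformSeries]] = {}
    for s in series:
        out.setdefault(s.subject_id, {})[s.cytokine] = s
    return out


def _common_times(per_cyt: Mapping[str, UniformSeries]) -> np.ndarray:
    grids = [s.times for s in per_cyt.values()]
    t = grids[0]
    for g in grids[1:]:
        if g.size != t.size or not np.allclose(g, t):
            raise ValueError("cytokine series of one subject disagree on grid")
    return t


def fit_pooled_pca(
    series: Sequence[UniformSeries],
    second_pc_threshold: float = 0.80,
) -> AggregateModel:
    """Fit the pooled-cohort aggregation model on fold-change series.

    Pools log2 fold-change values of every subject and time point, centres
    each cytokine, and extracts principal components per multi-cytokine
    block.  Components are sign-fixed so the largest-magnitude loading is
    positive.  The MK1 block always carries two scored patterns (MK1A,
    MK1B); other blocks retain PC2 only when PC1 explains less than the
    threshold (logged — the fixed nine-node universe scores them by PC1).
    """
    if any(s.units != "fold_change" for s in series):
        raise ValueError("aggregation expects fold-change series")
    lookup = _series_lookup(series)
    if len(lookup) < 2:
        raise ValueError("need at least 2 subjects to fit the pooled model")
    blocks: dict[str, BlockModel] = {}
    for block, members in PCA_BLOCKS.items():
        cols = []
        for subj, per_cyt in sorted(lookup.items()):
            missing = [c for c in members if c not in per_cyt]
            if missing:
                raise ValueError(f"subject {subj} misses cytokines {missing}")
            cols.append(
                np.vstack([np.log2(per_cyt[c].values) for c in members])
            )
        X = np.hstack(cols)                       # cytokines x samples
        means = X.mean(axis=1)
        Xc = X - means[:, None]
        total_var = float(np.sum(Xc * Xc))
        if total_var <= 1e-12:
            raise ValueError(f"block {block} has no variance")
        # principal axes of the cytokine covariance
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        fractions = (s**2) / (s**2).sum()
        loadings = U.T                            # components x cytokines
        # sign convention: largest-|loading| positive
        for k in range(loadings.shape[0]):
            imax = int(np.argmax(np.abs(loadings[k])))
            if loadings[k, imax] < 0:
                loadings[k] *= -1.0
        n_retained = 1 if fractions[0] >= second_pc_threshold else 2
        if block != "MK1" and n_retained == 2:
            logger.info(
                "block %s PC1 fraction %.3f < %.2f; PC2 would be retained "
                "but the fixed node universe scores it by PC1",
                block, fractions[0], second_pc_threshold,
            )
        keep = 2 if block == "MK1" else 1
        blocks[block] = BlockModel(
            block=block,
            cytokines=tuple(members),
            means=means,
            loadings=loadings[:keep],
            variance_fractions=fractions[:keep],
            n_retained=n_retained,
        )
    singleton_means: dict[str, float] = {}
    for set_name, members in SET_MEMBERS.items():
        if len(members) == 1 and set_name not in PCA_BLOCKS:
            cyt = members[0]
            vals = np.concatenate(
                [
                    np.log2(per_cyt[cyt].values)
                    for _, per_cyt in sorted(lookup.items())
                ]
            )
            singleton_means[cyt] = float(vals.mean())
    return AggregateModel(
        blocks=blocks,
        singleton_means=singleton_means,
        second_pc_threshold=second_pc_threshold,
    )


def score_aggregates(
    series: Sequence[UniformSeries],
    model: AggregateModel,
) -> list[AggregateTimeCourse]:
    """Score every subject's nine functional sets on the pooled model."""
    lookup = _series_lookup(series)
    out = []
    for subj, per_cyt in sorted(lookup.items()):
        times = _common_times(per_cyt)
        rows = []
        for node in AGGREGATE_NODES:
            members = SET_MEMBERS[node]
            if len(members) == 1:
                cyt = members[0]
                if cyt not in per_cyt:
                    raise ValueError(f"subject {subj} misses {cyt}")
                rows.append(
                    np.log2(per_cyt[cyt].values)
                    - model.singleton_means[cyt]
                )
            else:
                block = "MK1" if node in ("MK1A", "MK1B") else node
                bm = model.blocks[block]
                missing = [c for c in bm.cytokines if c not in per_cyt]
                if missing:
                    raise ValueError(
                        f"subject {subj} misses cytokines {missing}"
                    )
                log2_block = np.vstack(
                    [np.log2(per_cyt[c].values) for c in bm.cytokines]
                )
                comp = 1 if node == "MK1B" else 0
                rows.append(bm.scores(log2_block)[comp])
        group = next(iter(per_cyt.values())).group
        out.append(
            AggregateTimeCourse(
                subject_id=subj,
                group=group,
                node_names=AGGREGATE_NODES,
                times=times,
                scores=np.vstack(rows),
            )
        )
    return out
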