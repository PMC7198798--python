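"""Per-cytokine divergence of recovery trajectories between subjects.

Trajectory separation is measured by a semi-metric on time series of
possibly unequal length, then compared within and between subject groups
by a leave-one/two-out subsampling scheme: per repeat, 11 random subsets
of 10 subjects are drawn without replacement from each group; all
intra-group and cross-group pairwise distances inside each paired subset
are accumulated, and the resulting inter vs pooled-intra distributions are
tested with the two-sample t test and the Wilcoxon rank-sum test.

The default distance is an amplitude–shape semi-metric: both curves are
linearly re-interpolated on the union of their time grids, and the mean
absolute gap is scaled by itself plus the mean of the two curve ranges,
giving a value in [0, 1] with d(x, x) = 0 and symmetry (triangle
inequality is not promised).  A dynamic-time-warping variant is provided
for shape-insensitive comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .panel import UniformSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distances

def _union_grid_curves(x: UniformSeries, y: UniformSeries):
    tx, ty = x.times, y.times
    lo = max(tx[0], ty[0])
    hi = min(tx[-1], ty[-1])
    if hi <= lo:  # disjoint supports: compare on each curve's own grid
        grid = np.union1d(tx, ty)
    else:
        grid = np.union1d(tx, ty)
        grid = grid[(grid >= lo) & (grid <= hi)]
    xv = np.interp(grid, tx, x.values)
    yv = np.interp(grid, ty, y.values)
    return xv, yv


def amplitude_shape_distance(x: UniformSeries, y: UniformSeries) -> float:
    """Semi-metric in [0, 1]: normalized mean gap between the two curves."""
    xv, yv = _union_grid_curves(x, y)
    gap = float(np.mean(np.abs(xv - yv)))
    if gap == 0.0:
        return 0.0
    mean_range = 0.5 * (float(np.ptp(xv)) + float(np.ptp(yv)))
    return gap / (gap + mean_range)


def dtw_distance(x: UniformSeries, y: UniformSeries) -> float:
    """Dynamic-time-warping distance, path-length normalized."""
    a, b = x.values, y.values
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = cost[i - 1, j - 1] + min(
                D[i - 1, j], D[i, j - 1], D[i - 1, j - 1]
            )
    return float(D[n, m] / (n + m))


DISTANCE_METHODS: dict[str, Callable[[UniformSeries, UniformSeries], float]] = {
    "smets": amplitude_shape_distance,
    "dtw_norm": dtw_distance,
}


def series_distance(
    x: UniformSeries, y: UniformSeries, method: str = "smets"
) -> float:
    """Distance between two trajectories; see module docstring for methods."""
    try:
        fn = DISTANCE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown distance method {method!r}; "
            f"available: {sorted(DISTANCE_METHODS)}"
        ) from None
    return fn(x, y)


# ---------------------------------------------------------------------------
# Resampled distributions

def _summary(vals: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(vals, dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "se": np.nan, "median": np.nan, "madm": np.nan}
    med = float(np.median(arr))
    return {
        "mean": float(arr.mean()),
        "se": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0,
        "median": med,
        "madm": float(np.median(np.abs(arr - med))),
    }


@dataclass
class DistanceDistributions:
    """Intra/inter distance samples for one cytokine, with summaries."""

    cytokine: str
    intra_group_1: list[float]
    intra_group_2: list[float]
    inter: list[float]
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def pooled_intra(self) -> list[float]:
        return self.intra_group_1 + self.intra_group_2

    def __post_init__(self) -> None:
        self.summaries = {
            "intra_group_1": _summary(self.intra_group_1),
            "intra_group_2": _summary(self.intra_group_2),
            "pooled_intra": _summary(self.pooled_intra),
            "inter": _summary(self.inter),
        }


def _by_cytokine(series: Sequence[UniformSeries]) -> dict[str, list[UniformSeries]]:
    out: dict[str, list[UniformSeries]] = {}
    for s in series:
        out.setdefault(s.cytokine, []).append(s)
    return out


def resampled_distance_distributions(
    group1: Sequence[UniformSeries],
    group2: Sequence[UniformSeries],
    subset_size: int = 10,
    n_subsets: int = 11,
    n_repeats: int = 11,
    seed: int = 0,
    method: str = "smets",
) -> dict[str, DistanceDistributions]:
    """Leave-one/two-out subsampled distance distributions per cytokine.

    Per repeat and per cytokine, ``n_subsets`` subsets of ``subset_size``
    subjects are drawn without replacement from each group; all within- and
    cross-subset pairwise distances are accumulated.  Pairwise distances
    between fixed subjects are computed once and re-used across subsets.
    """
    rng = np.random.default_rng(seed)
    g1 = _by_cytokine(group1)
    g2 = _by_cytokine(group2)
    if set(g1) != set(g2):
        raise ValueError("the two groups cover different cytokines")
    out: dict[str, DistanceDistributions] = {}
    for cyt in sorted(g1):
        s1 = sorted(g1[cyt], key=lambda s: s.subject_id)
        s2 = sorted(g2[cyt], key=lambda s: s.subject_id)
        n1, n2 = len(s1), len(s2)
        if subset_size > n1 or subset_size > n2:
            raise ValueError(
                f"subset_size {subset_size} exceeds a group size ({n1}, {n2})"
            )
        # distance caches over the full groups
        d11 = {
            (i, j): series_distance(s1[i], s1[j], method)
            for i, j in itertools.combinations(range(n1), 2)
        }
        d22 = {
            (i, j): series_distance(s2[i], s2[j], method)
            for i, j in itertools.combinations(range(n2), 2)
        }
        d12 = {
            (i, j): series_distance(s1[i], s2[j], method)
            for i in range(n1)
            for j in range(n2)
        }
        intra1: list[float] = []
        intra2: list[float] = []
        inter: list[float] = []
        for _ in range(n_repeats):
            for _ in range(n_subsets):
                sub1 = np.sort(rng.choice(n1, size=subset_size, replace=False))
                sub2 = np.sort(rng.choice(n2, size=subset_size, replace=False))
                intra1.extend(
                    d11[(i, j)] for i, j in itertools.combinations(sub1, 2)
                )
                intra2.extend(
                    d22[(i, j)] for i, j in itertools.combinations(sub2, 2)
                )
                inter.extend(d12[(i, j)] for i in sub1 for j in sub2)
        out[cyt] = DistanceDistributions(
            cytokine=cyt, intra_group_1=intra1, intra_group_2=intra2,
            inter=inter,
        )
    return out


def test_group_separation(
    dist: DistanceDistributions,
) -> tuple[float, float, str]:
    """Two-sample tests of inter vs pooled-intra distances.

    Returns ``(t_p, ranksum_p, direction)`` where direction is
    ``"inter>intra"`` or ``"intra>inter"`` by the means.  Degenerate
    (zero-variance or singleton) inputs report p = 1 with a warning.
    """
    inter = np.asarray(dist.inter, dtype=float)
    intra = np.asarray(dist.pooled_intra, dtype=float)
    if inter.size == 0 or intra.size == 0:
        raise ValueError("empty distance distributions")
    direction = "inter>intra" if inter.mean() >= intra.mean() else "intra>inter"
    pooled = np.concatenate([inter, intra])
    if (
        inter.size < 2
        or intra.size < 2
        or np.allclose(pooled, pooled[0])
    ):
        logger.warning(
            "degenerate distance distributions for %s; p set to 1",
            dist.cytokine,
        )
        return 1.0, 1.0, direction
    t_p = float(stats.ttest_ind(inter, intra, equal_var=False).pvalue)
    ranksum_p = float(stats.ranksums(inter, intra).pvalue)
    return t_p, ranksum_p, direction


def divergence_table(
    dists: dict[str, DistanceDistributions],
) -> "pd.DataFrame":
    """Per-cytokine summary table (means, SEs, medians, MADMs, p-values)."""
    import pandas as pd

    rows = []
    for cyt in sorted(dists):
        d = dists[cyt]
        t_p, ranksum_p, direction = test_group_separation(d)
        row = {"cytokine": cyt}
        for name, summ in d.summaries.items():
            for stat, val in summ.items():
                row[f"{name}_{stat}"] = val
        row.update(t_p=t_p, ranksum_p=ranksum_p, direction=direction)
        rows.append(row)
    return pd.DataFrame(rows)
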