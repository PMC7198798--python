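"""Synthetic two-group cytokine cohorts from known ground-truth networks.

Every downstream stage (aggregation, rate inference, consensus, topology
comparison, blockade search) is validated against cohorts generated here,
where the group-level signed influence matrices are known exactly.  The
generator mimics the study design: two groups (11 healthy controls, 12
ill subjects), 16 plasma cytokines, 8 draws anchored on peak exercise
effort, lognormal-scale concentrations with a detection floor.

The latent dynamics follow the linear rate model d(x - basal)/dt =
A (x - basal) on the nine aggregate functional-set nodes; cytokine
concentrations are multiplicative (log2-scale) read-outs of their set's
node state.  Subjects deviate from the group network by multiplicative
log-normal weight jitter and random edge dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .graph import AGGREGATE_NODES, SignedWeightedDigraph
from .panel import CYTOKINES, NOMINAL_MINUTES, TIMEPOINT_LABELS, CytokinePanel

#: Table-2 style mapping cytokine -> (aggregate node, loading weight).  The
#: MK1 block carries two latent co-expression patterns: IL-1a/IL-1b read
#: out the MK1A factor, IL-8/IL-12 the MK1B factor, so the panel's
#: two-component scoring of the block has a ground-truth counterpart.
DEFAULT_LOADING_MAP: dict[str, tuple[str, float]] = {
    "IL-1a": ("MK1A", 1.0),
    "IL-1b": ("MK1A", 0.8),
    "IL-8": ("MK1B", 1.0),
    "IL-12": ("MK1B", 0.7),
    "IL-10": ("MK2", 1.0),
    "IL-6": ("MK6", 1.0),
    "IL-15": ("MK15", 1.0),
    "IL-23": ("MK23", 1.0),
    "IL-2": ("CK1", 1.0),
    "IFNg": ("CK1", 0.9),
    "TNFa": ("CK1", 0.8),
    "TNFb": ("CK1", 0.7),
    "IL-4": ("CK2", 1.0),
    "IL-5": ("CK2", 0.9),
    "IL-13": ("CK2", 0.8),
    "IL-17": ("CK17", 1.0),
}

#: Reference pg/ml scales per cytokine (order-of-magnitude plasma levels).
DEFAULT_REF_CONC = {c: 10.0 for c in CYTOKINES}


def sample_group_network(
    n_nodes: int,
    density: float,
    positive_fraction: float = 0.6,
    weight_scale: float = 0.04,
    seed: int = 0,
    stability_margin: float = 0.01,
) -> np.ndarray:
    """Draw a random stable signed influence matrix.

    Off-diagonal entries are nonzero with probability ``density``; signs are
    Bernoulli(``positive_fraction``), magnitudes uniform in
    ``(0.2, 1] * weight_scale`` (per-minute units).  The diagonal is set
    negative and diagonally dominant so the spectral abscissa is < 0.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    A = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if rng.random() < density:
                sign = 1.0 if rng.random() < positive_fraction else -1.0
                mag = rng.uniform(0.2, 1.0) * weight_scale
                A[i, j] = sign * mag
    _stabilize_diagonal(A, margin=stability_margin)
    return A


def _stabilize_diagonal(A: np.ndarray, margin: float = 0.01) -> None:
    """Set diagonal so each Gershgorin disc sits left of -margin (in place)."""
    off = np.abs(A.copy())
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    np.fill_diagonal(A, -(row_sums + margin))


def perturb_subject_network(
    A_group: np.ndarray,
    jitter_sd: float,
    dropout_prob: float,
    seed: int,
    stability_margin: float = 0.01,
) -> np.ndarray:
    """Subject-level variant of a group network.

    Nonzero off-diagonal weights are multiplied by exp(N(0, jitter_sd))
    (sign-preserving) and independently zeroed with probability
    ``dropout_prob``; the diagonal is re-shifted to preserve stability.
    """
    rng = np.random.default_rng(seed)
    A = np.array(A_group, dtype=float, copy=True)
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j or A[i, j] == 0.0:
                continue
            if dropout_prob > 0 and rng.random() < dropout_prob:
                A[i, j] = 0.0
            elif jitter_sd > 0:
                A[i, j] *= np.exp(rng.normal(0.0, jitter_sd))
    if jitter_sd > 0 or dropout_prob > 0:
        _stabilize_diagonal(A, margin=stability_margin)
    return A


def simulate_trajectory(
    A: np.ndarray,
    x0: np.ndarray,
    basal: np.ndarray,
    times: np.ndarray,
    process_noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Integrate d(x - basal)/dt = A (x - basal) on a uniform grid.

    Euler–Maruyama with additive N(0, process_noise_sd * sqrt(dt)) state
    increments; with zero noise the matrix-exponential solution is used at
    each grid point (exact for the linear model), so the trajectory is free
    of integration error.

    Returns a node x time matrix.
    """
    times = np.asarray(times, dtype=float)
    steps = np.diff(times)
    if times.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("times must be a uniform grid with >= 2 points")
    dt = float(steps[0])
    x0 = np.asarray(x0, dtype=float)
    basal = np.asarray(basal, dtype=float)
    n = A.shape[0]
    out = np.empty((n, times.size))
    dev = x0 - basal
    out[:, 0] = x0
    if process_noise_sd == 0.0:
        step_op = expm(A * dt)
        for k in range(1, times.size):
            dev = step_op @ dev
            out[:, k] = basal + dev
        return out
    rng = np.random.default_rng(seed)
    # Euler–Maruyama with substeps so the drift is resolved at coarse grids
    n_sub = max(1, int(np.ceil(dt / 0.5)))
    h = dt / n_sub
    for k in range(1, times.size):
        for _ in range(n_sub):
            dev = dev + h * (A @ dev) + process_noise_sd * np.sqrt(h) * rng.normal(
                size=n
            )
        out[:, k] = basal + dev
    return out


@dataclass
class GroundTruthModel:
    """Generating model for one subject group."""

    A_true: np.ndarray
    node_names: tuple[str, ...] = AGGREGATE_NODES
    basal: float = 1.0
    x_peak_mean: float = 1.5
    x_peak_sd: float = 0.15
    process_noise_sd: float = 0.0
    loading_map: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOADING_MAP)
    )
    lod: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A_true = np.asarray(self.A_true, dtype=float)
        if self.A_true.shape != (len(self.node_names),) * 2:
            raise ValueError("A_true shape does not match node_names")
        if np.max(np.real(np.linalg.eigvals(self.A_true))) >= 0:
            raise ValueError("A_true must have spectral abscissa < 0")
        missing = set(CYTOKINES) - set(self.loading_map)
        if missing:
            raise ValueError(f"loading_map misses cytokines: {sorted(missing)}")

    def as_graph(self) -> SignedWeightedDigraph:
        return SignedWeightedDigraph(self.node_names, self.A_true)


@dataclass
class SyntheticCohortSpec:
    """Study-scale cohort description: group sizes, models, noise levels."""

    models: Mapping[str, GroundTruthModel]
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 11, "GWI": 12}
    )
    subject_weight_jitter_sd: float = 0.2
    edge_dropout_prob: float = 0.1
    measurement_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.models) != set(self.n_per_group):
            raise ValueError("models and n_per_group must share group labels")
        if not 0 <= self.edge_dropout_prob <= 1:
            raise ValueError("edge_dropout_prob must lie in [0, 1]")
        for g, n in self.n_per_group.items():
            if n < 3:
                raise ValueError(f"group {g} needs >= 3 subjects")


def default_cohort_spec(
    seed: int = 0,
    distinct_groups: bool = True,
    density: float = 0.3,
    measurement_cv: float = 0.1,
    jitter_sd: float = 0.2,
    dropout_prob: float = 0.1,
    process_noise_sd: float = 0.0,
) -> SyntheticCohortSpec:
    """Study-condition cohort: 11 HC + 12 GWI, 9-node networks at density 0.3.

    With ``distinct_groups`` the two groups get independently drawn
    ground-truth networks (the illness-remodelling scenario); otherwise both
    share one network (the null scenario).
    """
    n = len(AGGREGATE_NODES)
    A_hc = sample_group_network(n, density=density, seed=seed * 2 + 1)
    A_gwi = (
        sample_group_network(n, density=density, seed=seed * 2 + 2)
        if distinct_groups
        else A_hc.copy()
    )
    models = {
        "HC": GroundTruthModel(A_hc, process_noise_sd=process_noise_sd),
        "GWI": GroundTruthModel(A_gwi, process_noise_sd=process_noise_sd),
    }
    return SyntheticCohortSpec(
        models=models,
        subject_weight_jitter_sd=jitter_sd,
        edge_dropout_prob=dropout_prob,
        measurement_cv=measurement_cv,
        seed=seed,
    )


def emit_score_cohort(
    spec: SyntheticCohortSpec,
    step_minutes: float = 3.0,
    window: tuple[float, float] = (0.0, 240.0),
):
    """Densely sampled aggregate score trajectories plus ground truth.

    Bypasses the cytokine read-out: each subject's node-state deviations
    from basal are returned directly on the uniform recovery grid as
    :class:`~immunet.aggregates.AggregateTimeCourse` objects (the noiseless
    limit of the panel chain, which is affine in the node states).
    ``spec.measurement_cv`` is applied as additive log-scale Gaussian
    measurement error on the scores, the score-level equivalent of
    multiplicative concentration noise.

    Returns ``(score_courses, truth)``.
    """
    from .aggregates import AggregateTimeCourse

    rng = np.random.default_rng(spec.seed)
    times = np.arange(window[0], window[1] + step_minutes / 2, step_minutes)
    node_names = next(iter(spec.models.values())).node_names
    courses = []
    subject_matrices: dict[str, np.ndarray] = {}
    subject_states: dict[str, np.ndarray] = {}
    for group in sorted(spec.models):
        model = spec.models[group]
        basal = np.full(len(node_names), model.basal)
        for k in range(spec.n_per_group[group]):
            sid = f"{group}{k + 1:02d}"
            A_subj = perturb_subject_network(
                model.A_true,
                spec.subject_weight_jitter_sd,
                spec.edge_dropout_prob,
                seed=int(rng.integers(2**31)),
            )
            x_peak = basal + rng.normal(
                model.x_peak_mean - model.basal, model.x_peak_sd,
                size=len(node_names),
            )
            traj = simulate_trajectory(
                A_subj, x_peak, basal, times,
                process_noise_sd=model.process_noise_sd,
                seed=int(rng.integers(2**31)),
            )
            scores = traj - basal[:, None]
            if spec.measurement_cv > 0:
                scores = scores + rng.normal(
                    0, spec.measurement_cv, size=scores.shape
                )
            subject_matrices[sid] = A_subj
            subject_states[sid] = traj
            courses.append(
                AggregateTimeCourse(
                    subject_id=sid, group=group, node_names=node_names,
                    times=times, scores=scores,
                )
            )
    truth = CohortTruth(
        group_matrices={g: m.A_true.copy() for g, m in spec.models.items()},
        subject_matrices=subject_matrices,
        subject_states=subject_states,
        node_names=node_names,
        times=times,
    )
    return courses, truth


@dataclass
class CohortTruth:
    """Ground truth stored alongside an emitted panel."""

    group_matrices: dict[str, np.ndarray]
    subject_matrices: dict[str, np.ndarray]
    subject_states: dict[str, np.ndarray]
    node_names: tuple[str, ...]
    times: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "node_names": list(self.node_names),
            "times": self.times.tolist(),
            "group_matrices": {
                g: m.tolist() for g, m in self.group_matrices.items()
            },
            "subject_matrices": {
                s: m.tolist() for s, m in self.subject_matrices.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def emit_cohort(
    spec: SyntheticCohortSpec,
    sample_time_jitter_sd: float = 1.0,
) -> tuple[CytokinePanel, CohortTruth]:
    """Generate a pg/ml panel plus its ground truth.

    Per subject: perturb the group network, draw an elevated peak-effort
    state, integrate node deviations over [-12, 240] min on a 1-min grid,
    read out the 16 cytokines at the 8 nominal draw times (with per-subject
    timing jitter on the intermediate draws) as
    ``ref * 2**(loading * (x - basal)) * exp(N(0, cv))``, and censor
    readings below the detection floor to zero.
    """
    rng = np.random.default_rng(spec.seed)
    sim_times = np.arange(-12.0, 240.0 + 0.5, 1.0)
    records = []
    subject_matrices: dict[str, np.ndarray] = {}
    subject_states: dict[str, np.ndarray] = {}
    group_matrices = {g: m.A_true.copy() for g, m in spec.models.items()}
    node_names = next(iter(spec.models.values())).node_names
    node_index = {n: i for i, n in enumerate(node_names)}

    for group in sorted(spec.models):
        model = spec.models[group]
        basal = np.full(len(node_names), model.basal)
        for k in range(spec.n_per_group[group]):
            sid = f"{group}{k + 1:02d}"
            A_subj = perturb_subject_network(
                model.A_true,
                spec.subject_weight_jitter_sd,
                spec.edge_dropout_prob,
                seed=int(rng.integers(2**31)),
            )
            x_peak = basal + rng.normal(
                model.x_peak_mean - model.basal, model.x_peak_sd,
                size=len(node_names),
            )
            traj = simulate_trajectory(
                A_subj, x_peak, basal, sim_times,
                process_noise_sd=model.process_noise_sd,
                seed=int(rng.integers(2**31)),
            )
            subject_matrices[sid] = A_subj
            subject_states[sid] = traj
            # draw times: endpoints fixed, interior draws jittered per
            # subject; enforce a strictly increasing draw schedule
            prev_minutes = -np.inf
            for label in TIMEPOINT_LABELS:
                nominal = NOMINAL_MINUTES[label]
                minutes = nominal
                if label not in ("T0", "T2") and sample_time_jitter_sd > 0:
                    minutes = float(
                        np.clip(
                            nominal + rng.normal(0, sample_time_jitter_sd),
                            sim_times[0], sim_times[-1] - 0.5,
                        )
                    )
                minutes = max(minutes, prev_minutes + 0.5)
                prev_minutes = minutes
                for cyt in CYTOKINES:
                    node, loading = model.loading_map[cyt]
                    state = np.interp(
                        minutes, sim_times, traj[node_index[node]]
                    )
                    conc = DEFAULT_REF_CONC[cyt] * 2.0 ** (
                        loading * (state - model.basal)
                    )
                    if spec.measurement_cv > 0:
                        conc *= np.exp(rng.normal(0, spec.measurement_cv))
                    if conc < model.lod.get(cyt, 0.0):
                        conc = 0.0
                    records.append(
                        (sid, group, cyt, label, minutes, conc)
                    )

    df = pd.DataFrame(
        records,
        columns=[
            "subject_id", "group", "cytokine", "timepoint_label",
            "minutes_from_T1", "concentration",
        ],
    )
    panel = CytokinePanel(df, units="pg_ml")
    truth = CohortTruth(
        group_matrices=group_matrices,
        subject_matrices=subject_matrices,
        subject_states=subject_states,
        node_names=node_names,
        times=sim_times,
    )
    return panel, truth
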