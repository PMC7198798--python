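"""Qualitative discrete-state simulation of circuit response.

A fuzzy-logic engine in the spirit of discrete-state network simulators:
node states live in [0, 1]; the target state of a node is resolved from
its regulators by fuzzy OR (max) over activator contributions and fuzzy
AND-NOT against the strongest inhibitor contribution, contributions being
normalised |weight| times regulator state.  A logistic reshaping centred
at 0.5 sharpens the target, and each node relaxes toward it with its own
time constant: ``x <- x + (dt/tau) * (sigma(target) - x)``.  Per-run time
constants are sampled from a truncated-positive Gaussian, and ensembles of
runs for source (ill), target (healthy) and treated (blockade-edited)
circuits share the same sampled parameters for paired comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import SignedWeightedDigraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    steepness: float = 8.0
    time_constant_mean: float = 10.0
    time_constant_sd: float = 2.0
    dt: float = 1.0
    horizon: int = 100
    n_runs: int = 100
    basal: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.steepness, self.time_constant_mean, self.dt) <= 0:
            raise ValueError("steepness, time_constant_mean and dt must be > 0")
        if self.time_constant_sd < 0 or self.horizon < 0 or self.n_runs < 1:
            raise ValueError("invalid sd/horizon/n_runs")
        if not 0 <= self.basal <= 1:
            raise ValueError("basal must lie in [0, 1]")


def _sigmoid(u: np.ndarray | float, steepness: float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(u) - 0.5)))


def resolve_target_state(
    states: np.ndarray,
    g: SignedWeightedDigraph,
    node: str,
    basal: float,
) -> float:
    """Fuzzy-logic target state of one node given current states.

    Activation a = max over activators of (normalised |weight| x state);
    inhibition h likewise over inhibitors; target = basal when the node
    has no activators, else a * (1 - h).
    """
    i = g.index[node]
    w = g.A[i, :].copy()
    w[i] = 0.0
    scale = np.abs(g.A - np.diag(np.diag(g.A))).max()
    if scale == 0:
        return float(basal)
    contrib = np.abs(w) / scale * np.asarray(states, dtype=float)
    act = contrib[w > 0]
    inh = contrib[w < 0]
    if act.size == 0:
        return float(basal)
    a = float(act.max())
    h = float(inh.max()) if inh.size else 0.0
    return a * (1.0 - h)


def advance_state(
    states: np.ndarray,
    g: SignedWeightedDigraph,
    params: SimulationParams,
    tau: np.ndarray,
) -> np.ndarray:
    """One incremental update of all nodes toward their reshaped targets."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("time constants must be positive")
    targets = np.array(
        [
            resolve_target_state(states, g, node, params.basal)
            for node in g.node_names
        ]
    )
    shaped = _sigmoid(targets, params.steepness)
    new = states + (params.dt / tau) * (shaped - states)
    return np.clip(new, 0.0, 1.0)


@dataclass
class SimulationTrace:
    """Per-run state trajectories plus ensemble summaries."""

    scenario: str
    node_names: tuple[str, ...]
    runs: np.ndarray                 # n_runs x nodes x (horizon + 1)
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.runs.mean(axis=0)
        self.sd = self.runs.std(axis=0)


def sample_time_constants(
    params: SimulationParams, n_nodes: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-positive Gaussian time constants (rejection sampling)."""
    tau = rng.normal(
        params.time_constant_mean, params.time_constant_sd, size=n_nodes
    )
    floor = max(params.dt, 1e-6)
    while np.any(tau < floor):
        bad = tau < floor
        tau[bad] = rng.normal(
            params.time_constant_mean, params.time_constant_sd,
            size=int(bad.sum()),
        )
    return tau


def simulate_ensemble(
    g: SignedWeightedDigraph,
    x0: np.ndarray,
    params: SimulationParams,
    scenario: str = "source",
    tau_draws: np.ndarray | None = None,
) -> SimulationTrace:
    """Ensemble of trajectories with per-run time-constant draws.

    Pass ``tau_draws`` (n_runs x nodes) to share sampled parameters across
    scenarios for paired comparison; otherwise they are drawn from the
    params seed.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("initial states must lie in [0, 1]")
    n = g.n_nodes
    if tau_draws is None:
        rng = np.random.default_rng(params.seed)
        tau_draws = np.stack(
            [sample_time_constants(params, n, rng) for _ in range(params.n_runs)]
        )
    runs = np.empty((params.n_runs, n, params.horizon + 1))
    for r in range(params.n_runs):
        x = x0.copy()
        runs[r, :, 0] = x
        for step in range(1, params.horizon + 1):
            x = advance_state(x, g, params, tau_draws[r])
            runs[r, :, step] = x
    return SimulationTrace(scenario=scenario, node_names=g.node_names, runs=runs)


def rescue_score(
    source_trace: SimulationTrace,
    target_trace: SimulationTrace,
    treated_trace: SimulationTrace,
    eps: float = 1e-9,
) -> dict[str, float]:
    """Per-node rescue: 1 - RMS(treated - target) / RMS(source - target).

    1 = perfect rescue (treated matches the target circuit's output),
    0 = no change from the source circuit, negative = worsening.  RMS is
    taken over the ensemble-mean trajectories; a near-zero denominator
    (source already matches target) reports 0 with a warning.
    """
    if not (
        source_trace.mean.shape
        == target_trace.mean.shape
        == treated_trace.mean.shape
    ):
        raise ValueError("trace shapes differ")
    out = {}
    for i, node in enumerate(source_trace.node_names):
        denom = float(
            np.sqrt(np.mean((source_trace.mean[i] - target_trace.mean[i]) ** 2))
        )
        num = float(
            np.sqrt(np.mean((treated_trace.mean[i] - target_trace.mean[i]) ** 2))
        )
        if denom < eps:
            logger.warning(
                "node %s: source already matches target; rescue set to 0", node
            )
            out[node] = 0.0
        else:
            out[node] = 1.0 - num / denom
    return out


def blockade_rescue_experiment(
    source: SignedWeightedDigraph,
    target: SignedWeightedDigraph,
    treated: SignedWeightedDigraph,
    x0: np.ndarray,
    params: SimulationParams,
) -> tuple[dict[str, SimulationTrace], dict[str, float]]:
    """Run the three scenario circuits under shared sampled parameters."""
    rng = np.random.default_rng(params.seed)
    tau_draws = np.stack(
        [
            sample_time_constants(params, source.n_nodes, rng)
            for _ in range(params.n_runs)
        ]
    )
    traces = {
        "source": simulate_ensemble(source, x0, params, "source", tau_draws),
        "target": simulate_ensemble(target, x0, params, "target", tau_draws),
        "treated": simulate_ensemble(treated, x0, params, "treated", tau_draws),
    }
    scores = rescue_score(traces["source"], traces["target"], traces["treated"])
    return traces, scores
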