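"""Per-subject inference of signed directed networks from score trajectories.

The recovery trajectory of the nine aggregate cytokine sets is modelled by
the linear rate equation dx/dt = A x, where ``A[i, j]`` is the signed
influence of set ``j`` on the rate of change of set ``i``.  A is estimated
per subject by partial-least-squares regression of the finite-difference
rates on the scores, with the number of latent components retained by the
broken-stick rule (a variant of Horn's parallel analysis): component k is
kept while its explained-variance fraction exceeds ``lambda * b_k`` with
``b_k = (1/p) * sum_{i=k..p} 1/i`` the expected fraction of the k-th
largest piece of a randomly broken unit stick.  Dense coefficient matrices
are pruned to discrete signed edges at a fraction ``theta`` of the largest
off-diagonal magnitude, and (lambda, theta) are calibrated against a
reference network by constrained simulated annealing maximising the mean
edge F-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .aggregates import AggregateTimeCourse
from .graph import SignedWeightedDigraph, check_same_nodes
from .knowledge import ReferenceNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable knobs of the per-subject network fit."""

    broken_stick_scale: float = 1.0   # lambda; smaller keeps more components
    prune_threshold: float = 0.1      # theta, fraction of max |off-diagonal|
    derivative_scheme: str = "central"
    standardize_predictors: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.broken_stick_scale) or self.broken_stick_scale <= 0:
            raise ValueError("broken_stick_scale must be positive and finite")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune_threshold must lie in [0, 1)")
        if self.derivative_scheme != "central":
            raise ValueError("only the central derivative scheme is provided")


# ---------------------------------------------------------------------------
# Derivatives

def estimate_derivatives(scores: AggregateTimeCourse) -> np.ndarray:
    """Finite-difference rates on the uniform grid (node x time).

    Central differences at interior points, one-sided at the ends; exact
    for trajectories linear in time.
    """
    t = scores.times
    if t.size < 3:
        raise ValueError("need >= 3 time points for derivative estimation")
    step = float(t[1] - t[0])
    x = scores.scores
    rates = np.empty_like(x)
    rates[:, 1:-1] = (x[:, 2:] - x[:, :-2]) / (2 * step)
    rates[:, 0] = (x[:, 1] - x[:, 0]) / step
    rates[:, -1] = (x[:, -1] - x[:, -2]) / step
    return rates


# ---------------------------------------------------------------------------
# Broken-stick component retention

def broken_stick_thresholds(p: int) -> np.ndarray:
    """Expected length fractions of a unit stick broken into p pieces."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_select(
    variance_fractions: Sequence[float],
    scale: float = 1.0,
    p: int | None = None,
) -> int:
    """Number of leading components whose variance beats the broken stick.

    Returns the largest K such that ``fraction_k > scale * b_k`` for every
    k <= K, with a minimum of one component.
    """
    fractions = np.asarray(variance_fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty variance fractions")
    if p is None:
        p = fractions.size
    b = broken_stick_thresholds(p)[: fractions.size]
    K = 0
    for k in range(fractions.size):
        if fractions[k] > scale * b[k]:
            K += 1
        else:
            break
    return max(K, 1)


# ---------------------------------------------------------------------------
# PLS rate-matrix fit

def _pls_fit_path(
    X: np.ndarray, Y: np.ndarray, standardize: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    """PLS coefficient matrices for every component count 1..p.

    Returns ``(coefs, x_variance_fractions)`` where ``coefs[K-1]`` maps raw
    scores to rates (targets x sources) using K latent components, and the
    fractions are the predictor variance explained by each successive
    component of the full fit.
    """
    p = X.shape[1]
    max_comp = min(p, X.shape[0] - 1, np.linalg.matrix_rank(X - X.mean(0)))
    max_comp = max(max_comp, 1)
    full = PLSRegression(n_components=max_comp, scale=standardize)
    full.fit(X, Y)
    # predictor variance captured by each latent component (on the
    # centred/scaled predictor block the components were extracted from)
    Xcs = X - X.mean(axis=0)
    if standardize:
        std = X.std(axis=0, ddof=1)
        std[std == 0.0] = 1.0
        Xcs = Xcs / std
    total = float(np.sum(Xcs**2))
    expl = np.array(
        [
            float(
                np.sum(
                    np.outer(full.x_scores_[:, k], full.x_loadings_[:, k]) ** 2
                )
            )
            for k in range(max_comp)
        ]
    )
    fractions = expl / total if total > 0 else expl
    coefs = []
    for K in range(1, max_comp + 1):
        model = PLSRegression(n_components=K, scale=standardize)
        model.fit(X, Y)
        coefs.append(np.asarray(model.coef_))
    return coefs, fractions


def fit_rate_matrix(
    scores: AggregateTimeCourse,
    rates: np.ndarray | None = None,
    config: InferenceConfig = InferenceConfig(),
) -> SignedWeightedDigraph:
    """Dense signed influence matrix A for one subject (Eq.-1 orientation).

    Regresses all rate rows jointly on all score rows by PLS; the latent
    dimension is chosen by the broken-stick rule on the predictor variance
    fractions; coefficients are back-transformed to the original scale.
    """
    if rates is None:
        rates = estimate_derivatives(scores)
    X = scores.scores.T              # samples x sources
    Y = np.asarray(rates).T          # samples x targets
    if Y.shape != X.shape:
        raise ValueError("scores and rates must share the node x time grid")
    # endpoint rates are only first-order accurate and sit at high-leverage
    # extremes of the trajectory; the regression uses interior samples
    if X.shape[0] > 4:
        X, Y = X[1:-1], Y[1:-1]
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate scores: zero variance in all predictors")
    coefs, fractions = _pls_fit_path(X, Y, config.standardize_predictors)
    K = broken_stick_select(
        fractions, scale=config.broken_stick_scale, p=X.shape[1]
    )
    K = min(K, len(coefs))
    A = coefs[K - 1]
    if A.shape[0] != A.shape[1]:
        raise ValueError("rate fit expects as many targets as sources")
    return SignedWeightedDigraph(scores.node_names, A)


def prune_to_network(
    A_dense: SignedWeightedDigraph | np.ndarray,
    theta: float,
    node_names: Sequence[str] | None = None,
) -> SignedWeightedDigraph:
    """Zero off-diagonal entries below ``theta * max |off-diagonal|``.

    The diagonal (self-degradation) is preserved as-is; edge signs are the
    signs of the surviving coefficients.
    """
    if not 0 <= theta < 1:
        raise ValueError("theta must lie in [0, 1)")
    if isinstance(A_dense, SignedWeightedDigraph):
        names, A = A_dense.node_names, A_dense.A.copy()
    else:
        A = np.array(A_dense, dtype=float, copy=True)
        names = tuple(node_names) if node_names is not None else tuple(
            f"n{i}" for i in range(A.shape[0])
        )
    off = np.abs(A.copy())
    np.fill_diagonal(off, 0.0)
    m = off.max()
    if m == 0.0:
        logger.warning("all off-diagonal coefficients are zero; empty network")
        return SignedWeightedDigraph(names, A)
    diag = np.diag(A).copy()
    A[off < theta * m] = 0.0
    np.fill_diagonal(A, diag)
    return SignedWeightedDigraph(names, A)


def infer_subject_network(
    scores: AggregateTimeCourse,
    config: InferenceConfig = InferenceConfig(),
) -> SignedWeightedDigraph:
    """Full per-subject chain: derivatives -> PLS fit -> pruning."""
    dense = fit_rate_matrix(scores, config=config)
    return prune_to_network(dense, config.prune_threshold)


# ---------------------------------------------------------------------------
# Edge scoring against a reference

def edge_fscore(
    inferred: SignedWeightedDigraph,
    reference: SignedWeightedDigraph | ReferenceNetwork,
    sign_sensitive: bool = False,
) -> tuple[float, float, float]:
    """(recall, PPV, F) of inferred edges against a reference network.

    Matching is on (source, target) direction, optionally also sign; the
    diagonal is excluded.  An empty inferred network reports PPV 0.
    """
    if isinstance(reference, ReferenceNetwork):
        ref_nodes = reference.node_names
        ref_edges = reference.edge_set(signed=sign_sensitive)
    else:
        ref_nodes = reference.node_names
        ref_edges = reference.edge_set(signed=sign_sensitive)
    if set(inferred.node_names) != set(ref_nodes):
        raise ValueError("inferred and reference node sets differ")
    inf_edges = inferred.edge_set(signed=sign_sensitive)
    matches = len(inf_edges & ref_edges)
    recall = matches / len(ref_edges) if ref_edges else 0.0
    if not inf_edges:
        logger.warning("empty inferred network; PPV undefined, reported as 0")
        ppv = 0.0
    else:
        ppv = matches / len(inf_edges)
    f = 2 * recall * ppv / (recall + ppv) if (recall + ppv) > 0 else 0.0
    return recall, ppv, f


# ---------------------------------------------------------------------------
# Simulated-annealing calibration of (lambda, theta)

@dataclass(frozen=True)
class SAConfig:
    t0: float = 1.0
    cooling: float = 0.95
    iterations: int = 200


def calibrate_inference(
    training_scores: Sequence[AggregateTimeCourse],
    reference: ReferenceNetwork | SignedWeightedDigraph,
    lambda_bounds: tuple[float, float] = (1e-12, 4.0),
    theta_bounds: tuple[float, float] = (0.0, 0.5),
    sa_config: SAConfig = SAConfig(),
    seed: int = 0,
    base_config: InferenceConfig = InferenceConfig(),
) -> tuple[InferenceConfig, list[float]]:
    """Maximise mean edge F-score over (lambda, theta) by simulated annealing.

    The per-subject PLS fits are precomputed for every component count, so
    each objective evaluation only re-selects K and re-prunes — the search
    is cheap and deterministic given the seed.  Returns the best config and
    the accepted-objective trajectory.
    """
    if not training_scores:
        raise ValueError("need at least one training subject")
    if lambda_bounds[0] > lambda_bounds[1] or theta_bounds[0] > theta_bounds[1]:
        raise ValueError("empty bounds")
    fits = []
    for sc in training_scores:
        rates = estimate_derivatives(sc)
        X, Y = sc.scores.T, rates.T
        if X.shape[0] > 4:  # drop first-order endpoint samples, as in the fit
            X, Y = X[1:-1], Y[1:-1]
        coefs, fractions = _pls_fit_path(
            X, Y, base_config.standardize_predictors
        )
        fits.append((sc.node_names, coefs, fractions))

    def objective(lam: float, theta: float) -> float:
        fs = []
        for node_names, coefs, fractions in fits:
            K = min(
                broken_stick_select(fractions, scale=lam, p=len(node_names)),
                len(coefs),
            )
            net = prune_to_network(coefs[K - 1], theta, node_names)
            fs.append(edge_fscore(net, reference)[2])
        return float(np.mean(fs))

    rng = np.random.default_rng(seed)
    # coarse deterministic scan seeds the annealer away from flat plateaus
    lam_grid = np.exp(
        np.linspace(
            np.log(max(lambda_bounds[0], 1e-12)),
            np.log(max(lambda_bounds[1], 1e-12)),
            8,
        )
    )
    lam_grid = np.clip(lam_grid, *lambda_bounds)
    theta_grid = np.linspace(theta_bounds[0], theta_bounds[1], 8)
    lam, theta = lambda_bounds[0], theta_bounds[0]
    best_scan = -np.inf
    for lg in lam_grid:
        for tg in theta_grid:
            val = objective(float(lg), float(tg))
            if val > best_scan:
                best_scan, lam, theta = val, float(lg), float(tg)
    current = objective(lam, theta)
    best = (current, lam, theta)
    trajectory = [current]
    temp = sa_config.t0
    # lambda is a positive scale parameter: propose in log space
    log_span = float(np.log(lambda_bounds[1] / max(lambda_bounds[0], 1e-12)))
    theta_span = theta_bounds[1] - theta_bounds[0]
    for _ in range(sa_config.iterations):
        cand_lam = float(
            np.clip(
                lam * np.exp(rng.normal(0, 0.3 * max(log_span, 1e-12))),
                *lambda_bounds,
            )
        )
        cand_theta = float(
            np.clip(
                theta + rng.normal(0, 0.3 * max(theta_span, 1e-12)),
                *theta_bounds,
            )
        )
        val = objective(cand_lam, cand_theta)
        accept = val >= current or rng.random() < np.exp(
            (val - current) / max(temp, 1e-12)
        )
        if accept:
            lam, theta, current = cand_lam, cand_theta, val
            if val > best[0]:
                best = (val, lam, theta)
        trajectory.append(current)
        temp *= sa_config.cooling
    logger.info(
        "calibration: F=%.3f at lambda=%.3f theta=%.3f", *best
    )
    return (
        replace(
            base_config,
            broken_stick_scale=best[1],
            prune_threshold=best[2],
        ),
        trajectory,
    )
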