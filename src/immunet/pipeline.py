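"""Config-driven end-to-end orchestration of the analysis chain.

Stages, mirroring the study's methods order: cohort synthesis or panel
ingestion -> preprocessing -> per-cytokine divergence -> functional-set
aggregation -> per-subject rate inference (with optional calibration
against the reference network) -> two-level consensus -> topological
comparison (GED, centralities, motifs) -> blockade search -> qualitative
dynamics with rescue scoring.  All randomness flows from a single master
seed split into per-stage seeds via a stable counter scheme, so any stage
can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import consensus as cons
from . import divergence as div
from . import dynamics as dyn
from . import intervention as interv
from . import netmetrics as nm
from .aggregates import fit_pooled_pca, score_aggregates
from .graph import AGGREGATE_NODES, SignedWeightedDigraph
from .inference import (
    InferenceConfig,
    SAConfig,
    calibrate_inference,
    infer_subject_network,
)
from .knowledge import ReferenceNetwork, load_reference_network, read_edge_list
from .panel import CytokinePanel, preprocess, read_panel
from .synthetic import default_cohort_spec, emit_cohort

logger = logging.getLogger(__name__)

REPORT_SECTIONS = (
    "cohort", "divergence", "aggregation", "inference", "consensus",
    "comparison", "intervention", "dynamics",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; seed is mandatory."""

    seed: int
    panel_path: str | None = None          # None -> synthetic cohort
    reference_path: str | None = None      # None -> packaged reference
    exclude_subjects: tuple[str, ...] = ()
    step_minutes: float = 3.0
    # synthetic-cohort conditions
    distinct_groups: bool = True
    density: float = 0.3
    measurement_cv: float = 0.1
    jitter_sd: float = 0.2
    dropout_prob: float = 0.1
    # divergence resampling
    div_subset_size: int = 10
    div_n_subsets: int = 11
    div_n_repeats: int = 11
    # inference + calibration
    calibrate: bool = True
    sa_iterations: int = 60
    lambda_bounds: tuple[float, float] = (0.25, 4.0)
    theta_bounds: tuple[float, float] = (0.0, 0.5)
    # consensus
    subset_size: int = 10
    n_subsamples: int = 100
    quorum: int = 6
    # comparison / intervention / dynamics
    ged_normalize: bool = True
    max_combo: int = 2
    dyn_horizon: int = 100
    dyn_runs: int = 50
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must set a seed")
        kwargs = dict(d)
        for key in ("exclude_subjects",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("lambda_bounds", "theta_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        if cfg.panel_path and not Path(cfg.panel_path).exists():
            raise FileNotFoundError(cfg.panel_path)
        if cfg.reference_path and not Path(cfg.reference_path).exists():
            raise FileNotFoundError(cfg.reference_path)
        return cfg


def _load_reference(config: PipelineConfig) -> ReferenceNetwork:
    if config.reference_path:
        edges = read_edge_list(config.reference_path)
        return ReferenceNetwork(
            node_names=AGGREGATE_NODES,
            edges={(e.source, e.target): e for e in edges},
        )
    return load_reference_network()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report structure (JSON-serialisable)."""
    report: dict[str, Any] = {}
    stage = "start"
    try:
        # -- cohort --------------------------------------------------------
        stage = "cohort"
        if config.panel_path:
            panel = read_panel(config.panel_path)
            truth = None
        else:
            spec = default_cohort_spec(
                seed=stage_seed(config.seed, "cohort"),
                distinct_groups=config.distinct_groups,
                density=config.density,
                measurement_cv=config.measurement_cv,
                jitter_sd=config.jitter_sd,
                dropout_prob=config.dropout_prob,
            )
            panel, truth = emit_cohort(spec)
        groups = sorted(set(panel.data["group"]))
        for g in groups:
            if len(panel.subjects_in(g)) < config.subset_size:
                raise ValueError(
                    f"group {g} smaller than consensus subset_size "
                    f"{config.subset_size}"
                )
        report["cohort"] = {
            "n_subjects": {g: len(panel.subjects_in(g)) for g in groups},
            "n_records": int(len(panel.data)),
            "synthetic": config.panel_path is None,
        }

        # -- preprocessing + divergence -----------------------------------
        stage = "preprocess"
        series = preprocess(
            panel,
            step_minutes=config.step_minutes,
            exclude=config.exclude_subjects,
        )
        by_group = {
            g: [s for s in series if s.group == g] for g in groups
        }
        stage = "divergence"
        dists = div.resampled_distance_distributions(
            by_group[groups[0]],
            by_group[groups[1]],
            subset_size=config.div_subset_size,
            n_subsets=config.div_n_subsets,
            n_repeats=config.div_n_repeats,
            seed=stage_seed(config.seed, "divergence"),
        )
        div_table = div.divergence_table(dists)
        report["divergence"] = {
            "per_cytokine": div_table.to_dict(orient="records"),
            "n_significant_ranksum": int(
                (div_table["ranksum_p"] < 0.05).sum()
            ),
        }

        # -- aggregation ----------------------------------------------------
        stage = "aggregate"
        model = fit_pooled_pca(series)
        scores = score_aggregates(series, model)
        report["aggregation"] = {
            "variance_table": model.variance_table(),
            "n_subjects_scored": len(scores),
        }

        # -- inference ------------------------------------------------------
        stage = "infer"
        reference = _load_reference(config)
        inf_config = InferenceConfig()
        calibration: dict[str, Any] = {"calibrated": False}
        if config.calibrate:
            inf_config, trajectory = calibrate_inference(
                scores,
                reference,
                lambda_bounds=config.lambda_bounds,
                theta_bounds=config.theta_bounds,
                sa_config=SAConfig(iterations=config.sa_iterations),
                seed=stage_seed(config.seed, "calibrate"),
            )
            calibration = {
                "calibrated": True,
                "broken_stick_scale": inf_config.broken_stick_scale,
                "prune_threshold": inf_config.prune_threshold,
                "best_f": max(trajectory),
            }
        subject_nets = {
            sc.subject_id: infer_subject_network(sc, inf_config)
            for sc in scores
        }
        subject_groups = {sc.subject_id: sc.group for sc in scores}
        report["inference"] = {
            "calibration": calibration,
            "median_edges_per_subject": float(
                np.median([g.n_edges() for g in subject_nets.values()])
            ),
        }

        # -- consensus ------------------------------------------------------
        stage = "consensus"
        ensembles: dict[str, cons.NetworkEnsemble] = {}
        characteristic: dict[str, SignedWeightedDigraph] = {}
        concordance: dict[str, Any] = {}
        for g in groups:
            nets_g = {
                s: n for s, n in subject_nets.items()
                if subject_groups[s] == g
            }
            ens = cons.build_ensemble(
                nets_g,
                group=g,
                subset_size=config.subset_size,
                n_subsamples=config.n_subsamples,
                quorum=config.quorum,
                seed=stage_seed(config.seed, f"consensus-{g}"),
            )
            ensembles[g] = ens
            characteristic[g] = cons.unanimity_characteristic(ens)
            levels = {
                "subject": list(nets_g.values()),
                "consensus": ens.consensus_networks,
                "characteristic": [characteristic[g]],
            }
            conc = cons.ensemble_concordance(levels, reference)
            concordance[g] = {
                lvl: {
                    k: v
                    for k, v in stats.items()
                    if k.startswith("median")
                }
                for lvl, stats in conc.items()
            }
        report["consensus"] = {
            "concordance": concordance,
            "characteristic_edges": {
                g: sorted(
                    f"{s}->{t}:{int(np.sign(w))}"
                    for s, t, w in characteristic[g].edges()
                )
                for g in groups
            },
            "characteristic_density": {
                g: cons.connection_density(
                    characteristic[g].n_edges(), len(AGGREGATE_NODES)
                )
                for g in groups
            },
        }

        # -- comparison -----------------------------------------------------
        stage = "compare"
        g1, g2 = groups[0], groups[1]
        ged = nm.ged_significance(
            ensembles[g1].consensus_networks,
            ensembles[g2].consensus_networks,
            n_draws=2000,
            seed=stage_seed(config.seed, "ged"),
            normalize=config.ged_normalize,
        )
        motifs = {
            g: {
                "ffl": [
                    asdict(m) for m in nm.classify_ffls(characteristic[g])
                ],
                "feedback": [
                    asdict(m)
                    for m in nm.find_feedback_loops(characteristic[g])
                ],
            }
            for g in groups
        }
        report["comparison"] = {
            "ged": {
                k: v
                for k, v in ged.items()
                if not isinstance(v, list)
            },
            "centrality_medians": {
                g: nm.centrality_medians(
                    ensembles[g].consensus_networks
                ).to_dict(orient="index")
                for g in groups
            },
            "motifs": motifs,
        }

        # -- intervention ---------------------------------------------------
        stage = "intervene"
        # edit the more densely connected (second) group toward the first
        source_g, target_g = (g2, g1)
        results = interv.rank_blockades(
            ensembles[source_g].consensus_networks,
            ensembles[target_g].consensus_networks,
            max_combo=config.max_combo,
            normalize=config.ged_normalize,
        )
        report["intervention"] = {
            "source_group": source_g,
            "target_group": target_g,
            "ranked": [
                {
                    "blocked": list(r.blocked_nodes),
                    "ged_mean": r.ged_mean,
                    "ged_se": r.ged_se,
                    "rank": r.rank,
                    "reduction_pct": r.reduction_pct,
                }
                for r in results[:10]
            ],
        }

        # -- dynamics -------------------------------------------------------
        stage = "dynamics"
        best_blocked = next(
            (r for r in results if r.blocked_nodes), results[0]
        )
        src_net = characteristic[source_g]
        tgt_net = characteristic[target_g]
        treated = interv.apply_blockade(src_net, best_blocked.blocked_nodes)
        params = dyn.SimulationParams(
            horizon=config.dyn_horizon,
            n_runs=config.dyn_runs,
            seed=stage_seed(config.seed, "dynamics"),
        )
        x0 = np.full(len(AGGREGATE_NODES), 0.9)  # elevated peak-effort state
        _, rescue = dyn.blockade_rescue_experiment(
            src_net, tgt_net, treated, x0, params
        )
        report["dynamics"] = {
            "blocked": list(best_blocked.blocked_nodes),
            "rescue_scores": rescue,
        }
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
    return _round_floats(report, 6)


def _round_floats(obj: Any, sig: int) -> Any:
    """Round floats to ``sig`` significant digits for stable serialisation."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if x == 0 or not np.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def render_report(report: Mapping[str, Any], path, fmt: str = "json") -> str:
    """Serialise the report as JSON or a markdown summary."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    elif fmt == "markdown":
        lines = ["# Pipeline report", ""]
        for section in REPORT_SECTIONS:
            lines.append(f"## {section}")
            lines.append("")
            payload = report.get(section, {})
            lines.append("| key | value |")
            lines.append("| --- | --- |")
            for k, v in payload.items() if isinstance(payload, dict) else []:
                lines.append(f"| {k} | {json.dumps(v)[:400]} |")
            lines.append("")
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return str(path)
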