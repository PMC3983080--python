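"""In silico benchmark sweep and weight-map sensitivity analysis.

The sweep rotates the plant role over the three bank members: for each
plant, training data are generated from that plant, a weight map is trained
for the remaining two members, and every target in the case-study preset is
controlled by

* ``S_matched``     — single-model controller using the plant itself (the
  unrealizable best case),
* ``S_mismatched``  — each remaining member alone (two runs per scenario),
* ``M_eq``          — both members with fixed equal weights,
* ``M_aw``          — both members with adaptive Akaike weights.

Performance is the squared error between the controlled plant trajectory
and the target on a 1-min grid.  Summaries report mean +/- standard error
per controller class and the percent reduction of ``M_aw`` against each
comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controller import RunConfig, apply_to_plant, run_open_loop, run_single_model
from .model_bank import PredictionModel
from .mpc_objective import CASE_STUDY_TARGETS, target_trajectory
from .synthetic_training import generate_training_design, simulate_training_data
from .weight_maps import build_weight_map

__all__ = [
    "BenchmarkResult",
    "run_benchmark",
    "summarize_benchmark",
    "weight_map_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    plant_id: str
    target: tuple
    controller: str          # S_matched | S_mismatched | M_eq | M_aw
    controller_detail: str   # e.g. which single model
    sq_error: float
    doses: np.ndarray


def run_benchmark(
    bank: list[PredictionModel],
    targets=CASE_STUDY_TARGETS,
    cfg: RunConfig | None = None,
    seed: int = 1,
    noise_sd: float = 0.05,
    n_timepoints: int = 8,
    plants: list[int] | None = None,
) -> list[BenchmarkResult]:
    """Run the full controller comparison sweep.

    ``plants`` restricts the plant rotation to the given bank indices
    (default: all members).  Partial failures are recorded and skipped so
    one pathological scenario cannot abort the sweep.
    """
    cfg = cfg or RunConfig()
    results: list[BenchmarkResult] = []
    plant_indices = list(range(len(bank))) if plants is None else list(plants)

    for pi in plant_indices:
        plant = bank[pi].copy()
        others = [m for j, m in enumerate(bank) if j != pi]
        design = generate_training_design(cfg.space)
        dataset = simulate_training_data(
            plant, design, noise_sd=noise_sd, n_timepoints=n_timepoints,
            seed=seed + pi,
        )
        wmap = build_weight_map(others, dataset, cfg.space)

        for tgt in targets:
            target = target_trajectory(*tgt)
            runs = [("S_matched", plant.model_id,
                     lambda: run_single_model(plant, target, cfg))]
            for m in others:
                runs.append(
                    ("S_mismatched", m.model_id,
                     lambda m=m: run_single_model(m, target, cfg))
                )
            runs.append(
                ("M_eq", "+".join(m.model_id for m in others),
                 lambda: run_open_loop(others, None, target, cfg, adaptive=False))
            )
            runs.append(
                ("M_aw", "+".join(m.model_id for m in others),
                 lambda: run_open_loop(others, wmap, target, cfg, adaptive=True))
            )
            for kind, detail, fn in runs:
                try:
                    useq = fn()
                    _, err = apply_to_plant(plant, useq, target)
                    results.append(
                        BenchmarkResult(
                            plant_id=plant.model_id,
                            target=tuple(tgt),
                            controller=kind,
                            controller_detail=detail,
                            sq_error=err,
                            doses=useq.doses,
                        )
                    )
                except Exception:
                    logger.exception(
                        "scenario failed: plant=%s target=%s controller=%s",
                        plant.model_id, tgt, kind,
                    )
    return results


def results_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "t_off": r.target[0],
                "p_ss": r.target[1],
                "controller": r.controller,
                "controller_detail": r.controller_detail,
                "sq_error": r.sq_error,
            }
            for r in results
        ]
    )


def summarize_benchmark(results: list[BenchmarkResult]) -> dict:
    """Mean +/- standard error per controller class and percent reductions
    of the adaptive-weight controller against each comparator."""
    df = results_frame(results)
    summary = {}
    for kind, g in df.groupby("controller"):
        vals = g["sq_error"].to_numpy()
        summary[kind] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
            if vals.size > 1 else 0.0,
        }
    if "M_aw" in summary:
        maw = summary["M_aw"]["mean"]
        for kind in ("S_mismatched", "M_eq", "S_matched"):
            if kind in summary and summary[kind]["mean"] > 0:
                summary[f"pct_reduction_vs_{kind}"] = float(
                    100.0 * (1.0 - maw / summary[kind]["mean"])
                )
    return summary


def weight_map_sensitivity(
    bank: list[PredictionModel],
    full_dataset,
    limited_dataset,
    cfg: RunConfig | None = None,
    targets=((8, 0.0),),
    n_lattice: int = 11,
    run_control: bool = True,
) -> dict:
    """Compare weight maps (and the regimens they produce) between a full
    and a limited training dataset.

    Reports the fraction of lattice points at which the model *ranking*
    (argsort of weights) agrees, and per-target dose differences between
    the control sequences designed under either map.  The agreement metric
    is symmetric in the two datasets.
    """
    cfg = cfg or RunConfig()
    map_full = build_weight_map(bank, full_dataset, cfg.space)
    map_lim = build_weight_map(bank, limited_dataset, cfg.space)

    pts = cfg.space.lattice(n_lattice)
    agree = 0
    for p in pts:
        rf = np.argsort(map_full.weights_at(p))
        rl = np.argsort(map_lim.weights_at(p))
        agree += int(np.array_equal(rf, rl))
    report = {
        "n_lattice": int(pts.shape[0]),
        "ranking_agreement": float(agree / pts.shape[0]),
        "dose_differences": {},
    }
    if run_control:
        for tgt in targets:
            target = target_trajectory(*tgt)
            u_full = run_open_loop(bank, map_full, target, cfg, adaptive=True)
            u_lim = run_open_loop(bank, map_lim, target, cfg, adaptive=True)
            report["dose_differences"][str(tgt)] = {
                "max_abs": float(np.max(np.abs(u_full.doses - u_lim.doses))),
                "doses_full": u_full.doses.tolist(),
                "doses_limited": u_lim.doses.tolist(),
            }
    return report
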