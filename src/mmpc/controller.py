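"""The receding-horizon open-loop control loop.

For each dosing interval the controller (i) builds per-model sparse-grid
surrogates of the tracking objective from each model's *own* current state,
(ii) sweeps out the Pareto set of candidate doses with the normalized
normal constraint method, (iii) selects the interval's dose by adaptive
Akaike-weighted ranking, and (iv) advances every prediction model under the
chosen bolus.  The resulting dose sequence U* is the finished open-loop
regimen, ready to be applied to the plant.

Controller kinds:

* ``M_aw``  — multiple models, adaptive Akaike weights (the full strategy);
* ``M_eq``  — multiple models, weights fixed at 1/n_M, no adaptation;
* ``S_i``   — single model i: direct minimization of J_i over the input
  space, no Pareto stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptive_selection import SelectionTrace, adapt_and_select, rank_solutions
from .model_bank import (
    BolusSchedule,
    InputSpace,
    ModelState,
    PredictionModel,
    default_input_space,
    simulate,
)
from .mpc_objective import (
    ObjectiveSpec,
    TargetTrajectory,
    build_objective_surrogates,
)
from .pareto_nnc import ParetoSet, _minimize_multistart, generate_pareto_set
from .weight_maps import WeightMap

__all__ = [
    "RunConfig",
    "ControlSequence",
    "run_open_loop",
    "run_single_model",
    "apply_to_plant",
    "sq_error",
]

DEFAULT_DOSE_TIMES = (3.0, 8.0, 13.0, 18.0, 23.0)


@dataclass
class RunConfig:
    """Everything the control loop needs besides models and weight map."""

    space: InputSpace = field(default_factory=default_input_space)
    dose_times: tuple = DEFAULT_DOSE_TIMES
    t_end: float = 30.0
    n_pareto: int = 15
    max_iter: int = 10
    tol_w: float = 1e-3
    use_surrogate: bool = True
    surrogate_cfg: dict = field(
        default_factory=lambda: dict(tol_abs=0.01, tol_rel=0.01, max_depth=6)
    )
    windowed_weights: bool = False
    objective: ObjectiveSpec | None = None

    def spec(self, n_u: int) -> ObjectiveSpec:
        if self.objective is not None:
            return self.objective
        return ObjectiveSpec(
            Q=np.eye(1), R=np.eye(n_u), u_scale=self.space.upper.copy()
        )

    def interval_of(self, k: int) -> tuple[float, float]:
        t0 = self.dose_times[k]
        if k + 1 < len(self.dose_times):
            return t0, min(self.dose_times[k + 1], self.t_end)
        # final interval: predict through the end of the experiment
        return t0, self.t_end


@dataclass
class ControlSequence:
    """The finished open-loop dosing regimen U*."""

    dose_times: np.ndarray
    doses: np.ndarray  # (n_intervals, n_u)
    traces: list[SelectionTrace | None] = field(default_factory=list)
    pareto_sets: list[ParetoSet | None] = field(default_factory=list)

    def schedule(self) -> BolusSchedule:
        return BolusSchedule(dose_times=self.dose_times, doses=self.doses)

    def to_json_dict(self) -> dict:
        return {
            "dose_times": self.dose_times.tolist(),
            "doses": self.doses.tolist(),
            "traces": [
                t.to_json_dict() if t is not None else None for t in self.traces
            ],
        }


def _interval_objectives(models, states, target, spec, interval, cfg):
    return build_objective_surrogates(
        models,
        states,
        target,
        spec,
        interval,
        cfg.space,
        grid_cfg=cfg.surrogate_cfg,
        use_surrogate=cfg.use_surrogate,
    )


def run_open_loop(
    bank: list[PredictionModel],
    wmap: WeightMap | None,
    target: TargetTrajectory,
    cfg: RunConfig,
    *,
    adaptive: bool = True,
) -> ControlSequence:
    """Design the open-loop dose sequence with the multiple-model strategy.

    With ``adaptive`` the weights are recalibrated from the weight map at
    every candidate dose (``M_aw``); otherwise fixed equal weights are used
    (``M_eq``, weight map not required).
    """
    if adaptive and wmap is None:
        raise ValueError("adaptive control requires a trained weight map")
    n_u = bank[0].n_u
    spec = cfg.spec(n_u)
    states = [m.initial_state() for m in bank]
    doses, traces, psets = [], [], []
    w_prev = wmap.global_weights() if adaptive else np.full(len(bank), 1.0 / len(bank))

    for k in range(len(cfg.dose_times)):
        interval = cfg.interval_of(k)
        try:
            objectives = _interval_objectives(
                bank, states, target, spec, interval, cfg
            )
            pareto = generate_pareto_set(objectives, cfg.space, cfg.n_pareto)
            if adaptive:
                window = interval if cfg.windowed_weights else None
                trace = adapt_and_select(
                    pareto,
                    wmap,
                    w_prev,
                    tol_w=cfg.tol_w,
                    tol_u=cfg.space.range / 100.0,
                    max_iter=cfg.max_iter,
                    window=window,
                )
                u_sel = trace.final_u
                w_prev = trace.final_weights
            else:
                idx, u_sel = rank_solutions(pareto, w_prev)
                trace = SelectionTrace(
                    iterations=[(u_sel.copy(), w_prev.copy(), idx)],
                    terminated_by="converged",
                    final_u=u_sel,
                    final_weights=w_prev.copy(),
                )
        except Exception as err:
            raise RuntimeError(
                f"control interval {k} (t = {interval[0]:g} min) failed: {err}"
            ) from err

        doses.append(np.asarray(u_sel, dtype=float))
        traces.append(trace)
        psets.append(pareto)
        states = _advance_all(bank, states, u_sel, k, cfg)

    return ControlSequence(
        dose_times=np.asarray(cfg.dose_times, dtype=float),
        doses=np.array(doses),
        traces=traces,
        pareto_sets=psets,
    )


def _advance_all(bank, states, dose, k, cfg):
    from .model_bank import advance_state

    t0 = cfg.dose_times[k]
    t1 = cfg.dose_times[k + 1] if k + 1 < len(cfg.dose_times) else cfg.t_end
    return [
        advance_state(m, s, dose, t0, t1) for m, s in zip(bank, states)
    ]


def run_single_model(
    model: PredictionModel,
    target: TargetTrajectory,
    cfg: RunConfig,
) -> ControlSequence:
    """Single-model controller: direct minimization of that model's
    objective per interval (no Pareto stage)."""
    spec = cfg.spec(model.n_u)
    state = model.initial_state()
    doses = []
    for k in range(len(cfg.dose_times)):
        interval = cfg.interval_of(k)
        (objective,) = _interval_objectives(
            [model], [state], target, spec, interval, cfg
        )
        res = _minimize_multistart(
            lambda u: float(objective(u)), cfg.space, n_starts=5
        )
        if res is None:
            raise RuntimeError(f"single-model optimization failed at interval {k}")
        u_sel = cfg.space.clip(res.x)
        doses.append(u_sel)
        (state,) = _advance_all([model], [state], u_sel, k, cfg)
    return ControlSequence(
        dose_times=np.asarray(cfg.dose_times, dtype=float),
        doses=np.array(doses),
        traces=[None] * len(doses),
        pareto_sets=[None] * len(doses),
    )


def sq_error(z: np.ndarray, r: np.ndarray) -> float:
    return float(np.sum((z - r) ** 2))


def apply_to_plant(
    plant: PredictionModel,
    useq: ControlSequence,
    target: TargetTrajectory,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    eval_dt: float = 1.0,
):
    """Simulate the plant under U* and score target tracking.

    Returns ``(SimulationResult, squared_error)`` on a 1-min evaluation
    grid over [0, t_end].  Optional observation noise emulates assay error
    (off by default: the in silico studies use deterministic plants).
    """
    t_end = max(30.0, useq.dose_times[-1] if useq.dose_times.size else 30.0)
    t_grid = np.arange(0.0, t_end + 1e-9, eval_dt)
    res = simulate(plant, useq.schedule(), t_grid)
    z = res.z[:, 0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, noise_sd * max(z.max(), 1e-12), size=z.shape)
    return res, sq_error(z, target(t_grid))
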