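"""Per-model finite-horizon tracking objectives and target trajectories.

The controller scores a candidate bolus ``U_k`` for the interval starting
at ``t_k`` with the weighted tracking/effort objective

    J = sum_m (z_hat(t_m) - r(t_m))' Q (z_hat(t_m) - r(t_m))
      + sum (u / u_scale)' R (u / u_scale),

summed over 1-min samples of the prediction horizon, and returns
``ln(J + log_eps)``: log-space compression flattens the many-orders-of-
magnitude cost surface and keeps the perfect-tracking case (J = 0) finite.
``u_scale`` defaults to ones so the effort term is the plain quadratic in
the dose vector; the controller configures it to the input-space upper
bounds so that a full dose of either reagent carries the same unit effort
regardless of its concentration range.

Target trajectories r(t) encode "activate fully, hold, then settle to a
fraction p_ss of maximal activation from t_off onward":

    r(t) = (1 - exp(-t / tau_r)) * [p_ss + (1 - p_ss) / (1 + exp((t - t_off) / tau_f))]

with rise and fall time constants of one minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_bank import InputSpace, ModelState, PredictionModel
from .surrogate import build_surrogate

__all__ = [
    "ObjectiveSpec",
    "TargetTrajectory",
    "target_trajectory",
    "CASE_STUDY_TARGETS",
    "tracking_objective",
    "build_objective_surrogates",
]

#: The ten (t_off, p_ss) case-study pairs shipped as a named preset.
CASE_STUDY_TARGETS = (
    (8, 0.0), (15, 0.0), (22, 0.0),
    (8, 0.25), (15, 0.25), (22, 0.25),
    (8, 0.5), (15, 0.5), (22, 0.5),
    (30, 1.0),
)


@dataclass
class ObjectiveSpec:
    """Weights and horizons of the tracking objective."""

    Q: np.ndarray = field(default_factory=lambda: np.eye(1))
    R: np.ndarray = field(default_factory=lambda: np.eye(2))
    H_u: int = 1
    H_p: int = 1
    log_eps: float = 1e-2
    sample_dt: float = 1.0  # min, within-horizon sampling of the error sum
    u_scale: np.ndarray | None = None  # effort normalization (defaults to 1)

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.H_u > self.H_p:
            raise ValueError("control horizon H_u must not exceed H_p")
        if self.log_eps <= 0:
            raise ValueError("log_eps must be positive")


@dataclass(frozen=True)
class TargetTrajectory:
    """Smooth on/off reference for the controlled output."""

    t_off: float  # min
    p_ss: float   # desired steady-state fraction of maximal activation
    tau_r: float = 1.0
    tau_f: float = 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        rise = 1.0 - np.exp(-t / self.tau_r)
        settle = self.p_ss + (1.0 - self.p_ss) / (
            1.0 + np.exp((t - self.t_off) / self.tau_f)
        )
        return rise * settle


def target_trajectory(t_off: float, p_ss: float) -> TargetTrajectory:
    """Build the target r(t) for a (t_off, p_ss) pair.

    ``t_off`` must lie in (0, 30] min and ``p_ss`` in [0, 1].
    """
    if not 0.0 < t_off <= 30.0:
        raise ValueError("t_off must lie in (0, 30] minutes")
    if not 0.0 <= p_ss <= 1.0:
        raise ValueError("p_ss must lie in [0, 1]")
    return TargetTrajectory(t_off=float(t_off), p_ss=float(p_ss))


def _horizon_times(interval, dt):
    t0, t1 = interval
    n = max(int(round((t1 - t0) / dt)), 1)
    return t0 + dt * np.arange(1, n + 1)


def tracking_objective(
    model: PredictionModel,
    state: ModelState,
    U_k: np.ndarray,
    target: TargetTrajectory,
    spec: ObjectiveSpec,
    interval: tuple[float, float],
) -> float:
    """Log-space tracking objective of a candidate dose for one interval.

    ``U_k`` is one dose vector (H_u = 1) or a (H_u, n_u) array; doses beyond
    the control horizon are held (the bolus is persistent, so holding means
    no further addition).  The prediction starts from the model's current
    ``state``; the first dose is applied at the interval start.
    """
    U = np.atleast_2d(np.asarray(U_k, dtype=float))
    t0, t1 = interval
    dt_interval = (t1 - t0) / spec.H_p
    t_samples = _horizon_times(interval, spec.sample_dt)

    u_scale = (
        np.ones(model.n_u) if spec.u_scale is None else np.asarray(spec.u_scale)
    )

    # advance through the control moves; with H_u = 1 this is one segment
    from .model_bank import predict_and_advance

    st = state.copy()
    z_parts = []
    cur_t = t0
    effort = 0.0
    for m in range(spec.H_p):
        dose = U[m] if m < U.shape[0] else np.zeros(model.n_u)
        if m < U.shape[0]:
            un = dose / u_scale
            effort += float(un @ spec.R @ un)
        seg_end = t0 + (m + 1) * dt_interval
        seg_times = t_samples[(t_samples > cur_t) & (t_samples <= seg_end + 1e-9)]
        z, st = predict_and_advance(model, st, dose, cur_t, seg_end, seg_times)
        z_parts.append(z)
        cur_t = seg_end

    z_hat = np.vstack(z_parts)[:, 0]
    r = target(t_samples)
    err = z_hat - r
    tracking = float(np.sum(err * (spec.Q[0, 0] * err))) if spec.Q.shape == (1, 1) \
        else float(sum(e @ spec.Q @ e for e in np.atleast_2d(err).T))
    J = tracking + effort
    return float(np.log(J + spec.log_eps))


def build_objective_surrogates(
    models: list[PredictionModel],
    states: list[ModelState],
    target: TargetTrajectory,
    spec: ObjectiveSpec,
    interval: tuple[float, float],
    space: InputSpace,
    grid_cfg: dict | None = None,
    use_surrogate: bool = True,
):
    """One objective callable per model for the current interval.

    With ``use_surrogate`` the log-space objective is interpolated on an
    error-controlled sparse grid over the input space, after which no
    further ODE solves are needed downstream; otherwise direct-evaluation
    callables with the identical contract are returned.
    """
    grid_cfg = dict(grid_cfg or {})

    def direct(model, state):
        def fn(u):
            return tracking_objective(model, state, u, target, spec, interval)

        return fn

    fns = [direct(m, s) for m, s in zip(models, states)]
    if not use_surrogate:
        return fns
    return [build_surrogate(fn, space, **grid_cfg) for fn in fns]
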