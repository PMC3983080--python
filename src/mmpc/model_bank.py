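"""Prediction-model abstraction and bolus-dosing simulation.

A prediction model is a nonlinear ODE system

    dx/dt = f(x, u, t, theta),   y = g(x, u, t, theta),   z = h(x, u, t, theta)

with state ``x`` (concentration-like, nonnegative), control input ``u``
(reagent concentrations), measured outputs ``y`` and controlled outputs
``z``.  Inputs are applied as boluses: a dose administered at time ``t_d``
raises a persistent standing input concentration that enters the rate laws
(typically through saturating Hill terms); later doses add to the standing
concentration.  Controlled outputs are normalized so that the peak of the
*uncontrolled* response equals one, putting structurally different models on
a common output scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InputSpace",
    "BolusSchedule",
    "PredictionModel",
    "ModelState",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "advance_state",
    "calibrate_normalization",
    "result_to_frame",
]

DEFAULT_T_END = 30.0  # minutes
DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9


class SimulationError(RuntimeError):
    """Raised when an ODE integration fails or produces non-finite state."""


@dataclass(frozen=True)
class InputSpace:
    """Admissible control-input box Omega = [lower, upper] componentwise."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D vectors of equal length")
        if np.any(lo > hi):
            raise ValueError("InputSpace requires lower <= upper componentwise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def n_u(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, u: np.ndarray, tol: float = 1e-9) -> bool:
        u = np.asarray(u, dtype=float)
        return bool(
            np.all(u >= self.lower - tol) and np.all(u <= self.upper + tol)
        )

    def clip(self, u: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(u, dtype=float), self.lower, self.upper)

    def lattice(self, n_per_dim: int) -> np.ndarray:
        """Full-factorial lattice over the box, shape (n_per_dim**n_u, n_u)."""
        axes = [
            np.linspace(lo, hi, n_per_dim)
            for lo, hi in zip(self.lower, self.upper)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


#: Case-study default: reagent 1 (phosphatase inhibitor) in [0, 50] uM,
#: reagent 2 (terminal-kinase inhibitor) in [0, 10] uM.
def default_input_space() -> InputSpace:
    return InputSpace(lower=np.zeros(2), upper=np.array([50.0, 10.0]))


@dataclass(frozen=True)
class BolusSchedule:
    """An ordered sequence of bolus doses: one input vector per dose time."""

    dose_times: np.ndarray
    doses: np.ndarray  # shape (n_times, n_u)

    def __post_init__(self):
        t = np.asarray(self.dose_times, dtype=float)
        d = np.atleast_2d(np.asarray(self.doses, dtype=float))
        if t.ndim != 1 or d.shape[0] != t.size:
            raise ValueError("doses must have one row per dose time")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("dose_times must be strictly increasing")
        object.__setattr__(self, "dose_times", t)
        object.__setattr__(self, "doses", d)

    @classmethod
    def empty(cls, n_u: int = 2) -> "BolusSchedule":
        return cls(dose_times=np.empty(0), doses=np.empty((0, n_u)))

    @classmethod
    def single(cls, dose: Sequence[float], dose_time: float) -> "BolusSchedule":
        return cls(dose_times=np.array([dose_time]), doses=np.array([dose]))

    def validate(self, space: InputSpace) -> None:
        for d in self.doses:
            if not space.contains(d):
                raise ValueError(f"dose {d} outside input space bounds")


@dataclass
class PredictionModel:
    """An ODE prediction model with measured/controlled output maps.

    ``rhs``, ``measured_map`` and ``controlled_map`` all take
    ``(x, u, t, params)`` where ``u`` is the standing input-concentration
    vector.  ``n_params`` is the number of uncertain parameters used in the
    AICc complexity penalty.  ``output_scale`` divides the raw controlled
    output; :func:`calibrate_normalization` sets it so the uncontrolled peak
    is one.
    """

    model_id: str
    n_x: int
    n_u: int
    x0: np.ndarray
    params: dict
    rhs: Callable
    measured_map: Callable
    controlled_map: Callable
    n_params: int
    output_scale: np.ndarray = field(default_factory=lambda: np.ones(1))

    def copy(self) -> "PredictionModel":
        m = dataclasses.replace(self)
        m.x0 = np.array(self.x0, dtype=float)
        m.params = dict(self.params)
        m.output_scale = np.array(self.output_scale, dtype=float)
        return m

    def initial_state(self) -> "ModelState":
        return ModelState(
            x=np.array(self.x0, dtype=float), u_standing=np.zeros(self.n_u)
        )


@dataclass
class ModelState:
    """Integration state carried across dosing intervals.

    ``u_standing`` is the accumulated (un-washed-out) input concentration.
    """

    x: np.ndarray
    u_standing: np.ndarray

    def copy(self) -> "ModelState":
        return ModelState(x=np.array(self.x), u_standing=np.array(self.u_standing))


@dataclass
class SimulationResult:
    t_grid: np.ndarray
    states: np.ndarray  # (n_t, n_x)
    y: np.ndarray  # (n_t, n_y)
    z: np.ndarray  # (n_t, n_z), normalized


def _integrate_segment(model, x, u, t0, t1, t_eval, rtol, atol):
    """Integrate one constant-input segment; returns (states_at_t_eval, x_end)."""
    def f(t, xx):
        return model.rhs(xx, u, t, model.params)

    if t1 <= t0:
        return np.empty((0, x.size)), x
    # append t1 so the end state comes from the same solve
    t_eval = np.asarray(t_eval, dtype=float)
    need_end = t_eval.size == 0 or t_eval[-1] < t1 - 1e-12
    t_all = np.append(t_eval, t1) if need_end else t_eval
    sol = solve_ivp(
        f,
        (t0, t1),
        x,
        method="LSODA",
        t_eval=t_all,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"integration failed for model '{model.model_id}' on "
            f"[{t0:.3g}, {t1:.3g}] min: {sol.message}"
        )
    x_end = sol.y[:, -1]
    states = sol.y[:, : t_eval.size].T if t_eval.size else np.empty((0, x.size))
    return states, x_end


def _integrate_piecewise(model, state, t0, t_grid, schedule, rtol, atol):
    """Integrate from ``state`` at t0 over t_grid, applying scheduled boluses.

    Returns (states on t_grid, final ModelState at max(t_grid[-1], t0)).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    x = np.array(state.x, dtype=float)
    u = np.array(state.u_standing, dtype=float)
    out = np.empty((t_grid.size, x.size))
    filled = np.zeros(t_grid.size, dtype=bool)

    # grid points at/before t0 get the current state (causality: nothing
    # happens before integration starts)
    pre = t_grid <= t0 + 1e-12
    out[pre] = x
    filled[pre] = True

    future = [(t, d) for t, d in zip(schedule.dose_times, schedule.doses) if t > t0 + 1e-12]
    breakpoints = [t for t, _ in future] + [max(t_grid[-1], t0)]
    doses = {t: d for t, d in future}

    t_cur = t0
    for t_next in breakpoints:
        if t_next > t_cur:
            mask = (~filled) & (t_grid > t_cur + 1e-12) & (t_grid <= t_next + 1e-12)
            t_eval = t_grid[mask]
            states, x = _integrate_segment(model, x, u, t_cur, t_next, t_eval, rtol, atol)
            out[mask] = states
            filled[mask] = True
            t_cur = t_next
        if t_next in doses:
            u = u + np.asarray(doses[t_next], dtype=float)
    out[~filled] = x  # grid points beyond the last breakpoint (none normally)
    return out, ModelState(x=x, u_standing=u)


def simulate(
    model: PredictionModel,
    schedule: BolusSchedule,
    t_grid: np.ndarray,
    *,
    state: ModelState | None = None,
    t_start: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SimulationResult:
    """Simulate a model under a bolus dosing schedule.

    Integrates piecewise between dose times (dose times are integration
    breakpoints, so boluses are resolved exactly) and returns state,
    measured-output and normalized controlled-output trajectories on
    ``t_grid``.  Deterministic.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if state is None:
        state = model.initial_state()
    states, _ = _integrate_piecewise(
        model, state, t_start, t_grid, schedule, rtol, atol
    )
    return _outputs(model, states, t_grid, state, schedule)


def _standing_u(state: ModelState, schedule: BolusSchedule, t: float) -> np.ndarray:
    u = np.array(state.u_standing)
    for td, d in zip(schedule.dose_times, schedule.doses):
        if td <= t + 1e-12:
            u = u + d
    return u


def _outputs(model, states, t_grid, state0, schedule):
    y_rows, z_rows = [], []
    for t, x in zip(t_grid, states):
        u = _standing_u(state0, schedule, t)
        y_rows.append(np.atleast_1d(model.measured_map(x, u, t, model.params)))
        z_rows.append(
            np.atleast_1d(model.controlled_map(x, u, t, model.params))
            / model.output_scale
        )
    return SimulationResult(
        t_grid=t_grid,
        states=states,
        y=np.array(y_rows),
        z=np.array(z_rows),
    )


def advance_state(
    model: PredictionModel,
    state: ModelState,
    dose: np.ndarray,
    t0: float,
    t1: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ModelState:
    """Apply a bolus at ``t0`` and integrate the model state to ``t1``."""
    new = state.copy()
    new.u_standing = new.u_standing + np.asarray(dose, dtype=float)
    _, end = _integrate_piecewise(
        model, new, t0, np.array([t1]), BolusSchedule.empty(model.n_u), rtol, atol
    )
    return end


def predict_z(
    model: PredictionModel,
    state: ModelState,
    dose: np.ndarray,
    t0: float,
    t_eval: np.ndarray,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Controlled-output prediction from ``state`` after a bolus at ``t0``."""
    st = state.copy()
    st.u_standing = st.u_standing + np.asarray(dose, dtype=float)
    states, _ = _integrate_piecewise(
        model, st, t0, np.asarray(t_eval, dtype=float),
        BolusSchedule.empty(model.n_u), rtol, atol,
    )
    z = np.array(
        [
            np.atleast_1d(model.controlled_map(x, st.u_standing, t, model.params))
            / model.output_scale
            for t, x in zip(np.atleast_1d(t_eval), states)
        ]
    )
    return z


def predict_and_advance(
    model: PredictionModel,
    state: ModelState,
    dose: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[np.ndarray, ModelState]:
    """Bolus at ``t0``, controlled-output samples on ``t_eval`` and the end
    state at ``t1``, from a single integration."""
    st = state.copy()
    st.u_standing = st.u_standing + np.asarray(dose, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    x = np.array(st.x, dtype=float)
    states, x_end = _integrate_segment(model, x, st.u_standing, t0, t1, t_eval, rtol, atol)
    z = np.array(
        [
            np.atleast_1d(model.controlled_map(xx, st.u_standing, t, model.params))
            / model.output_scale
            for t, xx in zip(t_eval, states)
        ]
    )
    return z, ModelState(x=x_end, u_standing=st.u_standing)


def calibrate_normalization(
    model: PredictionModel,
    t_grid: np.ndarray | None = None,
) -> PredictionModel:
    """Set ``output_scale`` so the uncontrolled controlled-output peak is 1.

    Idempotent, and invariant to any fixed rescaling of the raw controlled
    output map.  Raises if the uncontrolled peak is not positive.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, DEFAULT_T_END, 301)
    raw = model.copy()
    raw.output_scale = np.ones_like(np.atleast_1d(raw.output_scale), dtype=float)
    res = simulate(raw, BolusSchedule.empty(model.n_u), t_grid)
    peak = res.z.max(axis=0)
    if np.any(peak <= 0):
        raise ValueError(
            f"model '{model.model_id}' has non-positive uncontrolled peak; "
            "cannot normalize"
        )
    out = model.copy()
    out.output_scale = peak
    return out


def result_to_frame(result: SimulationResult, model_id: str):
    """Tidy long-format trajectory table (model_id, time_min, variable, value)."""
    import pandas as pd

    rows = []
    for j in range(result.states.shape[1]):
        for t, v in zip(result.t_grid, result.states[:, j]):
            rows.append((model_id, t, f"x{j}", v))
    for j in range(result.z.shape[1]):
        for t, v in zip(result.t_grid, result.z[:, j]):
            rows.append((model_id, t, f"z{j}", v))
    return pd.DataFrame(rows, columns=["model_id", "time_min", "variable", "value"])
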