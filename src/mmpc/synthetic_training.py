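"""Synthetic dose-response training experiments and spline smoothing.

Emulates the 14-experiment screening protocol used to train model weight
maps: one unperturbed control, a five-dose ladder of the phosphatase
inhibitor (input 1) administered at 15 min, a five-dose ladder of the
kinase inhibitor (input 2) at 6 min, and three dose combinations at 6 min.
Raw time courses carry additive Gaussian observation noise and are smoothed
with penalized cubic smoothing splines, then resampled on a dense uniform
grid (31 points by default) to increase time-course density.

The smoothing spline minimizes ``p * sum_i (y_i - s(t_i))^2 +
(1 - p) * int s''(t)^2 dt`` — the convention under which the default
smoothing weight is p = 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .model_bank import (
    BolusSchedule,
    InputSpace,
    PredictionModel,
    simulate,
)

__all__ = [
    "TrainingExperiment",
    "TrainingDataset",
    "generate_training_design",
    "simulate_training_data",
    "smooth_resample",
    "dataset_to_frame",
    "dataset_from_frame",
]

INPUT1_LADDER = (0.5, 2.0, 5.0, 20.0, 50.0)  # uM, dosed at 15 min
INPUT2_LADDER = (0.5, 1.0, 2.0, 5.0, 10.0)   # uM, dosed at 6 min
COMBO_DOSES = ((0.5, 1.0), (50.0, 1.0), (50.0, 10.0))  # dosed at 6 min
DEFAULT_SMOOTHING_P = 0.6
DEFAULT_N_RESAMPLE = 31


@dataclass
class TrainingExperiment:
    """One raw dose-response time course."""

    experiment_id: str
    dose: np.ndarray
    dose_time: float  # min
    t_samples: np.ndarray
    y_raw: np.ndarray
    n_replicates: int = 1

    def schedule(self) -> BolusSchedule:
        if np.all(self.dose == 0):
            return BolusSchedule.empty(self.dose.size)
        return BolusSchedule.single(self.dose, self.dose_time)


@dataclass
class TrainingDataset:
    """Raw experiments plus their smoothed, densely resampled counterparts."""

    experiments: list[TrainingExperiment]
    t_smooth: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_smooth: dict = field(default_factory=dict)  # experiment_id -> values
    smooth_p: float = DEFAULT_SMOOTHING_P
    smooth_n: int = DEFAULT_N_RESAMPLE

    @property
    def n_total(self) -> int:
        """Total number of raw measurement points across experiments."""
        return int(sum(e.y_raw.size for e in self.experiments))

    def smooth(
        self,
        p: float = DEFAULT_SMOOTHING_P,
        n_out: int = DEFAULT_N_RESAMPLE,
    ) -> "TrainingDataset":
        self.smooth_p, self.smooth_n = p, n_out
        for exp in self.experiments:
            t_out, y_out = smooth_resample(exp, p=p, n_out=n_out)
            self.t_smooth = t_out
            self.y_smooth[exp.experiment_id] = y_out
        return self


def generate_training_design(space: InputSpace) -> list[tuple[np.ndarray, float]]:
    """The 14-experiment screening design: control, two dose ladders, combos.

    Returns ``(dose, dose_time)`` pairs.  Requires a two-input space; all
    doses lie within the space bounds.
    """
    if space.n_u != 2:
        raise ValueError("the screening design is defined for a 2-input space")
    design: list[tuple[np.ndarray, float]] = [(np.zeros(2), 0.0)]
    design += [(np.array([d, 0.0]), 15.0) for d in INPUT1_LADDER]
    design += [(np.array([0.0, d]), 6.0) for d in INPUT2_LADDER]
    design += [(np.array(c), 6.0) for c in COMBO_DOSES]
    for dose, _ in design:
        if not space.contains(dose):
            raise ValueError(f"design dose {dose} outside input space")
    return design


def simulate_training_data(
    plant: PredictionModel,
    design: list[tuple[np.ndarray, float]],
    noise_sd: float = 0.05,
    n_timepoints: int = 8,
    seed: int = 0,
    *,
    t_end: float = 30.0,
    smooth: bool = True,
) -> TrainingDataset:
    """Simulate the plant through the design and add observation noise.

    Noise is i.i.d. Gaussian per point with standard deviation
    ``noise_sd * peak`` where peak is the maximum of that experiment's
    noiseless trajectory (error bars are roughly uniform on the normalized
    scale).  Seeded and reproducible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t_samples = np.linspace(0.0, t_end, n_timepoints)
    experiments = []
    for i, (dose, dose_time) in enumerate(design):
        sched = (
            BolusSchedule.empty(plant.n_u)
            if np.all(dose == 0)
            else BolusSchedule.single(dose, dose_time)
        )
        res = simulate(plant, sched, t_samples)
        z = res.z[:, 0]
        sd = noise_sd * max(z.max(), 1e-12)
        y = z + rng.normal(0.0, sd, size=z.shape) if noise_sd > 0 else z.copy()
        experiments.append(
            TrainingExperiment(
                experiment_id=f"exp{i:02d}",
                dose=np.asarray(dose, dtype=float),
                dose_time=float(dose_time),
                t_samples=t_samples.copy(),
                y_raw=y,
            )
        )
    ds = TrainingDataset(experiments=experiments)
    if smooth:
        ds.smooth()
    return ds


def smooth_resample(
    exp: TrainingExperiment,
    p: float = DEFAULT_SMOOTHING_P,
    n_out: int = DEFAULT_N_RESAMPLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized cubic smoothing spline, resampled on a uniform grid.

    Minimizes ``p * fidelity + (1 - p) * roughness`` (equivalently the
    standard form with lam = (1 - p) / p) and evaluates at ``n_out`` evenly
    spaced times spanning the raw time range.  ``p = 1`` interpolates the
    raw points exactly.
    """
    t = np.asarray(exp.t_samples, dtype=float)
    y = np.asarray(exp.y_raw, dtype=float)
    if t.size < 5:
        raise ValueError("smoothing requires at least 5 raw time points")
    if not 0.0 <= p <= 1.0:
        raise ValueError("smoothing weight p must lie in [0, 1]")
    t_out = np.linspace(t[0], t[-1], n_out)
    if p == 0.0:
        # pure-roughness limit: weighted linear least squares
        coef = np.polyfit(t, y, 1)
        return t_out, np.polyval(coef, t_out)
    lam = (1.0 - p) / p
    spline = make_smoothing_spline(t, y, lam=lam)
    return t_out, spline(t_out)


# ------------------------------------------------------------------ CSV IO

_CSV_COLUMNS = [
    "experiment_id",
    "dose_1",
    "dose_2",
    "dose_time_min",
    "time_min",
    "output_id",
    "value",
    "replicate",
]


def dataset_to_frame(ds: TrainingDataset) -> pd.DataFrame:
    rows = []
    for exp in ds.experiments:
        for t, v in zip(exp.t_samples, exp.y_raw):
            rows.append(
                (
                    exp.experiment_id,
                    exp.dose[0],
                    exp.dose[1],
                    exp.dose_time,
                    t,
                    "z0",
                    v,
                    1,
                )
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def dataset_from_frame(df: pd.DataFrame, *, smooth: bool = True) -> TrainingDataset:
    """Read a dataset in the training CSV schema (synthetic or real data)."""
    experiments = []
    for exp_id, g in df.groupby("experiment_id", sort=True):
        g = g.sort_values("time_min")
        experiments.append(
            TrainingExperiment(
                experiment_id=str(exp_id),
                dose=np.array([g["dose_1"].iloc[0], g["dose_2"].iloc[0]]),
                dose_time=float(g["dose_time_min"].iloc[0]),
                t_samples=g["time_min"].to_numpy(dtype=float),
                y_raw=g["value"].to_numpy(dtype=float),
                n_replicates=int(g["replicate"].max()),
            )
        )
    ds = TrainingDataset(experiments=experiments)
    if smooth:
        ds.smooth()
    return ds
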