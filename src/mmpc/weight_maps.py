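"""Akaike weight maps over the admissible control-input space.

The corrected Akaike Information Criterion for a least-squares fit with
``n_j`` sampled points on the j-th measured output is

    AICc = sum_j n_j * ln(RSS_j / n_j) + 2k + 2k(k+1) / (n - k - 1),

with ``n = sum_j n_j`` and ``k`` the number of uncertain model parameters.
Akaike weights are the normalized relative likelihoods
``w_i = exp(-Delta_i / 2) / sum_r exp(-Delta_r / 2)`` with
``Delta_i = AICc_i - min_r AICc_r``.

A weight map makes these quantities queryable at *any* input vector u in
Omega, not only at the doses that were actually tested: both the smoothed
training data and each model's predictions under the training protocols are
extended over the (dose x time) space by piecewise-linear interpolation on a
Delaunay triangulation, and the per-model residual sum of squares at u is
computed between the two interpolated surfaces along the time course.
Queries outside the convex hull of the training points clamp to the value at
the nearest support point, so the map is total on Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .model_bank import InputSpace, PredictionModel, simulate

__all__ = [
    "aicc",
    "akaike_weights",
    "TrainingInterpolant",
    "interpolate_training_data",
    "WeightMap",
    "build_weight_map",
]


def aicc(rss_per_output, n_per_output, k: int) -> float:
    """Corrected AIC from per-output residual sums of squares.

    Requires ``n = sum_j n_j > k + 1`` (small-sample correction) and
    positive RSS.
    """
    rss = np.atleast_1d(np.asarray(rss_per_output, dtype=float))
    nj = np.atleast_1d(np.asarray(n_per_output, dtype=float))
    if rss.shape != nj.shape:
        raise ValueError("rss_per_output and n_per_output must align")
    n = float(nj.sum())
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n = {n} <= k + 1 = {k + 1} "
            "(small-sample correction diverges)"
        )
    if np.any(rss <= 0):
        raise ValueError("RSS must be positive")
    return float(
        np.sum(nj * np.log(rss / nj)) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    )


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from AICc values, computed in log space.

    Infinite AICc maps to weight 0; at least one value must be finite.
    """
    a = np.atleast_1d(np.asarray(aicc_values, dtype=float))
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("at least one AICc value must be finite")
    loglik = np.where(finite, -(a - a[finite].min()) / 2.0, -np.inf)
    # log-sum-exp normalization
    m = loglik.max()
    w = np.exp(loglik - m)
    return w / w.sum()


class TrainingInterpolant:
    """Piecewise-linear interpolant over scattered (dose, time) points.

    Coordinates are scaled to the unit cube (per input range and time range)
    before triangulation so that dose and time axes are commensurate.
    Outside the convex hull the value at the nearest support point is
    returned.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray, scale: np.ndarray):
        self._scale = np.asarray(scale, dtype=float)
        pts = np.asarray(points, dtype=float) / self._scale
        vals = np.asarray(values, dtype=float)
        try:
            self._linear = LinearNDInterpolator(pts, vals)
        except QhullError as err:
            raise ValueError(
                "degenerate triangulation of the training support (all "
                "points coplanar in some queried dimension); add experiments "
                "that vary every input independently"
            ) from err
        self._nearest = NearestNDInterpolator(pts, vals)

    def __call__(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float)) / self._scale
        v = self._linear(q)
        bad = ~np.isfinite(v)
        if np.any(bad):
            # points exactly on a hull facet can fail the simplex lookup;
            # nudge toward the support centroid before clamping to nearest
            centroid = self._linear.points.mean(axis=0)
            nudged = q[bad] + 1e-9 * (centroid - q[bad])
            v2 = self._linear(nudged)
            v[bad] = v2
            bad = ~np.isfinite(v)
            if np.any(bad):
                v[bad] = self._nearest(q[bad])
        return v


def _support_scale(space: InputSpace, t_max: float) -> np.ndarray:
    rng = np.where(space.range > 0, space.range, 1.0)
    return np.concatenate([rng, [max(t_max, 1.0)]])


def interpolate_training_data(dataset, u, t, space: InputSpace | None = None):
    """Interpolate smoothed training data at input ``u`` and time(s) ``t``.

    Convenience wrapper that builds the scattered-data interpolant over the
    dataset's (dose, time) support and evaluates it.  For repeated queries
    build a :class:`WeightMap` (which caches the interpolant) instead.
    """
    if not dataset.y_smooth:
        raise ValueError("dataset must be smoothed first (TrainingDataset.smooth)")
    pts, vals = _data_support(dataset)
    if space is None:
        lo = pts[:, :-1].min(axis=0)
        hi = pts[:, :-1].max(axis=0)
        space = InputSpace(lower=lo, upper=hi)
    interp = TrainingInterpolant(pts, vals, _support_scale(space, pts[:, -1].max()))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    q = np.column_stack([np.tile(np.asarray(u, dtype=float), (t.size, 1)), t])
    out = interp(q)
    return out if out.size > 1 else float(out[0])


def _data_support(dataset):
    pts, vals = [], []
    for exp in dataset.experiments:
        y = dataset.y_smooth[exp.experiment_id]
        for t, v in zip(dataset.t_smooth, y):
            pts.append(np.concatenate([exp.dose, [t]]))
            vals.append(v)
    return np.array(pts), np.array(vals)


@dataclass
class WeightMap:
    """Queryable per-model AICc and Akaike-weight surfaces over Omega.

    ``aicc_at`` / ``weights_at`` accept an optional ``window = (t0, t1)``
    restricting the comparison to the training time points inside the
    window (used by the controller when recalibrating weights for the
    current prediction interval).  The effective sample size scales with
    the window fraction so windowed AICc values stay commensurate.
    """

    model_ids: list[str]
    k: np.ndarray                 # per-model uncertain-parameter counts
    n_total: int                  # raw measurement points backing the map
    space: InputSpace
    times: np.ndarray             # smoothed comparison time grid
    data_interp: TrainingInterpolant
    model_interps: list[TrainingInterpolant]
    support_points: np.ndarray    # experimental (dose, time) support
    raw_experiments: list = field(default_factory=list)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def _window_times(self, window):
        if window is None:
            return self.times
        t0, t1 = window
        sel = self.times[(self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)]
        if sel.size < 2:
            # degenerate window: fall back to the nearest two grid points
            idx = np.argsort(np.abs(self.times - 0.5 * (t0 + t1)))[:2]
            sel = np.sort(self.times[idx])
        return sel

    def aicc_at(self, u, window=None) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        key = (tuple(np.round(u, 9)), None if window is None else
               (round(float(window[0]), 6), round(float(window[1]), 6)))
        if key in self._cache:
            return self._cache[key]
        tw = self._window_times(window)
        q = np.column_stack([np.tile(u, (tw.size, 1)), tw])
        data = self.data_interp(q)
        n_eff = self.n_total * tw.size / self.times.size
        vals = np.empty(self.n_models)
        for i, interp in enumerate(self.model_interps):
            pred = interp(q)
            msr = float(np.mean((data - pred) ** 2))
            rss = max(msr, 1e-300) * n_eff
            vals[i] = aicc([rss], [n_eff], int(self.k[i]))
        self._cache[key] = vals
        return vals

    def weights_at(self, u, window=None) -> np.ndarray:
        return akaike_weights(self.aicc_at(u, window))

    def global_weights(self) -> np.ndarray:
        """Weights from the entire training set, without interpolation.

        Per-model RSS against every smoothed experiment directly; used to
        initialize the adaptive selection when no input has been proposed
        yet.
        """
        key = ("__global__",)
        if key in self._cache:
            return self._cache[key]
        n = self.n_total
        vals = np.empty(self.n_models)
        data_vals = self.data_interp(self.support_points)
        for i, interp in enumerate(self.model_interps):
            pred = interp(self.support_points)
            msr = float(np.mean((data_vals - pred) ** 2))
            vals[i] = aicc([max(msr, 1e-300) * n], [n], int(self.k[i]))
        w = akaike_weights(vals)
        self._cache[key] = w
        return w

    def weight_lattice(self, n_per_dim: int = 11, window=None):
        """Weights evaluated on a regular lattice over Omega."""
        pts = self.space.lattice(n_per_dim)
        return pts, np.array([self.weights_at(p, window) for p in pts])

    def to_json_dict(self, n_per_dim: int = 11) -> dict:
        pts, w = self.weight_lattice(n_per_dim)
        a = np.array([self.aicc_at(p) for p in pts])
        return {
            "model_ids": self.model_ids,
            "k": self.k.tolist(),
            "n_total": self.n_total,
            "lattice": pts.tolist(),
            "aicc": a.tolist(),
            "weights": w.tolist(),
            "bounds": {
                "lower": self.space.lower.tolist(),
                "upper": self.space.upper.tolist(),
            },
        }


def build_weight_map(
    models: list[PredictionModel],
    dataset,
    space: InputSpace,
) -> WeightMap:
    """Train a weight map: simulate each model through every training
    protocol, build per-model and data interpolants over the shared
    (dose, time) support, and return the queryable map.
    """
    if not dataset.y_smooth:
        dataset.smooth()
    pts, data_vals = _data_support(dataset)
    scale = _support_scale(space, pts[:, -1].max())
    data_interp = TrainingInterpolant(pts, data_vals, scale)
    model_interps = []
    # model predictions go through the *identical* pipeline as the data —
    # sampled at the raw experiment times, then smoothed and resampled with
    # the same spline — so the spline's systematic rounding of post-bolus
    # transients cancels in the residuals instead of polluting them
    from .synthetic_training import TrainingExperiment, smooth_resample

    for m in models:
        vals = []
        for exp in dataset.experiments:
            res = simulate(m, exp.schedule(), exp.t_samples)
            pseudo = TrainingExperiment(
                experiment_id=exp.experiment_id,
                dose=exp.dose,
                dose_time=exp.dose_time,
                t_samples=exp.t_samples,
                y_raw=res.z[:, 0],
            )
            _, y_out = smooth_resample(
                pseudo, p=dataset.smooth_p, n_out=dataset.smooth_n
            )
            vals.extend(y_out)
        model_interps.append(TrainingInterpolant(pts, np.array(vals), scale))
    return WeightMap(
        model_ids=[m.model_id for m in models],
        k=np.array([m.n_params for m in models], dtype=int),
        n_total=dataset.n_total,
        space=space,
        times=np.asarray(dataset.t_smooth, dtype=float),
        data_interp=data_interp,
        model_interps=model_interps,
        support_points=pts,
        raw_experiments=list(dataset.experiments),
    )
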