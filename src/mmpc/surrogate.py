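"""Error-controlled sparse-grid interpolation surrogates over the input space.

Builds hierarchical sparse-grid interpolants on the nested,
boundary-including (Clenshaw-Curtis-type) point family with piecewise
multilinear basis functions.  One-dimensional refinement levels contribute

* level 0: the midpoint {1/2} with the constant basis function,
* level 1: the boundary points {0, 1} with half-domain hat functions,
* level l >= 2: the odd multiples of 2^-l with hat functions of half-width
  2^-l,

and the d-dimensional sparse grid at depth n is the union of tensor
products of these difference grids over all level vectors with total level
<= n.  Hierarchical surpluses (function value minus the value of the
coarser interpolant at the new node) are the interpolation coefficients;
the maximum absolute surplus on the newest level serves as the error
estimate that drives refinement.

Surrogates evaluate in microseconds, so a model objective sampled at a few
dozen ODE solves can be screened across the whole input space essentially
for free.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .model_bank import InputSpace

__all__ = [
    "Surrogate",
    "TimeSurrogate",
    "build_surrogate",
    "evaluate",
    "sparse_grid_size",
]

DEFAULT_TOL_ABS = 0.01
DEFAULT_TOL_REL = 0.01
DEFAULT_MAX_DEPTH = 6


def _level_nodes_1d(level: int) -> np.ndarray:
    """Unit-interval nodes *new* at the given level."""
    if level == 0:
        return np.array([0.5])
    if level == 1:
        return np.array([0.0, 1.0])
    step = 2.0 ** (-level)
    return np.arange(1, 2**level, 2) * step


def _basis_widths(levels: np.ndarray) -> np.ndarray:
    """Inverse support half-widths of the hierarchical hat functions.

    Every basis function is ``max(1 - w * |x - node|, 0)``: the level-0
    constant has w = 0, the level-1 boundary hats have w = 2 (|x - node|
    never exceeds 1/2 on their support side), and level l >= 2 hats have
    w = 2**l.
    """
    return np.where(levels == 0, 0.0, 2.0 ** np.maximum(levels, 1))


def _basis_1d(level: np.ndarray, node: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Hierarchical piecewise-linear basis, broadcast over nodes and points."""
    w = _basis_widths(np.asarray(level))
    return np.maximum(1.0 - w * np.abs(x - node), 0.0)


def sparse_grid_size(dim: int, depth: int) -> int:
    """Number of sparse-grid nodes at the given depth and dimension."""
    def m(l):
        return 1 if l == 0 else (2 if l == 1 else 2 ** (l - 1))

    total = 0
    for lv in itertools.product(range(depth + 1), repeat=dim):
        if sum(lv) <= depth:
            total += int(np.prod([m(l) for l in lv]))
    return total


@dataclass
class Surrogate:
    """A built sparse-grid interpolant over an input box."""

    bounds: InputSpace
    nodes_unit: np.ndarray       # (N, d) support nodes in unit coordinates
    levels: np.ndarray           # (N, d) per-dimension refinement levels
    surpluses: np.ndarray        # (N,) hierarchical coefficients
    fvals: np.ndarray            # (N,) stored function values
    depth: int                   # highest total level built
    est_abs_err: float
    est_rel_err: float
    stopped_by: str              # 'abs' | 'rel' | 'depth'
    _eval_cache: dict = field(default_factory=dict, repr=False)

    @property
    def dimension(self) -> int:
        return self.nodes_unit.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes_unit.shape[0]

    def nodes_physical(self) -> np.ndarray:
        lo, rng = self.bounds.lower, self.bounds.range
        return lo + self.nodes_unit * np.where(rng > 0, rng, 1.0)

    def _to_unit(self, u: np.ndarray) -> np.ndarray:
        lo, rng = self.bounds.lower, self.bounds.range
        return (u - lo) / np.where(rng > 0, rng, 1.0)

    @property
    def _widths(self) -> np.ndarray:
        w = self._eval_cache.get("widths")
        if w is None:
            w = _basis_widths(self.levels)
            self._eval_cache["widths"] = w
        return w

    def __call__(self, u) -> float | np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.ndim == 1:
            if not self.bounds.contains(u):
                raise ValueError(
                    "surrogate evaluated outside its input box (no extrapolation)"
                )
            x = self._to_unit(u)
            B = np.maximum(
                1.0 - self._widths * np.abs(x - self.nodes_unit), 0.0
            ).prod(axis=1)
            return float(B @ self.surpluses)
        U = np.atleast_2d(u)
        if not all(self.bounds.contains(row) for row in U):
            raise ValueError(
                "surrogate evaluated outside its input box (no extrapolation)"
            )
        X = self._to_unit(U)  # (M, d)
        B = np.maximum(
            1.0 - self._widths[None, :, :]
            * np.abs(X[:, None, :] - self.nodes_unit[None, :, :]),
            0.0,
        ).prod(axis=2)
        return B @ self.surpluses

    def to_json_dict(self) -> dict:
        return {
            "bounds": {
                "lower": self.bounds.lower.tolist(),
                "upper": self.bounds.upper.tolist(),
            },
            "nodes_unit": self.nodes_unit.tolist(),
            "levels": self.levels.tolist(),
            "surpluses": self.surpluses.tolist(),
            "fvals": self.fvals.tolist(),
            "depth": self.depth,
            "est_abs_err": self.est_abs_err,
            "est_rel_err": self.est_rel_err,
            "stopped_by": self.stopped_by,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json_dict(cls, d: dict) -> "Surrogate":
        return cls(
            bounds=InputSpace(
                lower=np.array(d["bounds"]["lower"]),
                upper=np.array(d["bounds"]["upper"]),
            ),
            nodes_unit=np.array(d["nodes_unit"], dtype=float),
            levels=np.array(d["levels"], dtype=int),
            surpluses=np.array(d["surpluses"], dtype=float),
            fvals=np.array(d["fvals"], dtype=float),
            depth=int(d["depth"]),
            est_abs_err=float(d["est_abs_err"]),
            est_rel_err=float(d["est_rel_err"]),
            stopped_by=str(d["stopped_by"]),
        )


def build_surrogate(
    fn,
    space: InputSpace,
    tol_abs: float = DEFAULT_TOL_ABS,
    tol_rel: float = DEFAULT_TOL_REL,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> Surrogate:
    """Refine a sparse-grid interpolant of ``fn`` levelwise until the
    estimated error (max hierarchical surplus at the newest level) meets the
    absolute or relative tolerance, or the depth limit is reached.

    ``fn`` takes a physical input vector from ``space`` and returns a finite
    scalar; the relative tolerance is taken against the observed range of
    function values.
    """
    d = space.n_u
    lo, rng = space.lower, np.where(space.range > 0, space.range, 1.0)

    nodes: list[np.ndarray] = []
    levels: list[np.ndarray] = []
    surpluses: list[float] = []
    fvals: list[float] = []
    est_abs = np.inf
    est_rel = np.inf
    stopped_by = "depth"
    depth_built = 0

    def eval_current(X):
        if not nodes:
            return np.zeros(X.shape[0])
        N = np.array(nodes)
        L = np.array(levels)
        S = np.array(surpluses)
        B = _basis_1d(L[None, :, :], N[None, :, :], X[:, None, :]).prod(axis=2)
        return B @ S

    for total_level in range(max_depth + 1):
        new_nodes = []
        new_levels = []
        for lv in itertools.product(range(total_level + 1), repeat=d):
            if sum(lv) != total_level:
                continue
            axes = [_level_nodes_1d(l) for l in lv]
            for pt in itertools.product(*axes):
                new_nodes.append(np.array(pt))
                new_levels.append(np.array(lv, dtype=int))
        X = np.array(new_nodes)
        prior = eval_current(X)
        level_surpluses = []
        for x_unit, pred in zip(new_nodes, prior):
            u_phys = lo + x_unit * rng
            val = float(fn(u_phys))
            if not np.isfinite(val):
                raise ValueError(
                    f"non-finite function value at support node {u_phys}"
                )
            s = val - pred
            nodes.append(x_unit)
            levels.append(new_levels[len(level_surpluses)])
            surpluses.append(s)
            fvals.append(val)
            level_surpluses.append(s)
        depth_built = total_level
        if total_level == 0:
            continue  # a single point carries no error information
        est_abs = float(np.max(np.abs(level_surpluses)))
        f_range = float(np.max(fvals) - np.min(fvals))
        est_rel = est_abs / f_range if f_range > 0 else 0.0
        if est_abs <= tol_abs:
            stopped_by = "abs"
            break
        if est_rel <= tol_rel:
            stopped_by = "rel"
            break

    return Surrogate(
        bounds=space,
        nodes_unit=np.array(nodes),
        levels=np.array(levels, dtype=int),
        surpluses=np.array(surpluses),
        fvals=np.array(fvals),
        depth=depth_built,
        est_abs_err=est_abs if np.isfinite(est_abs) else 0.0,
        est_rel_err=est_rel if np.isfinite(est_rel) else 0.0,
        stopped_by=stopped_by,
    )


def evaluate(s: Surrogate, u) -> float | np.ndarray:
    """Evaluate a surrogate at input vector(s) ``u`` (inside its box)."""
    return s(u)


class TimeSurrogate:
    """Per-timepoint sparse grids with linear interpolation between grids.

    Provides a continuous trajectory estimate z(u, t) over the prediction
    window from a handful of input-space surrogates.
    """

    def __init__(self, times, fn_of_u_t, space, **grid_kwargs):
        self.times = np.asarray(times, dtype=float)
        self.grids = [
            build_surrogate(lambda u, _t=t: fn_of_u_t(u, _t), space, **grid_kwargs)
            for t in self.times
        ]

    def __call__(self, u, t) -> float:
        t = float(t)
        if t <= self.times[0]:
            return self.grids[0](u)
        if t >= self.times[-1]:
            return self.grids[-1](u)
        j = int(np.searchsorted(self.times, t)) - 1
        t0, t1 = self.times[j], self.times[j + 1]
        a = (t - t0) / (t1 - t0)
        return (1 - a) * self.grids[j](u) + a * self.grids[j + 1](u)
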