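"""Pareto-set generation by the normalized normal constraint (NNC) method.

Per prediction interval the controller faces one tracking objective per
model; the NNC method turns this multiobjective problem into a family of
scalar subproblems.  Each objective is first minimized individually
(anchor points), the objective space is affinely normalized so each anchor
maps its own objective to 0 and the worst anchor value per objective to 1,
and the *utopia hyperplane* through the normalized anchors is seeded with
evenly distributed points.  For each seed, one normalized objective is
minimized subject to the input box and to half-space constraints normal to
the utopia-plane directions, sweeping out the leading edge of the
attainable objective set.  A Pareto filter removes dominated or duplicate
outcomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model_bank import InputSpace

__all__ = [
    "ParetoPoint",
    "ParetoSet",
    "anchor_points",
    "generate_pareto_set",
    "pareto_filter",
]

logger = logging.getLogger(__name__)

DUPLICATE_TOL = 1e-6  # normalized objective space


@dataclass
class ParetoPoint:
    u: np.ndarray        # input vector
    J: np.ndarray        # raw (log-space) objective vector
    J_norm: np.ndarray   # normalized objective vector


@dataclass
class ParetoSet:
    points: list[ParetoPoint]
    anchors_u: np.ndarray    # (n_M, n_u) individual minimizers
    anchors_J: np.ndarray    # (n_M, n_M) objective vectors at the anchors
    utopia: np.ndarray       # per-objective minima
    nadir: np.ndarray        # per-objective worst anchor values

    def __len__(self):
        return len(self.points)

    def inputs(self) -> np.ndarray:
        return np.array([p.u for p in self.points])

    def objectives(self) -> np.ndarray:
        return np.array([p.J for p in self.points])

    def to_json_dict(self) -> dict:
        return {
            "inputs": [p.u.tolist() for p in self.points],
            "objectives": [p.J.tolist() for p in self.points],
            "objectives_normalized": [p.J_norm.tolist() for p in self.points],
            "anchors_u": self.anchors_u.tolist(),
            "anchors_J": self.anchors_J.tolist(),
            "utopia": self.utopia.tolist(),
            "nadir": self.nadir.tolist(),
        }


def _lattice_starts(space: InputSpace, n_starts: int = 5) -> np.ndarray:
    """Multistart seeds: box center plus corners (capped at n_starts)."""
    center = 0.5 * (space.lower + space.upper)
    corners = list(itertools.product(*zip(space.lower, space.upper)))
    starts = [center] + [np.array(c, dtype=float) for c in corners]
    return np.array(starts[:n_starts])


def _minimize_multistart(fn, space, n_starts=5, constraints=None, extra_starts=None):
    best = None
    bounds = list(zip(space.lower, space.upper))
    starts = list(_lattice_starts(space, n_starts))
    if extra_starts is not None:
        # informed starts (prescreen winner, warm start, anchors) replace
        # lattice starts so the total stays at n_starts
        informed = [np.asarray(s, dtype=float) for s in np.atleast_2d(extra_starts)]
        starts = (informed + starts)[:max(n_starts, len(informed))]
    for x0 in starts:
        if constraints:
            res = minimize(
                fn, x0, method="SLSQP", bounds=bounds, constraints=constraints,
                options={"maxiter": 40, "ftol": 1e-8},
            )
            # SLSQP frequently reports failure on piecewise-linear surfaces
            # while returning a perfectly feasible point; accept on the
            # constraint values themselves
            feasible = all(
                np.all(np.atleast_1d(c["fun"](res.x)) >= -1e-4)
                for c in constraints
            )
            if not feasible:
                continue
        else:
            res = minimize(
                fn, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200},
            )
        if best is None or res.fun < best.fun:
            best = res
    return best


def anchor_points(objectives, space: InputSpace, n_starts: int = 5):
    """Individual minimizers of each objective plus utopia/nadir scaling.

    Returns ``(anchors_u, anchors_J, utopia, nadir)`` where the
    normalization maps anchor i's own objective to 0 and the worst anchor
    value of each objective to 1 (degenerate ranges fall back to unit
    scale).
    """
    n_M = len(objectives)
    anchors_u = []
    for fn in objectives:
        res = _minimize_multistart(lambda u, f=fn: float(f(u)), space, n_starts)
        if res is None:
            raise RuntimeError("anchor optimization failed at every start")
        anchors_u.append(space.clip(res.x))
    anchors_u = np.array(anchors_u)
    anchors_J = np.array(
        [[float(f(u)) for f in objectives] for u in anchors_u]
    )
    utopia = anchors_J.min(axis=0)
    nadir = anchors_J.max(axis=0)
    return anchors_u, anchors_J, utopia, nadir


def _normalizer(utopia, nadir):
    denom = np.where(nadir - utopia > 1e-12, nadir - utopia, 1.0)

    def norm(J):
        return (np.asarray(J, dtype=float) - utopia) / denom

    return norm


def _utopia_plane_points(n_M: int, n_points: int) -> np.ndarray:
    """Evenly distributed convex-combination weights on the utopia plane."""
    if n_M == 1:
        return np.ones((1, 1))
    if n_M == 2:
        a = np.linspace(0.0, 1.0, n_points)
        return np.column_stack([1.0 - a, a])
    # simplex lattice with at least n_points members
    res = n_M - 1
    while True:
        combos = [
            np.array(c) / res
            for c in itertools.product(range(res + 1), repeat=n_M)
            if sum(c) == res
        ]
        if len(combos) >= n_points:
            return np.array(combos[:n_points])
        res += 1


def pareto_filter(points: list[ParetoPoint], tol: float = DUPLICATE_TOL):
    """Remove dominated and duplicate points; stable order.

    A point dominates another if it is no worse in every objective and
    strictly better in at least one.
    """
    kept: list[ParetoPoint] = []
    for p in points:
        dominated = False
        duplicate = False
        for q in points:
            if q is p:
                continue
            if np.all(q.J <= p.J) and np.any(q.J < p.J):
                dominated = True
                break
        if not dominated:
            for q in kept:
                if np.max(np.abs(q.J_norm - p.J_norm)) <= tol:
                    duplicate = True
                    break
        if not dominated and not duplicate:
            kept.append(p)
    return kept


def generate_pareto_set(
    objectives,
    space: InputSpace,
    n_points: int = 15,
    n_starts: int = 5,
) -> ParetoSet:
    """Run the NNC sweep and return the filtered Pareto set.

    ``objectives`` are scalar callables on the input space (typically
    sparse-grid surrogates of the per-model tracking objectives).
    Infeasible subproblems are skipped with a log entry; if every
    subproblem fails an error is raised.
    """
    n_M = len(objectives)
    if n_points < n_M:
        raise ValueError("n_points must be at least the number of objectives")
    anchors_u, anchors_J, utopia, nadir = anchor_points(objectives, space, n_starts)
    norm = _normalizer(utopia, nadir)
    anchors_N = np.array([norm(J) for J in anchors_J])

    candidates: list[ParetoPoint] = []
    for u, J in zip(anchors_u, anchors_J):
        candidates.append(ParetoPoint(u=u, J=J, J_norm=norm(J)))

    if n_M == 1:
        return ParetoSet(
            points=pareto_filter(candidates), anchors_u=anchors_u,
            anchors_J=anchors_J, utopia=utopia, nadir=nadir,
        )

    # utopia-plane directions toward the last anchor
    normals = [anchors_N[-1] - anchors_N[j] for j in range(n_M - 1)]
    last = objectives[-1]

    denom_last = max(nadir[-1] - utopia[-1], 1e-12)

    def scalar_obj(u):
        return float(last(u) - utopia[-1]) / denom_last

    # cheap prescreen start: the feasible-leaning lattice point with the
    # best scalarized objective helps SLSQP on kinked surrogate surfaces
    screen = space.lattice(7)
    screen_last = np.array([scalar_obj(u) for u in screen])

    n_failed = 0
    prev_solution = None
    for wt in _utopia_plane_points(n_M, n_points):
        X_p = wt @ anchors_N

        def make_con(Nj):
            def con(u):
                Jn = norm(np.array([float(f(u)) for f in objectives]))
                return -float(Nj @ (Jn - X_p))  # >= 0 feasible

            return con

        constraints = [
            {"type": "ineq", "fun": make_con(Nj)} for Nj in normals
        ]
        feas = np.array(
            [all(c["fun"](u) >= 0 for c in constraints) for u in screen]
        )
        if feas.any():
            masked = np.where(feas, screen_last, np.inf)
            extra = [screen[int(np.argmin(masked))]]
        else:
            extra = [screen[int(np.argmin(screen_last))]]
        # warm starts: the previous front point and the anchors (standard
        # practice when sweeping the utopia plane)
        if prev_solution is not None:
            extra.append(prev_solution)
        extra.extend(anchors_u)
        res = _minimize_multistart(
            scalar_obj, space, n_starts, constraints, extra_starts=extra
        )
        if res is None:
            n_failed += 1
            logger.info("NNC subproblem infeasible at plane point %s", X_p)
            continue
        u = space.clip(res.x)
        prev_solution = u
        J = np.array([float(f(u)) for f in objectives])
        candidates.append(ParetoPoint(u=u, J=J, J_norm=norm(J)))
    if n_failed == n_points:
        # fully degenerate front (near-identical objectives): the anchors
        # are the Pareto set
        logger.warning(
            "all NNC subproblems infeasible; returning anchor points only"
        )

    return ParetoSet(
        points=pareto_filter(candidates),
        anchors_u=anchors_u,
        anchors_J=anchors_J,
        utopia=utopia,
        nadir=nadir,
    )
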