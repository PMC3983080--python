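"""Control-input selection from the Pareto set with weight adaptation.

The interval's input is chosen by ranking Pareto points with the weighted
score ``omega' J`` (weights = Akaike weights, J = per-model log-space
objectives).  Because the weights themselves depend on the proposed input
(the weight map is queried *at* the candidate dose), selection iterates:
rank -> recalibrate weights at the winner -> rank again, until neither the
weights nor the input move beyond tolerance.  A revisited input indicates a
limit cycle; the cycle's weight vectors are averaged and the ranking is
recomputed once as a tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pareto_nnc import ParetoSet

__all__ = ["SelectionTrace", "rank_solutions", "adapt_and_select"]


@dataclass
class SelectionTrace:
    iterations: list = field(default_factory=list)  # (u, weights, winner_idx)
    terminated_by: str = ""  # 'converged' | 'limit_cycle' | 'max_iter'
    final_u: np.ndarray | None = None
    final_weights: np.ndarray | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_json_dict(self) -> dict:
        return {
            "iterations": [
                {"u": np.asarray(u).tolist(), "weights": np.asarray(w).tolist(),
                 "winner": int(i)}
                for u, w, i in self.iterations
            ],
            "terminated_by": self.terminated_by,
            "final_u": self.final_u.tolist(),
            "final_weights": self.final_weights.tolist(),
        }


def rank_solutions(pareto: ParetoSet, weights) -> tuple[int, np.ndarray]:
    """Index and input of the Pareto point minimizing ``weights' J``.

    Ties are broken deterministically by lexicographic input order.
    """
    if len(pareto) == 0:
        raise ValueError("cannot rank an empty Pareto set")
    w = np.asarray(weights, dtype=float)
    J = pareto.objectives()
    if w.size != J.shape[1]:
        raise ValueError("weight vector does not match objective dimension")
    scores = J @ w
    tied = np.flatnonzero(scores <= scores.min() + 1e-12)
    if tied.size > 1:
        tied_inputs = np.array([pareto.points[i].u for i in tied])
        # lexicographic order on the input vector
        best_idx = int(tied[np.lexsort(tied_inputs.T[::-1])[0]])
    else:
        best_idx = int(tied[0])
    return best_idx, pareto.points[best_idx].u


def _weights_at(wmap, u, window):
    if callable(wmap):
        return np.asarray(wmap(u), dtype=float)
    return np.asarray(wmap.weights_at(u, window), dtype=float)


def adapt_and_select(
    pareto: ParetoSet,
    wmap,
    w0,
    tol_w: float = 1e-3,
    tol_u: np.ndarray | float | None = None,
    max_iter: int = 10,
    window: tuple[float, float] | None = None,
) -> SelectionTrace:
    """Iterate Akaike-weighted ranking and weight recalibration.

    ``wmap`` is a weight map (``weights_at(u, window)``) or any callable
    ``u -> weights``.  ``w0`` seeds the first ranking (at the first control
    interval: weights from the entire training set).  ``tol_u`` defaults to
    1/100 of the spread of the Pareto inputs per dimension.  Deterministic:
    identical inputs produce identical traces.
    """
    if len(pareto) == 0:
        raise ValueError("empty Pareto set")
    U = pareto.inputs()
    if tol_u is None:
        spread = U.max(axis=0) - U.min(axis=0)
        tol_u = np.where(spread > 0, spread / 100.0, 1e-9)
    tol_u = np.broadcast_to(np.asarray(tol_u, dtype=float), U.shape[1])

    trace = SelectionTrace()
    w_prev = np.asarray(w0, dtype=float)
    u_prev = None
    visited: list[np.ndarray] = []

    for _ in range(max_iter):
        idx, u = rank_solutions(pareto, w_prev)
        w_new = _weights_at(wmap, u, window)
        trace.iterations.append((u.copy(), w_new.copy(), idx))

        if u_prev is not None and np.all(np.abs(u - u_prev) <= tol_u) \
                and np.max(np.abs(w_new - w_prev)) < tol_w:
            trace.terminated_by = "converged"
            trace.final_u, trace.final_weights = u, w_new
            return trace

        # limit cycle: the candidate repeats an input seen earlier (not the
        # immediately preceding one, which would be convergence in u)
        first = next(
            (i for i, v in enumerate(visited[:-1]) if np.array_equal(u, v)),
            None,
        )
        if first is not None:
            # average the weight vectors over one period of the cycle
            cycle_ws = [w for _, w, _ in trace.iterations[first:-1]]
            w_avg = np.mean(cycle_ws, axis=0)
            w_avg = w_avg / w_avg.sum()
            idx, u = rank_solutions(pareto, w_avg)
            trace.iterations.append((u.copy(), w_avg.copy(), idx))
            trace.terminated_by = "limit_cycle"
            trace.final_u, trace.final_weights = u, w_avg
            return trace

        visited.append(u.copy())
        u_prev, w_prev = u, w_new

    trace.terminated_by = "max_iter"
    trace.final_u, trace.final_weights = u_prev, w_prev
    return trace
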