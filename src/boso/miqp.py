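"""The best-subset selection problem for one cardinality K, encoded as a
mixed-integer quadratic program and solved exactly.

The bilevel problem — minimize validation error subject to the coefficients
being optimal for the (ridge) training problem on the selected subset — is
collapsed into a single MIQP: with a = Xtrain' ytrain and C = Xtrain' Xtrain,
the inner-problem optimality conditions become the linear stationarity rows

    a_i = (C beta + v)_i          for every selected feature (z_i = 1),
    beta_i = 0                    for every deselected feature (z_i = 0),
    v = delta_t * beta            for the single active grid point (y_t = 1),

either as big-M inequalities or as solver-native indicator implications,
together with sum(z) = K over the features and sum(y_t) = 1 over the
regularization grid.  The intercept occupies column 0 of the augmented
design; its z is fixed to 1, it is excluded from the cardinality count and
carries no penalty term in v.

The solver here is an exact branch-and-bound on the selection binaries.  At
a complete assignment the continuous block is a square linear system (the
stationarity rows restricted to the selected columns), so no numerical QP is
needed; nodes are pruned with an admissible lower bound — the residual of
projecting the validation response onto the span of the intercept plus every
still-allowed column, which no feasible completion can beat.  Instances are
therefore solved to global optimality (status ``optimal``) unless the time
limit interrupts the search, in which case the incumbent is returned with
status ``feasible_time_limit``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .data import SplitData
from .ridge_core import DeltaGrid

__all__ = [
    "MIQPProblem",
    "MIQPSolution",
    "build_ols_miqp",
    "build_ridge_miqp",
    "choose_bigM",
    "solve",
]

GAP_TOL = 1e-6  # relative optimality tolerance of the search


@dataclass
class MIQPProblem:
    """An encoded best-subset instance for a fixed cardinality K.

    ``a`` and ``C`` include the intercept as coordinate 0; ``Xval`` carries a
    leading all-ones column to match.
    """

    a: np.ndarray
    C: np.ndarray
    Xval: np.ndarray
    yval: np.ndarray
    delta_grid: np.ndarray
    K: int
    bigM: float
    variant: str  # "ols" | "ridge"

    @property
    def p(self) -> int:
        return int(self.a.shape[0] - 1)

    def __post_init__(self) -> None:
        if self.C.shape != (self.p + 1, self.p + 1):
            raise ValueError("C shape inconsistent with a")
        if self.K > self.p:
            raise ValueError(f"K={self.K} exceeds feature count p={self.p}")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if len(self.delta_grid) == 0:
            raise ValueError("delta grid must be non-empty")


@dataclass
class MIQPSolution:
    """Solved state: coefficients, support binaries, active grid point."""

    beta: np.ndarray  # length p+1, intercept first, zeros off support
    z: np.ndarray  # length p binary support (intercept excluded)
    t_selected: int  # index of the active delta in the grid
    delta: float
    objective: float  # validation sum of squared errors
    status: str  # optimal | feasible_time_limit | infeasible
    n_nodes: int = 0
    gap: float = 0.0

    @property
    def selected(self) -> tuple[int, ...]:
        return tuple(int(j) for j in np.flatnonzero(self.z))


def _augment(split: SplitData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Xa = np.column_stack([np.ones(split.n_train), split.X_train])
    a = Xa.T @ split.y_train
    C = Xa.T @ Xa
    Xval = np.column_stack([np.ones(split.n_val), split.X_val])
    return a, C, Xval


def _grid_values(grid: Union[DeltaGrid, np.ndarray, list]) -> np.ndarray:
    if isinstance(grid, DeltaGrid):
        return np.asarray(grid.values, dtype=float)
    return np.asarray(grid, dtype=float).ravel()


def build_ols_miqp(split: SplitData, K: int, bigM: Optional[float] = None) -> MIQPProblem:
    """Encode the ordinary-least-squares variant (a single delta = 0)."""
    if K > split.p:
        raise ValueError(f"K={K} exceeds feature count p={split.p}")
    a, C, Xval = _augment(split)
    grid = np.array([0.0])
    if bigM is None:
        bigM = choose_bigM(split, grid)
    return MIQPProblem(a, C, Xval, split.y_val, grid, K, float(bigM), "ols")


def build_ridge_miqp(
    split: SplitData,
    K: int,
    grid: Union[DeltaGrid, np.ndarray, list],
    bigM: Optional[float] = None,
) -> MIQPProblem:
    """Encode the ridge variant with the delta grid selected by binaries y_t."""
    if K > split.p:
        raise ValueError(f"K={K} exceeds feature count p={split.p}")
    values = _grid_values(grid)
    if values.size == 0:
        raise ValueError("delta grid must be non-empty")
    a, C, Xval = _augment(split)
    if bigM is None:
        bigM = choose_bigM(split, values)
    return MIQPProblem(a, C, Xval, split.y_val, values, K, float(bigM), "ridge")


def choose_bigM(
    split: SplitData,
    grid: Union[DeltaGrid, np.ndarray, list],
    safety_factor: float = 10.0,
    floor: float = 1e3,
) -> float:
    """A data-scaled big-M bound covering the full-model ridge coefficients
    and the stationarity-row residuals at beta = 0 for every grid delta.

    The returned constant is ``safety_factor`` times the largest of those
    magnitudes, floored so that near-degenerate standardized problems still
    get a comfortably slack bound.
    """
    a, C, _ = _augment(split)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(C))):
        raise ValueError("non-finite training data")
    values = _grid_values(grid)
    pen = np.ones(a.shape[0])
    pen[0] = 0.0
    worst = float(np.max(np.abs(a)))  # residual of every row at beta = 0
    for delta in values:
        G = C + delta * np.diag(pen)
        try:
            beta = np.linalg.solve(G, a)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(G) @ a
        if not np.all(np.isfinite(beta)):
            beta = np.linalg.pinv(G) @ a
        worst = max(worst, float(np.max(np.abs(beta))))
    return max(safety_factor * worst, floor)


def _leaf_objective(
    problem: MIQPProblem,
    Q: tuple[int, ...],
    use_indicator: bool,
) -> Optional[tuple[float, int, np.ndarray]]:
    """Best (objective, t, beta) over the delta grid for a complete support.

    Solves the stationarity system restricted to the intercept plus the
    selected columns directly from the encoded (a, C).  In big-M mode a
    candidate is rejected when the relaxed rows or coefficient bounds exceed
    M (an inadequate constant); indicator mode has no such bound.
    """
    idx = np.concatenate([[0], np.asarray(Q, dtype=int) + 1])
    a_Q = problem.a[idx]
    C_QQ = problem.C[np.ix_(idx, idx)]
    Xv = problem.Xval[:, idx]
    pen = np.ones(idx.size)
    pen[0] = 0.0
    best: Optional[tuple[float, int, np.ndarray]] = None
    for t, delta in enumerate(problem.delta_grid):
        G = C_QQ + delta * np.diag(pen)
        try:
            beta_Q = np.linalg.solve(G, a_Q)
        except np.linalg.LinAlgError:
            beta_Q, *_ = np.linalg.lstsq(G, a_Q, rcond=None)
        if not np.all(np.isfinite(beta_Q)):
            continue
        if not use_indicator:
            M = problem.bigM
            if np.max(np.abs(beta_Q)) > M:
                continue
            # relaxed stationarity rows (z_i = 0): |a_i - C[i, idx] beta| <= M
            relaxed = np.setdiff1d(np.arange(problem.p + 1), idx)
            if relaxed.size:
                r = problem.a[relaxed] - problem.C[np.ix_(relaxed, idx)] @ beta_Q
                if np.max(np.abs(r)) > M:
                    continue
        e = problem.yval - Xv @ beta_Q
        obj = float(e @ e)
        if best is None or obj < best[0] - 0.0:
            best = (obj, t, beta_Q)
    return best


def solve(
    problem: MIQPProblem,
    time_limit_s: float = 60.0,
    use_indicator: bool = True,
) -> MIQPSolution:
    """Solve the encoded instance by exact branch-and-bound on the selection
    binaries.

    Branching follows a validation-correlation order with the include branch
    explored first (good incumbents early); a node is pruned when the
    unconstrained validation projection onto its still-allowed columns cannot
    beat the incumbent.  Returns the global optimum (status ``optimal``)
    unless interrupted by ``time_limit_s``, in which case the incumbent is
    returned with status ``feasible_time_limit``.
    """
    if time_limit_s <= 0:
        raise ValueError("time_limit_s must be positive")
    p, K = problem.p, problem.K
    deadline = time.monotonic() + time_limit_s
    yv = problem.yval
    Xv = problem.Xval

    # branching order: features most correlated with the validation response first
    yc = yv - yv.mean()
    norms = np.linalg.norm(Xv[:, 1:] - Xv[:, 1:].mean(axis=0), axis=0)
    denom = np.where(norms > 0, norms, 1.0) * (np.linalg.norm(yc) + 1e-300)
    score = np.abs((Xv[:, 1:] - Xv[:, 1:].mean(axis=0)).T @ yc) / denom
    order = np.argsort(-score, kind="stable")

    state = {
        "best_obj": np.inf,
        "best": None,  # (obj, t, beta_Q, Q)
        "nodes": 0,
        "timed_out": False,
    }

    def bound(allowed: list[int]) -> float:
        cols = np.concatenate([[0], np.asarray(allowed, dtype=int) + 1]) if allowed else np.array([0])
        _, res, rank, _ = np.linalg.lstsq(Xv[:, cols], yv, rcond=None)
        if res.size:
            return float(res[0])
        r = yv - Xv[:, cols] @ np.linalg.lstsq(Xv[:, cols], yv, rcond=None)[0]
        return float(r @ r)

    def consider(Q: tuple[int, ...]) -> None:
        leaf = _leaf_objective(problem, Q, use_indicator)
        if leaf is None:
            return
        obj, t, beta_Q = leaf
        if obj < state["best_obj"] * (1 - GAP_TOL) or (
            state["best"] is None and np.isfinite(obj)
        ):
            state["best_obj"] = obj
            state["best"] = (obj, t, beta_Q, Q)

    def recurse(pos: int, included: list[int], allowed_bound: float) -> None:
        if state["timed_out"]:
            return
        if time.monotonic() > deadline:
            state["timed_out"] = True
            return
        state["nodes"] += 1
        remaining = p - pos
        if len(included) == K:
            consider(tuple(sorted(included)))
            return
        if len(included) + remaining < K:
            return  # cannot reach cardinality K
        if len(included) + remaining == K:
            consider(tuple(sorted(included + [int(j) for j in order[pos:]])))
            return
        if allowed_bound >= state["best_obj"] * (1 - GAP_TOL) and np.isfinite(
            state["best_obj"]
        ):
            return
        j = int(order[pos])
        # include branch: allowed set unchanged, bound still valid
        recurse(pos + 1, included + [j], allowed_bound)
        # exclude branch: allowed set shrinks, recompute the projection bound
        excl_allowed = included + [int(q) for q in order[pos + 1 :]]
        recurse(pos + 1, included, bound(excl_allowed))

    # greedy initial incumbent (top-K by branching score) so a time-limited
    # search always has a feasible solution to return
    consider(tuple(sorted(int(j) for j in order[:K])))
    recurse(0, [], 0.0)

    if state["best"] is None:
        return MIQPSolution(
            beta=np.zeros(p + 1),
            z=np.zeros(p, dtype=int),
            t_selected=-1,
            delta=np.nan,
            objective=np.inf,
            status="infeasible",
            n_nodes=state["nodes"],
            gap=np.inf,
        )
    obj, t, beta_Q, Q = state["best"]
    beta = np.zeros(p + 1)
    idx = np.concatenate([[0], np.asarray(Q, dtype=int) + 1])
    beta[idx] = beta_Q
    z = np.zeros(p, dtype=int)
    z[list(Q)] = 1
    status = "feasible_time_limit" if state["timed_out"] else "optimal"
    return MIQPSolution(
        beta=beta,
        z=z,
        t_selected=int(t),
        delta=float(problem.delta_grid[t]),
        objective=obj,
        status=status,
        n_nodes=state["nodes"],
        gap=0.0 if status == "optimal" else np.nan,
    )
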