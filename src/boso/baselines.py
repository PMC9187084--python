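"""Comparator selectors — forward stepwise, lasso, relaxed lasso — and the
exhaustive best-subset enumerator used as the solver's independent oracle.

Every comparator is tuned on validation sum of squared errors (the same data
the bilevel method uses for subset selection), not cross-validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from sklearn.linear_model import lasso_path

from .data import SplitData
from .ridge_core import DeltaGrid, ridge_fit

__all__ = [
    "BaselineFit",
    "forward_stepwise",
    "lasso_path_select",
    "relaxed_lasso_select",
    "brute_force_best_subset",
]


@dataclass
class BaselineFit:
    method: str
    selected: tuple[int, ...]
    beta: np.ndarray  # intercept first, then one coefficient per feature
    tuning: dict = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def coef(self) -> np.ndarray:
        return self.beta[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def _ols_on_subset(X: np.ndarray, y: np.ndarray, cols: list[int]) -> np.ndarray:
    """Least-squares fit with intercept on the given columns; returns the
    full-length coefficient vector (intercept first)."""
    n, p = X.shape
    D = np.column_stack([np.ones(n), X[:, cols]]) if cols else np.ones((n, 1))
    b, *_ = np.linalg.lstsq(D, y, rcond=None)
    beta = np.zeros(p + 1)
    beta[0] = b[0]
    if cols:
        beta[np.asarray(cols) + 1] = b[1:]
    return beta


def _val_sse(split: SplitData, beta: np.ndarray) -> float:
    r = split.y_val - (beta[0] + split.X_val @ beta[1:])
    return float(r @ r)


def forward_stepwise(split: SplitData, max_steps: Optional[int] = None) -> BaselineFit:
    """Greedy path adding at each step the feature that most reduces the
    training RSS; the path size is chosen by minimum validation SSE."""
    p = split.p
    if max_steps is None:
        max_steps = min(p, split.n_train - 1)
    if max_steps > p:
        raise ValueError("max_steps cannot exceed the feature count")
    X, y = split.X_train, split.y_train
    active: list[int] = []
    path: list[list[int]] = [[]]
    for _ in range(max_steps):
        best_rss, best_j = np.inf, None
        for j in range(p):
            if j in active:
                continue
            beta = _ols_on_subset(X, y, active + [j])
            r = y - (beta[0] + X @ beta[1:])
            rss = float(r @ r)
            if rss < best_rss - 1e-12:
                best_rss, best_j = rss, j
        if best_j is None:
            break
        active.append(best_j)
        path.append(list(active))
    best = (np.inf, _ols_on_subset(X, y, []), [])
    for cols in path:
        beta = _ols_on_subset(X, y, cols)
        sse = _val_sse(split, beta)
        if sse < best[0]:
            best = (sse, beta, cols)
    return BaselineFit(
        method="forward_stepwise",
        selected=tuple(sorted(best[2])),
        beta=best[1],
        tuning={"val_sse": best[0], "steps": len(best[2]), "path": active},
    )


def _lasso_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    n = X.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    lam_max = np.max(np.abs(Xc.T @ yc)) / n
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def _lasso_coefs(split: SplitData, n_lambda: int) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent lasso path on training data: (alphas, coefs[p, m])."""
    X, y = split.X_train, split.y_train
    alphas = _lasso_lambda_grid(X, y, n_lambda)
    # coordinate descent solves the no-intercept problem: center first and
    # recover the intercept as ybar - xbar . w afterwards
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alphas_out, coefs, _ = lasso_path(Xc, yc, alphas=alphas)
    return alphas_out, coefs


def lasso_path_select(split: SplitData, n_lambda: int = 100) -> BaselineFit:
    """Lasso with the penalty chosen by minimum validation SSE over the path."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    X, y = split.X_train, split.y_train
    alphas, coefs = _lasso_coefs(split, n_lambda)
    best = None
    for i, lam in enumerate(alphas):
        c = coefs[:, i]
        b0 = float(y.mean() - X.mean(axis=0) @ c)
        beta = np.concatenate([[b0], c])
        sse = _val_sse(split, beta)
        if best is None or sse < best[0]:
            best = (sse, beta, float(lam))
    sse, beta, lam = best
    return BaselineFit(
        method="lasso",
        selected=tuple(np.flatnonzero(beta[1:]).tolist()),
        beta=beta,
        tuning={"lambda": lam, "val_sse": sse},
    )


def relaxed_lasso_select(
    split: SplitData, n_lambda: int = 50, n_gamma: int = 11
) -> BaselineFit:
    """Relaxed lasso: for each lasso support, blend the lasso coefficients
    with the least-squares refit on that support,
    beta(gamma) = gamma * beta_lasso + (1 - gamma) * beta_LS, choosing
    (lambda, gamma) by minimum validation SSE.  gamma = 1 recovers the plain
    lasso, so the tuned blend is never worse on validation."""
    if n_gamma < 2:
        raise ValueError("n_gamma must be at least 2")
    X, y = split.X_train, split.y_train
    alphas, coefs = _lasso_coefs(split, n_lambda)
    gammas = np.linspace(0.0, 1.0, n_gamma)
    xbar = X.mean(axis=0)
    ybar = float(y.mean())
    best = None
    for i, lam in enumerate(alphas):
        c = coefs[:, i]
        support = np.flatnonzero(c).tolist()
        b_lasso = np.concatenate([[ybar - xbar @ c], c])
        if support and len(support) < split.n_train:
            try:
                b_ls = _ols_on_subset(X, y, support)
            except np.linalg.LinAlgError:
                b_ls = b_lasso
        else:
            b_ls = b_lasso if support else np.concatenate([[ybar], np.zeros(split.p)])
        for g in gammas:
            beta = g * b_lasso + (1 - g) * b_ls
            sse = _val_sse(split, beta)
            if best is None or sse < best[0]:
                best = (sse, beta, float(lam), float(g))
    sse, beta, lam, gamma = best
    return BaselineFit(
        method="relaxed_lasso",
        selected=tuple(np.flatnonzero(beta[1:]).tolist()),
        beta=beta,
        tuning={"lambda": lam, "gamma": gamma, "val_sse": sse},
    )


def brute_force_best_subset(
    split: SplitData,
    K: int,
    grid: Union[DeltaGrid, np.ndarray, list],
) -> BaselineFit:
    """Exhaustively enumerate all size-K subsets crossed with the delta grid,
    fitting ridge on training data and scoring SSE on validation; the global
    argmin is returned (ties broken towards the lexicographically smallest
    index set, then the smallest delta).

    This enumerator deliberately routes through :func:`ridge_fit` — a code
    path independent of the MIQP solver — so the two can validate each other.
    """
    p = split.p
    if K > p:
        raise ValueError("K cannot exceed the feature count")
    values = grid.values if isinstance(grid, DeltaGrid) else np.asarray(grid, float).ravel()
    n_comb = math.comb(p, K)
    if n_comb * len(values) > 1_000_000:
        raise ValueError(
            "enumeration too large (C(p,K)*m > 1e6); use the MIQP solver"
        )
    best = None
    for Q in itertools.combinations(range(p), K):
        for delta in values:
            try:
                fit = ridge_fit(split.X_train[:, list(Q)], split.y_train,
                                float(delta), subset=Q)
            except np.linalg.LinAlgError:
                continue
            r = split.y_val - fit.predict(split.X_val[:, list(Q)])
            sse = float(r @ r)
            if best is None or sse < best[0] * (1 - 1e-12):
                best = (sse, Q, float(delta), fit)
    if best is None:
        raise np.linalg.LinAlgError("every subset was singular at delta = 0")
    sse, Q, delta, fit = best
    beta = np.zeros(p + 1)
    beta[0] = fit.intercept
    beta[np.asarray(Q, dtype=int) + 1] = fit.coef
    return BaselineFit(
        method="brute_force",
        selected=tuple(Q),
        beta=beta,
        tuning={"delta": delta, "objective": sse},
    )
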