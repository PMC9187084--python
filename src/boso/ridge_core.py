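"""Closed-form ridge/OLS fitting on a fixed feature subset, the regularization
grid, and the ridge-adjusted information criteria that drive the stopping rule.

The ridge estimator solves the stationarity system

    X'y = (X'X + delta * I*) beta

where ``I*`` is the identity with a zero in the intercept position: the
intercept is never penalized and never counted towards model size.  Model
complexity is measured by the effective degrees of freedom of the ridge hat
matrix, df(delta) = trace(X (X'X + delta I)^-1 X') = sum_i d_i^2/(d_i^2+delta)
over the singular values d_i of the subset design, which reduces to the number
of selected features K at delta = 0.  The information criteria replace K by
df(delta); the extended BIC adds a model-space penalty 2 g log C(p, K_eff)
with K_eff = ceil(df) and g = 0.5 when p > n (0 otherwise, where it coincides
with BIC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DeltaGrid",
    "RidgeFitResult",
    "ridge_fit",
    "df_ridge",
    "k_eff",
    "information_criterion",
    "make_delta_grid",
]

_CRITERIA = ("aic", "bic", "ebic")


@dataclass(frozen=True)
class DeltaGrid:
    """A strictly increasing grid of positive ridge penalties."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ValueError("delta grid must be non-empty")
        if np.any(v <= 0):
            raise ValueError("delta grid values must be positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("delta grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return self.m


@dataclass
class RidgeFitResult:
    """A fitted ridge (or OLS) model on a fixed subset.

    ``beta`` carries the intercept first, followed by one coefficient per
    column of the design the model was fitted on.
    """

    beta: np.ndarray
    delta: float
    mse: float
    df: float
    subset: Optional[tuple[int, ...]] = None

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def coef(self) -> np.ndarray:
        return self.beta[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    delta: float,
    fit_intercept: bool = True,
    subset: Optional[Sequence[int]] = None,
) -> RidgeFitResult:
    """Fit ridge regression (OLS when ``delta`` is 0) with an unpenalized
    intercept.

    Parameters
    ----------
    X : (n, K) array
        Design restricted to the selected features (may have zero columns for
        an intercept-only model).
    y : (n,) array
        Response.
    delta : float
        Non-negative l2 penalty on the slope coefficients.
    fit_intercept : bool
        Prepend an all-ones column; the intercept coordinate is unpenalized.
    subset : optional
        Feature indices the columns of ``X`` correspond to, recorded verbatim.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``delta`` is 0 and the (intercept-augmented) design is
        rank-deficient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    n, K = X.shape
    if fit_intercept:
        D = np.column_stack([np.ones(n), X])
        pen = np.ones(K + 1)
        pen[0] = 0.0
    else:
        D = X
        pen = np.ones(K)
    G = D.T @ D + delta * np.diag(pen)
    if delta == 0.0 and np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design with delta = 0")
    beta = np.linalg.solve(G, D.T @ y)
    resid = y - D @ beta
    mse = float(resid @ resid / n)
    df = df_ridge(X, delta) if K >= 1 else 0.0
    if not fit_intercept:
        beta = np.concatenate([[0.0], beta])
    return RidgeFitResult(
        beta=beta,
        delta=float(delta),
        mse=mse,
        df=df,
        subset=tuple(subset) if subset is not None else None,
    )


def df_ridge(X_Q: np.ndarray, delta: float) -> float:
    """Effective degrees of freedom of the ridge hat matrix,
    trace(X (X'X + delta I)^-1 X') = sum d_i^2 / (d_i^2 + delta).

    At ``delta = 0`` this is the rank of ``X_Q`` (the number of effective
    parameters is precisely K for a full-rank subset design).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    X_Q = np.atleast_2d(np.asarray(X_Q, dtype=float))
    if X_Q.shape[1] < 1:
        return 0.0
    d = np.linalg.svd(X_Q, compute_uv=False)
    d2 = d**2
    if delta == 0.0:
        tol = d2.max(initial=0.0) * max(X_Q.shape) * np.finfo(float).eps
        return float(np.count_nonzero(d2 > tol))
    return float(np.sum(d2 / (d2 + delta)))


def k_eff(df: float) -> int:
    """Effective (integer) model size: df rounded up to the nearest integer."""
    if df < 0:
        raise ValueError("df must be non-negative")
    # tolerate float noise just above an integer
    return int(math.ceil(df - 1e-9))


def _log_binom(p: int, k: int) -> float:
    """log C(p, k) via log-gamma; stable for p in the thousands."""
    if k < 0 or k > p:
        raise ValueError("k outside [0, p]")
    return float(gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1))


def information_criterion(
    mse: float,
    n: int,
    K: int,
    df: float,
    p: int,
    criterion: str = "ebic",
) -> float:
    """AIC / BIC / extended-BIC value for a fitted subset model.

    eBIC = n log(MSE) + df log(n) + 2 g log C(p, K_eff), with the consistency
    parameter g = 0.5 when p > n and 0 otherwise (equivalent to BIC); AIC
    replaces log(n) by 2 and drops the model-space term.
    """
    criterion = criterion.lower()
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    if mse <= 0:
        raise ValueError("mse must be positive (log undefined otherwise)")
    if n < 1:
        raise ValueError("n must be at least 1")
    if K < 0 or p < K:
        raise ValueError("need 0 <= K <= p")
    base = n * math.log(mse)
    if criterion == "aic":
        return base + 2.0 * df
    value = base + df * math.log(n)
    if criterion == "ebic":
        g = 0.5 if p > n else 0.0
        if g > 0:
            ke = k_eff(df) if df > 0 else 0
            ke = min(ke, p)
            value += 2.0 * g * _log_binom(p, ke)
    return value


def make_delta_grid(X: np.ndarray, y: np.ndarray, m: int) -> DeltaGrid:
    """Log-equally-spaced ridge penalties spanning the lasso/ridge lambda
    range of the standardized problem.

    On column-standardized X and centered y the largest useful lasso penalty
    is lambda_max = max_j |x_j' y| / n; the grid runs from
    1e-4 * lambda_max * n up to lambda_max * n / 1e-3 (the conventional
    inflation of the lasso lambda_max for a pure-l2 path), which is
    homogeneous of degree 1 in y.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    yc = y - y.mean()
    if not np.any(yc):
        raise ValueError("response is constant; no usable penalty range")
    sd = X.std(axis=0, ddof=0)
    mu = X.mean(axis=0)
    ok = sd > 0
    if not np.any(ok):
        raise ValueError("X has no non-constant column")
    Xs = (X[:, ok] - mu[ok]) / sd[ok]
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if lam_max <= 0:
        raise ValueError("response is orthogonal to every feature")
    d_min = 1e-4 * lam_max * n
    d_max = lam_max * n / 1e-3
    if m == 1:
        return DeltaGrid(np.array([d_min]))
    return DeltaGrid(np.geomspace(d_min, d_max, m))
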