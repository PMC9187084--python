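"""Synthetic regression problems with AR(1)-correlated Gaussian predictors
and sparse coefficient patterns, plus support-recovery metrics.

Rows of X are i.i.d. N(0, Sigma) with Sigma_ij = rho^|i-j|; the response is
y = X beta + eps with eps ~ N(0, sigma^2) and the noise variance calibrated
analytically to a target signal-to-noise ratio: sigma^2 = beta' Sigma beta / SNR.
The coefficient patterns ("beta-types") follow the standard sparse-regression
benchmark conventions:

* type 1 — s ones at approximately equally-spaced indices,
* type 2 — s ones in the first s positions (adjacent, hence correlated
  under AR(1)),
* type 3 — s non-zeros at equally-spaced indices with values decaying
  linearly from 10 to 0.5,
* type 5 — first s entries equal to 1, the tail decaying as 0.5^(j-s).

Four problem-size presets are provided: low (n=100, p=10, s=5), medium
(n=500, p=100, s=5), high5 (n=50, p=1000, s=5) and high10 (n=100, p=1000,
s=10), with ten SNR levels from 0.05 to 6.00 equally spaced on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "SimulationSpec",
    "SimulationData",
    "SelectionMetrics",
    "SETTINGS",
    "make_setting",
    "snr_grid",
    "make_beta",
    "ar1_covariance",
    "simulate",
    "score_selection",
]

SETTINGS = {
    "low": (100, 10, 5),
    "medium": (500, 100, 5),
    "high5": (50, 1000, 5),
    "high10": (100, 1000, 10),
}

BETA_TYPES = (1, 2, 3, 5)


@dataclass(frozen=True)
class SimulationSpec:
    n: int
    p: int
    s: int
    beta_type: int = 1
    rho: float = 0.35
    snr: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.s > self.p:
            raise ValueError("true-support size s cannot exceed p")
        if self.n < 2:
            raise ValueError("need at least 2 instances")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.beta_type not in BETA_TYPES:
            raise ValueError(f"beta_type must be one of {BETA_TYPES}")


@dataclass
class SimulationData:
    X: np.ndarray
    y: np.ndarray
    beta_true: np.ndarray
    sigma2: float
    Sigma: np.ndarray
    spec: SimulationSpec


@dataclass
class SelectionMetrics:
    f1: float
    precision: float
    recall: float
    fp: int
    fn: int
    nonzeros: int
    rte: float


def make_setting(
    name: str,
    beta_type: int = 1,
    rho: float = 0.35,
    snr: float = 1.0,
    seed: int = 1,
) -> SimulationSpec:
    """Build a spec from one of the named (n, p, s) presets."""
    key = name.lower()
    if key not in SETTINGS:
        raise ValueError(
            f"unknown setting {name!r}; valid presets: {sorted(SETTINGS)}"
        )
    n, p, s = SETTINGS[key]
    return SimulationSpec(n=n, p=p, s=s, beta_type=beta_type, rho=rho,
                          snr=snr, seed=seed)


def snr_grid() -> np.ndarray:
    """Ten signal-to-noise levels from 0.05 to 6.00, log-equally spaced."""
    return np.geomspace(0.05, 6.00, 10)


def make_beta(p: int, s: int, beta_type: int = 1) -> np.ndarray:
    """The true coefficient vector for a given sparsity pattern."""
    if s > p:
        raise ValueError("s cannot exceed p")
    if beta_type not in BETA_TYPES:
        raise ValueError(f"beta_type must be one of {BETA_TYPES}")
    beta = np.zeros(p)
    if beta_type in (1, 3):
        idx = _spaced_indices(p, s)
        beta[idx] = 1.0 if beta_type == 1 else np.linspace(10.0, 0.5, s)
    elif beta_type == 2:
        beta[:s] = 1.0
    else:  # type 5
        beta[:s] = 1.0
        tail = np.arange(s + 1, p + 1)
        beta[s:] = 0.5 ** (tail - s)
    return beta


def _spaced_indices(p: int, s: int) -> np.ndarray:
    """Approximately equally-spaced 0-based indices, deduplicated by shifting
    colliding indices right (deterministic)."""
    if s == 1:
        return np.array([0])
    raw = np.rint(1 + (np.arange(1, s + 1) - 1) * (p - 1) / (s - 1)).astype(int)
    used: list[int] = []
    for i in raw:
        while i in used:
            i += 1
        if i > p:  # ran off the right edge: take the smallest free slot
            i = next(j for j in range(1, p + 1) if j not in used)
        used.append(i)
    return np.asarray(used) - 1


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """The AR(1) covariance Sigma_ij = rho^|i-j| (symmetric PD for rho in [0,1))."""
    return toeplitz(rho ** np.arange(p))


def simulate(spec: SimulationSpec) -> SimulationData:
    """Draw one dataset; deterministic given the spec's seed.

    Noise variance satisfies beta' Sigma beta / sigma^2 = snr exactly.
    """
    rng = np.random.default_rng(spec.seed)
    Sigma = ar1_covariance(spec.p, spec.rho)
    beta = make_beta(spec.p, spec.s, spec.beta_type)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((spec.n, spec.p)) @ L.T
    signal = float(beta @ Sigma @ beta)
    if signal <= 0:
        raise ValueError("true coefficient vector carries no signal")
    sigma2 = signal / spec.snr
    y = X @ beta + rng.standard_normal(spec.n) * np.sqrt(sigma2)
    return SimulationData(X=X, y=y, beta_true=beta, sigma2=sigma2,
                          Sigma=Sigma, spec=spec)


def score_selection(
    selected: Iterable[int],
    beta_hat: Sequence[float],
    data: SimulationData,
) -> SelectionMetrics:
    """Support-recovery metrics and relative test error of a fitted model
    against the generator's ground truth (intercept excluded).

    rte = ((beta_hat - beta)' Sigma (beta_hat - beta) + sigma^2) / sigma^2,
    which equals 1 for exact recovery and SNR + 1 for the null model.
    """
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    p = data.beta_true.size
    if beta_hat.size != p:
        raise ValueError("beta_hat must have length p (intercept excluded)")
    sel = set(int(j) for j in selected)
    if sel and (min(sel) < 0 or max(sel) >= p):
        raise ValueError("selected indices outside 0..p-1")
    true = set(np.flatnonzero(data.beta_true).tolist())
    tp = len(sel & true)
    fp = len(sel - true)
    fn = len(true - sel)
    precision = tp / len(sel) if sel else 0.0
    recall = tp / len(true) if true else 0.0
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom > 0 else 0.0
    d = beta_hat - data.beta_true
    rte = float((d @ data.Sigma @ d + data.sigma2) / data.sigma2)
    return SelectionMetrics(
        f1=f1,
        precision=precision,
        recall=recall,
        fp=fp,
        fn=fn,
        nonzeros=len(sel),
        rte=rte,
    )
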