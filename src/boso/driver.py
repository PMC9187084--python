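"""The full selection algorithm: a cardinality sweep with information-
criterion stopping, wrapped in a two-stage random-block decomposition so the
exact subset search stays tractable when p is large.

For each candidate cardinality K the MIQP picks the subset (and ridge penalty
delta) minimizing validation error; the criterion (AIC/BIC/eBIC) is then
evaluated on a ridge refit using BOTH training and validation rows, and the
sweep stops once the criterion stops improving.  For large p, features are
shuffled into random blocks of length L, the sweep is run inside each block,
survivors are pooled and re-blocked until the survivor set stabilizes, and a
final sweep over the survivors produces the model.  With eBIC the block phase
runs twice: a first pass under the less restrictive BIC with a coarse delta
grid, then a second pass on its survivors under eBIC with a finer grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data import SplitData, train_val_split
from .miqp import build_ridge_miqp, choose_bigM, solve
from .ridge_core import (
    DeltaGrid,
    information_criterion,
    make_delta_grid,
    ridge_fit,
)

__all__ = [
    "BosoConfig",
    "BosoFit",
    "BlockStageResult",
    "k_sweep",
    "random_blocks",
    "block_stage",
    "boso",
]


@dataclass
class BosoConfig:
    """Tunable parameters of the selection algorithm.

    Defaults follow the reference protocol: blocks of L = 10 features, a
    10-point delta grid in the first (BIC) stage, a finer second-stage grid
    (50 points when at most 100 survivors remain, 100 otherwise), a 60-second
    cap per MIQP solve, and eBIC as the stopping criterion.
    """

    criterion: str = "ebic"
    block_size: int = 10
    m_stage1: int = 10
    m_stage2: Optional[int] = None  # None: 50 if <=100 survivors else 100
    time_limit_s: float = 60.0
    seed: int = 0
    max_block_iters: int = 20
    standardize: bool = True
    stop_patience: int = 1
    use_indicator: bool = True
    bigM: Optional[float] = None

    def __post_init__(self) -> None:
        self.criterion = self.criterion.lower()
        if self.criterion not in ("aic", "bic", "ebic"):
            raise ValueError("criterion must be aic, bic or ebic")
        if self.block_size < 2:
            raise ValueError("block_size must be at least 2")
        if self.m_stage1 < 1:
            raise ValueError("m_stage1 must be at least 1")
        if self.time_limit_s <= 0:
            raise ValueError("time_limit_s must be positive")
        if self.stop_patience < 1:
            raise ValueError("stop_patience must be at least 1")


@dataclass
class BosoFit:
    """The selected model: support, coefficients and the criterion trail."""

    selected: tuple[int, ...]
    beta: np.ndarray  # intercept first, then one coefficient per feature (p+1)
    delta: float
    K: int
    criterion: str
    ic_value: float
    ic_trajectory: list[tuple[int, float]]
    stage_log: list[dict] = field(default_factory=list)
    feature_ids: Optional[list[str]] = None

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def coef(self) -> np.ndarray:
        return self.beta[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


@dataclass
class BlockStageResult:
    """Outcome of one random-block phase."""

    selected: tuple[int, ...]
    fit: BosoFit
    n_iters: int
    converged: bool
    log: list[dict] = field(default_factory=list)


def _intercept_only_fit(split: SplitData, criterion: str, p_total: int) -> BosoFit:
    X_all, y_all = split.concat_train_val()
    n = y_all.size
    mu = float(y_all.mean())
    mse = float(np.mean((y_all - mu) ** 2))
    ic = information_criterion(mse, n, 0, 0.0, p_total, criterion) if mse > 0 else -np.inf
    beta = np.zeros(split.p + 1)
    beta[0] = mu
    return BosoFit(
        selected=(),
        beta=beta,
        delta=0.0,
        K=0,
        criterion=criterion,
        ic_value=ic,
        ic_trajectory=[(0, ic)],
    )


def k_sweep(
    split: SplitData,
    grid: Union[DeltaGrid, np.ndarray],
    config: BosoConfig,
    criterion: Optional[str] = None,
    p_total: Optional[int] = None,
) -> BosoFit:
    """Sweep K = 0, 1, 2, ... solving the MIQP at each cardinality and stop
    once the information criterion fails to improve for ``stop_patience``
    consecutive K values; return the argmin-K model.

    The criterion is evaluated on a ridge refit of the MIQP-selected
    (subset, delta) using the concatenated training + validation rows;
    ``p_total`` is the model-space size used by eBIC (the full feature count
    when sweeping inside a block).
    """
    criterion = (criterion or config.criterion).lower()
    p = split.p
    p_total = p if p_total is None else max(p_total, p)
    X_all, y_all = split.concat_train_val()
    n_all = y_all.size
    bigM = config.bigM
    if bigM is None:
        bigM = choose_bigM(split, grid)

    base = _intercept_only_fit(split, criterion, p_total)
    trajectory = list(base.ic_trajectory)
    log: list[dict] = []
    best = (base.ic_value, base)
    worse_streak = 0

    k_max = min(p, max(split.n_train - 1, 1))
    for K in range(1, k_max + 1):
        problem = build_ridge_miqp(split, K, grid, bigM=bigM)
        sol = solve(problem, time_limit_s=config.time_limit_s,
                    use_indicator=config.use_indicator)
        if sol.status == "infeasible":
            raise RuntimeError(f"MIQP infeasible at K={K}: formulation bug")
        Q = list(sol.selected)
        refit = ridge_fit(X_all[:, Q], y_all, sol.delta, subset=Q)
        if refit.mse <= 0:
            ic = -np.inf  # perfect interpolation: cannot be improved upon
        else:
            ic = information_criterion(refit.mse, n_all, K, refit.df, p_total,
                                       criterion)
        beta = np.zeros(p + 1)
        beta[0] = refit.intercept
        beta[np.asarray(Q, dtype=int) + 1] = refit.coef
        fit = BosoFit(
            selected=tuple(Q),
            beta=beta,
            delta=float(sol.delta),
            K=K,
            criterion=criterion,
            ic_value=ic,
            ic_trajectory=[],
        )
        trajectory.append((K, ic))
        log.append({
            "K": K,
            "criterion_value": ic,
            "objective": sol.objective,
            "status": sol.status,
            "gap": sol.gap,
            "selected": tuple(Q),
            "delta": float(sol.delta),
        })
        if ic < best[0]:
            best = (ic, fit)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= config.stop_patience:
                break
        if not math.isfinite(ic) and ic < 0:
            break  # interpolating fit; larger K cannot improve

    result = best[1]
    result.ic_trajectory = trajectory
    result.stage_log = log
    if split.feature_ids is not None:
        result.feature_ids = [split.feature_ids[j] for j in result.selected]
    return result


def random_blocks(
    features: Sequence[int], L: int, rng: np.random.Generator
) -> list[list[int]]:
    """Uniformly shuffled partition into blocks of length L (last possibly
    shorter)."""
    if L < 2:
        raise ValueError("L must be at least 2")
    feats = np.asarray(list(features), dtype=int)
    perm = rng.permutation(feats.size)
    shuffled = feats[perm]
    return [list(shuffled[i : i + L]) for i in range(0, shuffled.size, L)]


def block_stage(
    split: SplitData,
    candidate_features: Sequence[int],
    config: BosoConfig,
    criterion: str,
    m: int,
    rng: Optional[np.random.Generator] = None,
    p_total: Optional[int] = None,
) -> BlockStageResult:
    """One random-block phase: repeatedly partition the candidates, run the
    cardinality sweep inside each block, and pool the survivors until the
    pool stabilizes or drops below the block length; a final sweep over the
    survivors produces the phase's model."""
    candidates = sorted(int(j) for j in candidate_features)
    if not candidates:
        raise ValueError("candidate feature set is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p_total = split.p if p_total is None else p_total
    L = config.block_size
    log: list[dict] = []

    X_all, y_all = split.concat_train_val()
    grid = make_delta_grid(X_all[:, candidates], y_all, m)

    converged = False
    n_iters = 0
    current = candidates
    while len(current) > L and n_iters < config.max_block_iters:
        n_iters += 1
        survivors: list[int] = []
        for b, block in enumerate(random_blocks(current, L, rng)):
            fit = k_sweep(split.restrict(block), grid, config,
                          criterion=criterion, p_total=p_total)
            picked = [block[j] for j in fit.selected]
            survivors.extend(picked)
            log.append({
                "iteration": n_iters,
                "block": b,
                "block_features": tuple(block),
                "selected": tuple(picked),
                "criterion_value": fit.ic_value,
            })
        survivors = sorted(set(survivors))
        if survivors == current:
            converged = True
            break
        current = survivors
        if not current:
            break

    if len(current) <= L:
        converged = True

    if current:
        final = k_sweep(split.restrict(current), grid, config,
                        criterion=criterion, p_total=p_total)
        selected = tuple(current[j] for j in final.selected)
        beta = np.zeros(split.p + 1)
        beta[0] = final.intercept
        beta[np.asarray(current, dtype=int) + 1] = final.coef
        fit = BosoFit(
            selected=selected,
            beta=beta,
            delta=final.delta,
            K=final.K,
            criterion=criterion,
            ic_value=final.ic_value,
            ic_trajectory=final.ic_trajectory,
            stage_log=log + final.stage_log,
        )
    else:
        fit = _intercept_only_fit(split, criterion, p_total)
        fit.stage_log = log
        selected = ()
    if not converged and n_iters >= config.max_block_iters:
        import warnings

        warnings.warn(
            "random-block phase hit max_block_iters without a stable "
            "survivor set; returning current survivors",
            RuntimeWarning,
        )
    return BlockStageResult(
        selected=selected, fit=fit, n_iters=n_iters, converged=converged, log=log
    )


def _standardize(X: np.ndarray, y: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through unscaled
    y_mu = float(y.mean())
    return (X - mu) / sd, y - y_mu, mu, sd, y_mu


def boso(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[BosoConfig] = None,
    split: Optional[Union[SplitData, Sequence[float]]] = None,
    feature_ids: Optional[list[str]] = None,
) -> BosoFit:
    """Run the full algorithm on a design matrix and response.

    ``split`` may be a pre-made :class:`SplitData` (its matrices are used
    as-is, ignoring ``X``/``y``), a pair/triple of fractions, or ``None`` for
    the default 50/50 random train/validation split drawn from the config
    seed.  The returned coefficients are a ridge refit at the winning
    (subset, delta) on all supplied rows, reported on the original scale.
    """
    config = config or BosoConfig()
    if isinstance(split, SplitData):
        sd_split = split
        X_all, y_all = sd_split.concat_train_val()
        feature_ids = feature_ids or sd_split.feature_ids
    else:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] < 4:
            raise ValueError("need at least 4 rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite entries in X or y")
        fractions = tuple(split) if split is not None else (0.5, 0.5)
        sd_split = train_val_split(X, y, fractions, seed=config.seed,
                                   feature_ids=feature_ids)
        X_all, y_all = sd_split.concat_train_val()

    if config.standardize:
        _, _, mu, sdv, y_mu = _standardize(
            np.vstack([sd_split.X_train, sd_split.X_val]),
            np.concatenate([sd_split.y_train, sd_split.y_val]),
        )
        work = SplitData(
            (sd_split.X_train - mu) / sdv,
            sd_split.y_train - y_mu,
            (sd_split.X_val - mu) / sdv,
            sd_split.y_val - y_mu,
        )
    else:
        mu = np.zeros(sd_split.p)
        sdv = np.ones(sd_split.p)
        y_mu = 0.0
        work = SplitData(sd_split.X_train, sd_split.y_train,
                         sd_split.X_val, sd_split.y_val)

    p = work.p
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    stage1_criterion = "bic" if config.criterion == "ebic" else config.criterion
    stage1 = block_stage(work, range(p), config, stage1_criterion,
                         config.m_stage1, rng=rng, p_total=p)

    stage_log = [{"stage": 1, **entry} for entry in stage1.fit.stage_log]
    if config.criterion == "ebic" and stage1.selected:
        m2 = config.m_stage2
        if m2 is None:
            m2 = 50 if len(stage1.selected) <= 100 else 100
        stage2 = block_stage(work, stage1.selected, config, "ebic", m2,
                             rng=rng, p_total=p)
        final = stage2
        stage_log += [{"stage": 2, **entry} for entry in stage2.fit.stage_log]
    else:
        final = stage1

    # final ridge refit at the winning (Q, delta) on all supplied rows
    Q = sorted(final.selected)
    Xw_all, yw_all = work.concat_train_val()
    if Q:
        refit = ridge_fit(Xw_all[:, Q], yw_all, final.fit.delta, subset=Q)
        coef_std = np.zeros(p)
        coef_std[Q] = refit.coef
        intercept_std = refit.intercept
        delta = final.fit.delta
    else:
        coef_std = np.zeros(p)
        intercept_std = float(yw_all.mean())
        delta = 0.0

    coef = coef_std / sdv
    intercept = y_mu + intercept_std - float(mu @ coef)
    beta = np.concatenate([[intercept], coef])
    zeroed = [j for j in Q if coef[j] == 0.0]
    selected = tuple(j for j in Q if j not in zeroed)
    return BosoFit(
        selected=selected,
        beta=beta,
        delta=float(delta),
        K=len(selected),
        criterion=config.criterion,
        ic_value=final.fit.ic_value,
        ic_trajectory=final.fit.ic_trajectory,
        stage_log=stage_log,
        feature_ids=[feature_ids[j] for j in selected] if feature_ids else None,
    )
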