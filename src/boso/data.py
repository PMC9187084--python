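"""Train/validation/test containers shared by the solver, driver and baselines.

All matrices are plain ``numpy`` arrays with samples in rows and features in
columns.  Feature indices are 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SplitData", "train_val_split"]


@dataclass
class SplitData:
    """A regression problem split into train/validation (optionally test) parts.

    All parts share one feature universe: the column count of every design
    matrix must agree.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: Optional[np.ndarray] = None
    y_test: Optional[np.ndarray] = None
    feature_ids: Optional[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.y_train = np.asarray(self.y_train, dtype=float).ravel()
        self.X_val = np.asarray(self.X_val, dtype=float)
        self.y_val = np.asarray(self.y_val, dtype=float).ravel()
        if self.X_train.ndim != 2 or self.X_val.ndim != 2:
            raise ValueError("design matrices must be 2-D")
        if self.X_train.shape[1] != self.X_val.shape[1]:
            raise ValueError("train and validation feature counts differ")
        if self.X_train.shape[0] != self.y_train.shape[0]:
            raise ValueError("X_train/y_train row mismatch")
        if self.X_val.shape[0] != self.y_val.shape[0]:
            raise ValueError("X_val/y_val row mismatch")
        if (self.X_test is None) != (self.y_test is None):
            raise ValueError("X_test and y_test must be given together")
        if self.X_test is not None:
            self.X_test = np.asarray(self.X_test, dtype=float)
            self.y_test = np.asarray(self.y_test, dtype=float).ravel()
            if self.X_test.shape[1] != self.p:
                raise ValueError("test feature count differs")
        if self.feature_ids is not None and len(self.feature_ids) != self.p:
            raise ValueError("feature_ids length differs from feature count")

    @property
    def p(self) -> int:
        return self.X_train.shape[1]

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    @property
    def n_val(self) -> int:
        return self.X_val.shape[0]

    def restrict(self, cols: Sequence[int]) -> "SplitData":
        """A view of the split keeping only the given feature columns."""
        cols = list(cols)
        ids = [self.feature_ids[j] for j in cols] if self.feature_ids else None
        return SplitData(
            self.X_train[:, cols],
            self.y_train,
            self.X_val[:, cols],
            self.y_val,
            self.X_test[:, cols] if self.X_test is not None else None,
            self.y_test,
            feature_ids=ids,
        )

    def concat_train_val(self) -> tuple[np.ndarray, np.ndarray]:
        """Training and validation rows stacked (the refit/criterion data)."""
        X = np.vstack([self.X_train, self.X_val])
        y = np.concatenate([self.y_train, self.y_val])
        return X, y


def train_val_split(
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] = (0.5, 0.5),
    seed: int = 0,
    feature_ids: Optional[list[str]] = None,
) -> SplitData:
    """Randomly split rows into train/validation (and test if a third
    fraction is given).

    Fractions must sum to 1; sizes are rounded so that every row is used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    fr = list(fractions)
    if not np.isclose(sum(fr), 1.0):
        raise ValueError("fractions must sum to 1")
    if len(fr) not in (2, 3):
        raise ValueError("give 2 or 3 fractions")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n)) if len(fr) == 3 else n - n_train
    n_train = max(n_train, 2)
    n_val = max(n_val, 2)
    if n_train + n_val > n:
        raise ValueError("fewer than 2 usable rows in one of the splits")
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :] if len(fr) == 3 else None
    return SplitData(
        X[idx_train],
        y[idx_train],
        X[idx_val],
        y[idx_val],
        X[idx_test] if idx_test is not None and idx_test.size else None,
        y[idx_test] if idx_test is not None and idx_test.size else None,
        feature_ids=feature_ids,
    )
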