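"""Tabular I/O, expression filtering, stratified splitting, multi-seed
ensembles and the simulation-benchmark runner.

These are the operations surrounding the core selector when it is applied to
omics drug-response data: a samples-by-features expression table with a
numeric response (e.g. log IC50), mean/variance gene filtering, a
quantile-stratified train/validation/test split, and an ensemble of runs over
many split seeds summarized by how often each feature recurs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .baselines import forward_stepwise, lasso_path_select, relaxed_lasso_select
from .data import SplitData
from .driver import BosoConfig, BosoFit, boso
from .sim_bench import SimulationSpec, make_setting, score_selection, simulate

__all__ = [
    "TabularDataset",
    "EnsembleReport",
    "load_dataset",
    "save_dataset",
    "filter_expression",
    "stratified_split",
    "run_ensemble",
    "read_scenario_config",
    "run_benchmark",
]


@dataclass
class TabularDataset:
    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("X shape inconsistent with ids")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y length inconsistent with X")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids are not unique")


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # auto-detect comma vs tab from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed delimited file {path}: {err}") from err
    return df


def load_dataset(
    features_path: Union[str, Path],
    response_path: Optional[Union[str, Path]] = None,
    response_col: Optional[str] = None,
) -> TabularDataset:
    """Load a samples-by-features table (first column = sample ids, header =
    feature ids) and a response, either from a separate single-column file or
    from a named column of the feature table.

    Missing or non-numeric cells raise with the offending locations named.
    """
    df = _read_table(features_path)
    if response_col is not None:
        if response_col not in df.columns:
            raise ValueError(f"response column {response_col!r} not in table")
        y = df[response_col]
        df = df.drop(columns=[response_col])
    elif response_path is not None:
        ydf = _read_table(response_path)
        if ydf.shape[1] != 1:
            raise ValueError("response file must have exactly one value column")
        ydf = ydf.reindex(df.index)
        y = ydf.iloc[:, 0]
    else:
        raise ValueError("give response_path or response_col")
    Xnum = df.apply(pd.to_numeric, errors="coerce")
    ynum = pd.to_numeric(y, errors="coerce")
    bad_r, bad_c = np.where(~np.isfinite(Xnum.to_numpy()))
    bad = [f"({df.index[r]}, {df.columns[c]})" for r, c in zip(bad_r, bad_c)]
    if bad:
        raise ValueError(f"missing/non-numeric cells: {', '.join(bad[:20])}")
    if not np.all(np.isfinite(ynum.to_numpy())):
        rows = list(df.index[~np.isfinite(ynum.to_numpy())])
        raise ValueError(f"missing/non-numeric response for samples: {rows[:20]}")
    return TabularDataset(
        X=Xnum.to_numpy(),
        y=ynum.to_numpy(),
        feature_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def save_dataset(ds: TabularDataset, features_path: Union[str, Path],
                 response_col: str = "response") -> None:
    """Write the dataset as a canonical TSV (response as the last column);
    the format round-trips bitwise through :func:`load_dataset`."""
    df = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.feature_ids)
    df[response_col] = ds.y
    df.index.name = "sample"
    df.to_csv(features_path, sep="\t", float_format="%.17g", lineterminator="\n")


def filter_expression(
    ds: TabularDataset,
    mean_min: float = 1.0,
    var_min: float = 1.0,
    scale: str = "log2tpm",
) -> TabularDataset:
    """Keep genes with mean expression above ``mean_min`` TPM and variance
    above ``var_min`` on the supplied scale.

    ``scale='log2tpm'`` (the usual RNA-seq convention, log2(TPM+1)) converts
    back to TPM for the mean threshold while the variance threshold applies
    to the log-scale values as given; ``scale='tpm'`` applies both thresholds
    to the raw values.
    """
    if scale not in ("log2tpm", "tpm"):
        raise ValueError("scale must be 'log2tpm' or 'tpm'")
    if scale == "log2tpm":
        mean_tpm = np.mean(2.0**ds.X - 1.0, axis=0)
    else:
        mean_tpm = ds.X.mean(axis=0)
    variance = ds.X.var(axis=0, ddof=0)
    keep = (mean_tpm > mean_min) & (variance > var_min)
    if not np.any(keep):
        raise ValueError(
            "no feature passes the filter; lower mean_min/var_min"
        )
    idx = np.flatnonzero(keep)
    return TabularDataset(
        X=ds.X[:, idx],
        y=ds.y,
        feature_ids=[ds.feature_ids[j] for j in idx],
        sample_ids=ds.sample_ids,
    )


def stratified_split(
    y: np.ndarray,
    fractions: Sequence[float] = (0.4, 0.4, 0.2),
    bins: int = 5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Split sample indices so each part sees a homogeneous distribution of
    the response: y is quantile-binned into ``bins`` strata and each stratum
    is divided by the given fractions (largest-remainder rounding).

    Returns one index array per fraction.  Strata smaller than 3 (with three
    non-zero fractions) are merged with their neighbor, with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    fr = np.asarray(fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    if bins < 1:
        raise ValueError("bins must be at least 1")
    n = y.size
    rng = np.random.default_rng(seed)
    if bins == 1:
        strata = [np.arange(n)]
    else:
        edges = np.quantile(y, np.linspace(0, 1, bins + 1)[1:-1])
        codes = np.searchsorted(edges, y, side="right")
        strata = [np.flatnonzero(codes == b) for b in range(bins)]
        strata = [s for s in strata if s.size]
        min_size = 3 if np.count_nonzero(fr) == 3 else 2
        merged: list[np.ndarray] = []
        for s in strata:
            if s.size < min_size and merged:
                warnings.warn("merging a small stratum with its neighbor",
                              RuntimeWarning)
                merged[-1] = np.concatenate([merged[-1], s])
            else:
                merged.append(s)
        strata = merged
    parts: list[list[int]] = [[] for _ in fr]
    for s in strata:
        s = rng.permutation(s)
        exact = fr * s.size
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for _ in range(s.size - counts.sum()):
            k = int(np.argmax(rem))
            counts[k] += 1
            rem[k] = -1
        start = 0
        for k, c in enumerate(counts):
            parts[k].extend(s[start : start + c].tolist())
            start += c
    return [np.sort(np.asarray(part, dtype=int)) for part in parts]


@dataclass
class EnsembleReport:
    """Per-seed fits, test correlations, and feature recurrence counts."""

    fits: list[BosoFit]
    test_correlations: list[float]
    recurrence: dict[str, int]
    seeds: list[int] = field(default_factory=list)

    def recurrence_table(self) -> pd.DataFrame:
        rows = sorted(self.recurrence.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["feature", "num_times"])


def run_ensemble(
    dataset: TabularDataset,
    config: Optional[BosoConfig] = None,
    n_seeds: int = 100,
    fractions: Sequence[float] = (0.4, 0.4, 0.2),
    bins: int = 5,
) -> EnsembleReport:
    """Fit the selector under ``n_seeds`` different stratified splits and
    aggregate how often each feature is selected, plus the per-seed Pearson
    correlation between prediction and response on the held-out test part.

    All randomness derives from ``config.seed``: run i uses the spawned seed
    (seed, i), so any single run can be reproduced in isolation.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be at least 1")
    config = config or BosoConfig()
    fits: list[BosoFit] = []
    cors: list[float] = []
    rec: dict[str, int] = {}
    seeds: list[int] = []
    for i in range(n_seeds):
        sub_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
            % (2**31 - 1)
        )
        seeds.append(sub_seed)
        idx = stratified_split(dataset.y, fractions, bins=bins, seed=sub_seed)
        itr, iva = idx[0], idx[1]
        ite = idx[2] if len(idx) > 2 and idx[2].size else None
        split = SplitData(
            dataset.X[itr], dataset.y[itr],
            dataset.X[iva], dataset.y[iva],
            dataset.X[ite] if ite is not None else None,
            dataset.y[ite] if ite is not None else None,
            feature_ids=dataset.feature_ids,
        )
        run_cfg = BosoConfig(**{**config.__dict__, "seed": sub_seed})
        fit = boso(None, None, config=run_cfg, split=split,
                   feature_ids=dataset.feature_ids)
        fits.append(fit)
        for j in fit.selected:
            name = dataset.feature_ids[j]
            rec[name] = rec.get(name, 0) + 1
        if ite is not None and ite.size >= 3:
            pred = fit.predict(dataset.X[ite])
            if np.std(pred) > 0 and np.std(dataset.y[ite]) > 0:
                cors.append(float(pearsonr(pred, dataset.y[ite])[0]))
            else:
                cors.append(0.0)
    return EnsembleReport(fits=fits, test_correlations=cors, recurrence=rec,
                          seeds=seeds)


# ---------------------------------------------------------------------------
# simulation-benchmark runner


def read_scenario_config(path: Union[str, Path]) -> dict:
    """Parse a key = value scenario file (setting, beta_type, rho, snr, reps,
    seed; '#' starts a comment)."""
    out: dict = {}
    casts = {"beta_type": int, "reps": int, "seed": int,
             "rho": float, "snr": float, "setting": str}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        if key not in casts:
            raise ValueError(f"{path}:{ln}: unknown key {key!r}")
        out[key] = casts[key](value.strip())
    return out


_BENCH_METHODS = ("boso", "forward_stepwise", "lasso", "relaxed_lasso")


def run_benchmark(
    scenario: dict,
    methods: Sequence[str] = _BENCH_METHODS,
    config: Optional[BosoConfig] = None,
) -> pd.DataFrame:
    """Run one scenario (setting/beta_type/rho/snr) for ``reps`` replicates
    and score every method's selection against ground truth.

    Returns a tidy table: one row per method x replicate with f1, precision,
    recall, fp, fn, nonzeros and relative test error.
    """
    config = config or BosoConfig()
    reps = int(scenario.get("reps", 10))
    base_seed = int(scenario.get("seed", 1))
    rows = []
    for rep in range(1, reps + 1):
        spec = make_setting(
            scenario.get("setting", "low"),
            beta_type=int(scenario.get("beta_type", 1)),
            rho=float(scenario.get("rho", 0.35)),
            snr=float(scenario.get("snr", 1.0)),
            seed=base_seed + rep - 1,
        )
        rows.extend(_score_methods(spec, methods, config, rep))
    return pd.DataFrame(rows)


def _score_methods(spec: SimulationSpec, methods, config: BosoConfig, rep: int):
    from .data import train_val_split

    data = simulate(spec)
    split = train_val_split(data.X, data.y, (0.5, 0.5), seed=spec.seed)
    out = []
    for method in methods:
        if method == "boso":
            cfg = BosoConfig(**{**config.__dict__, "seed": spec.seed})
            fit = boso(None, None, config=cfg, split=split)
            selected, coef = fit.selected, fit.coef
        elif method == "forward_stepwise":
            bl = forward_stepwise(split)
            selected, coef = bl.selected, bl.coef
        elif method == "lasso":
            bl = lasso_path_select(split)
            selected, coef = bl.selected, bl.coef
        elif method == "relaxed_lasso":
            bl = relaxed_lasso_select(split)
            selected, coef = bl.selected, bl.coef
        else:
            raise ValueError(f"unknown method {method!r}")
        m = score_selection(selected, coef, data)
        out.append({
            "method": method,
            "setting": f"n{spec.n}_p{spec.p}_s{spec.s}",
            "beta_type": spec.beta_type,
            "rho": spec.rho,
            "snr": spec.snr,
            "rep": rep,
            "seed": spec.seed,
            "f1": m.f1,
            "precision": m.precision,
            "recall": m.recall,
            "fp": m.fp,
            "fn": m.fn,
            "nonzeros": m.nonzeros,
            "rte": m.rte,
        })
    return out


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
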