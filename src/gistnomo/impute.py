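"""Iterative boosted-tree multiple imputation for mixed categorical tables.

The algorithm fills a table with missing cells by chained supervised
learning: variables are visited in ascending order of missing count; for
each, a gradient-boosted decision-tree learner (with native categorical
handling) is trained on the rows where that variable is observed, using all
other — currently completed — variables as predictors, and its predictions
replace the variable's missing cells.  Passes over the variables repeat
until the imputations stop changing (a missForest-style divergence rule) or
a hard pass cap is hit.  Several such chains are run from different seeds
and aggregated per cell: majority vote for categorical variables, mean for
numeric ones.

The learner is pluggable: anything with ``fit(X, y)`` / ``predict(X)`` on a
DataFrame whose categorical columns have pandas ``category`` dtype works.
The reference binding is LightGBM.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype

__all__ = [
    "ImputationConfig",
    "ImputationResult",
    "order_variables_by_missingness",
    "initial_impute",
    "run_chain",
    "misscatboosts_impute",
    "evaluate_imputation",
    "mode_impute",
    "lightgbm_learner_factory",
]

DEFAULT_LEARNER_PARAMS = {
    "n_estimators": 200,
    "max_depth": 6,
    "learning_rate": 0.1,
    # row/column bagging gives the chains independent stochasticity; a
    # deterministic learner would make every chain identical
    "subsample": 0.9,
    "subsample_freq": 1,
    "colsample_bytree": 0.9,
}


def lightgbm_learner_factory(params: dict, seed: int, kind: str):
    """Return a LightGBM classifier/regressor configured for imputation.

    ``kind`` is "classifier" for categorical targets, "regressor" for
    numeric ones.  Single-threaded and seeded for reproducibility.
    """
    import lightgbm as lgb

    common = dict(
        n_estimators=int(params.get("n_estimators", 200)),
        max_depth=int(params.get("max_depth", 6)),
        learning_rate=float(params.get("learning_rate", 0.1)),
        min_child_samples=int(params.get("min_child_samples", 5)),
        num_leaves=int(params.get("num_leaves", 63)),
        subsample=float(params.get("subsample", 0.9)),
        subsample_freq=int(params.get("subsample_freq", 1)),
        colsample_bytree=float(params.get("colsample_bytree", 0.9)),
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_row_wise=True,
    )
    if kind == "classifier":
        return lgb.LGBMClassifier(**common)
    return lgb.LGBMRegressor(**common)


@dataclass
class ImputationConfig:
    """Knobs of the multiple-imputation ensemble.

    n_chains: independent imputation chains aggregated per cell.
    max_passes: hard cap on sweeps over the variables within one chain.
    tolerance: a chain also stops once its change statistic falls below this.
    learner_params: passed to the learner factory (trees, depth, rate).
    learner_factory: ``(params, seed, kind) -> estimator``; defaults to the
        LightGBM binding.
    """

    n_chains: int = 5
    max_passes: int = 10
    tolerance: float = 1e-4
    learner_params: dict = field(default_factory=lambda: dict(DEFAULT_LEARNER_PARAMS))
    learner_factory: Callable = lightgbm_learner_factory
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class ImputationResult:
    completed_table: pd.DataFrame
    variable_order: list[str]
    chain_traces: list[list[float]]
    #: per masked categorical cell (row, column) -> {level: votes}
    aggregation_record: dict[tuple, dict]


def order_variables_by_missingness(table: pd.DataFrame) -> list[str]:
    """Columns sorted ascending by missing-cell count; ties keep the
    original column order (stable sort), so fully observed columns lead."""
    if table.shape[1] < 1:
        raise ValueError("table must have at least one column")
    counts = table.isna().sum()
    return list(counts.sort_values(kind="stable").index)


def initial_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Column-mean fill for numeric gaps, column-mode fill for categorical
    ones.  A fully missing column has no basis for a guess and is an error."""
    out = table.copy()
    for col in out.columns:
        if not out[col].isna().any():
            continue
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} is entirely missing")
        if is_numeric_dtype(out[col]):
            out[col] = out[col].fillna(observed.mean())
        else:
            out[col] = out[col].fillna(observed.mode(dropna=True).iloc[0])
    return out


def _as_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Cast object columns to pandas category dtype for the learner."""
    out = table.copy()
    for col in out.columns:
        if not is_numeric_dtype(out[col]):
            out[col] = out[col].astype("category")
    return out


def _change_statistic(current: pd.DataFrame, previous: pd.DataFrame,
                      mask: pd.DataFrame) -> float:
    """Fraction of imputed categorical cells that changed since the last
    pass, plus normalized squared change over imputed numeric cells."""
    cat_changed = cat_total = 0
    num_sq = num_norm = 0.0
    for col in mask.columns:
        m = mask[col].to_numpy()
        if not m.any():
            continue
        cur = current[col].to_numpy()[m]
        prev = previous[col].to_numpy()[m]
        if is_numeric_dtype(current[col]):
            num_sq += float(np.sum((cur - prev) ** 2))
            num_norm += float(np.sum(np.asarray(cur, dtype=float) ** 2))
        else:
            cat_changed += int(np.sum(cur != prev))
            cat_total += m.sum()
    stat = 0.0
    if cat_total:
        stat += cat_changed / cat_total
    if num_norm > 0:
        stat += num_sq / num_norm
    return stat


def run_chain(table: pd.DataFrame, mask: pd.DataFrame, config: ImputationConfig,
              chain_seed: int) -> tuple[pd.DataFrame, list[float]]:
    """One imputation chain: initial fill, then iterated boosted-tree
    re-imputation until the change statistic diverges (first increase),
    drops below tolerance, or ``max_passes`` is reached.

    On divergence the previous pass's iterate is returned, mirroring the
    missForest convention of keeping the last improving state.
    """
    order = order_variables_by_missingness(table)
    active = [v for v in order if v in mask.columns and mask[v].any()]
    if not active:
        return table.copy(), []

    rng = np.random.default_rng(chain_seed)
    current = initial_impute(table)
    trace: list[float] = []
    best = current.copy()
    last_stat = np.inf

    for pass_no in range(1, config.max_passes + 1):
        before_pass = current.copy()
        for var in active:
            m = mask[var].to_numpy()
            predictors = [c for c in table.columns if c != var]
            X = _as_model_frame(current[predictors])
            y = current[var]
            kind = "regressor" if is_numeric_dtype(y) else "classifier"
            learner = config.learner_factory(
                config.learner_params, int(rng.integers(0, 2**31 - 1)), kind
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    learner.fit(X.loc[~m], y.loc[~m])
                    pred = learner.predict(X.loc[m])
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"learner failed on variable {var!r} in pass {pass_no}: {exc}"
                ) from exc
            current.loc[m, var] = pred
        stat = _change_statistic(current, before_pass, mask)
        trace.append(stat)
        if stat >= last_stat:  # diverged: roll back to the previous iterate
            current = best
            break
        best = current.copy()
        last_stat = stat
        if stat <= config.tolerance:
            break
    return current, trace


def _aggregate(chains: list[pd.DataFrame], table: pd.DataFrame,
               mask: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    out = table.copy()
    record: dict[tuple, dict] = {}
    for col in mask.columns:
        m = mask[col]
        if not m.any():
            continue
        rows = table.index[m]
        if is_numeric_dtype(table[col]):
            vals = np.column_stack([c.loc[rows, col].to_numpy(dtype=float)
                                    for c in chains])
            out.loc[rows, col] = vals.mean(axis=1)
            for i, r in enumerate(rows):
                record[(r, col)] = {"values": vals[i].tolist()}
        else:
            for r in rows:
                votes = Counter(str(c.at[r, col]) for c in chains)
                top = max(votes.values())
                # ties broken by the lowest-index chain's value
                winner = next(str(c.at[r, col]) for c in chains
                              if votes[str(c.at[r, col])] == top)
                out.at[r, col] = winner
                record[(r, col)] = dict(votes)
    return out, record


def misscatboosts_impute(table: pd.DataFrame, config: ImputationConfig | None = None,
                         mask: pd.DataFrame | None = None) -> ImputationResult:
    """Run the full multiple-imputation ensemble on a table with missing
    cells and aggregate the chains into one completed table.

    Observed cells are passed through untouched; every imputed categorical
    value is a level observed in its column.
    """
    config = config or ImputationConfig()
    config.validate()
    if table.shape[1] < 1 or table.isna().all().all():
        raise ValueError("table must have at least one non-fully-missing column")
    if mask is None:
        mask = table.isna()
    order = order_variables_by_missingness(table)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(config.n_chains)]
    chains, traces = [], []
    for idx, cs in enumerate(chain_seeds):
        try:
            completed, trace = run_chain(table, mask, config, cs)
        except Exception as exc:
            raise RuntimeError(f"imputation chain {idx} failed: {exc}") from exc
        chains.append(completed)
        traces.append(trace)

    completed, record = _aggregate(chains, table, mask)
    return ImputationResult(
        completed_table=completed,
        variable_order=order,
        chain_traces=traces,
        aggregation_record=record,
    )


def mode_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline comparator: unconditional column mode / mean fill."""
    return initial_impute(table)


def evaluate_imputation(completed: pd.DataFrame, truth: pd.DataFrame,
                        mask: pd.DataFrame) -> dict[str, float]:
    """Score an imputation against the pre-masking truth.

    PFC: fraction of masked categorical cells imputed incorrectly.
    NRMSE: RMSE over masked numeric cells, normalized by the truth column's
    standard deviation (pooled across numeric columns).
    """
    if not mask.to_numpy().any():
        raise ValueError("mask is empty; nothing to score")
    cat_wrong = cat_total = 0
    num_sq: list[float] = []
    for col in mask.columns:
        m = mask[col].to_numpy()
        if not m.any():
            continue
        imp = completed[col].to_numpy()[m]
        tru = truth[col].to_numpy()[m]
        if is_numeric_dtype(truth[col]):
            sd = float(truth[col].std(ddof=0))
            if sd == 0:
                raise ValueError(f"zero-variance numeric column {col!r}")
            num_sq.extend(((np.asarray(imp, float) - np.asarray(tru, float)) / sd) ** 2)
        else:
            cat_wrong += int(np.sum(imp != tru))
            cat_total += int(m.sum())
    metrics: dict[str, float] = {}
    if cat_total:
        metrics["pfc"] = cat_wrong / cat_total
    if num_sq:
        metrics["nrmse"] = float(np.sqrt(np.mean(num_sq)))
    return metrics
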