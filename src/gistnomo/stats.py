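"""Descriptive survival statistics and the balance-gated 7:3 repeated
train/test splitting protocol.

A candidate split is accepted only if every covariate shows no significant
train-vs-test difference: each categorical level by a 2x2 chi-squared test
of level membership against cohort membership (Yates continuity
correction, which matches the published per-level p-values), numeric age
by a two-sample Kolmogorov-Smirnov test by default (a Kruskal-Wallis rank
test is selectable).  Candidate splits are drawn by simple random
sampling and rejection-sampled until the requested number pass the gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from pandas.api.types import is_numeric_dtype
from scipy.stats import chi2_contingency, kruskal, ks_2samp

__all__ = [
    "BalanceReport",
    "SplitSet",
    "kaplan_meier",
    "logrank_test",
    "balance_tests",
    "generate_balanced_splits",
    "median_iqr",
]


@dataclass
class BalanceReport:
    """Per-variable (numeric) / per-level (categorical) balance tests of a
    train-vs-test split; ``passed`` iff every p-value >= alpha."""

    rows: pd.DataFrame  # columns: variable, level, test, statistic, p, pass
    alpha: float

    @property
    def passed(self) -> bool:
        return bool(self.rows["pass"].all())

    def worst(self) -> str:
        idx = self.rows["p"].idxmin()
        r = self.rows.loc[idx]
        return f"{r['variable']}" + (f"[{r['level']}]" if r["level"] else "")


@dataclass
class SplitSet:
    splits: list[tuple[np.ndarray, np.ndarray, BalanceReport]]
    ratio: float
    alpha: float
    n_attempts: int
    rejections: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.splits)


def kaplan_meier(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (times, S(t)) with S(0)=1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    km = KaplanMeierFitter()
    km.fit(time, event)
    s = km.survival_function_
    return s.index.to_numpy(dtype=float), s.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Multi-group log-rank test; returns (chi-square statistic, p)."""
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(time, float), group,
                                    np.asarray(event, int))
    return float(res.test_statistic), float(res.p_value)


def _chi2_level(in_level_train: int, n_train: int, in_level_test: int,
                n_test: int, correction: bool = True) -> tuple[float, float]:
    table = np.array([[in_level_train, n_train - in_level_train],
                      [in_level_test, n_test - in_level_test]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    stat, p, _, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def balance_tests(train: pd.DataFrame, test: pd.DataFrame,
                  variables: list[str] | None = None, alpha: float = 0.05,
                  numeric_method: str = "ks",
                  chi2_correction: bool = True) -> BalanceReport:
    """Test each covariate for train-vs-test distributional balance.

    Categorical variables are tested level by level (2x2 chi-squared of
    level membership x cohort), matching the published per-level p-value
    layout.  ``numeric_method`` is "ks" or "kruskal".
    """
    if train.empty or test.empty:
        raise ValueError("both cohorts must be non-empty")
    if numeric_method not in ("ks", "kruskal"):
        raise ValueError(f"unknown numeric_method {numeric_method!r}")
    variables = variables or [c for c in train.columns
                              if c not in ("survival_months", "os_event", "css_event")]
    rows = []
    for var in variables:
        if is_numeric_dtype(train[var]):
            a = train[var].dropna().to_numpy(dtype=float)
            b = test[var].dropna().to_numpy(dtype=float)
            if numeric_method == "ks":
                stat, p = ks_2samp(a, b)
                test_name = "kolmogorov-smirnov"
            else:
                stat, p = kruskal(a, b)
                test_name = "kruskal-wallis"
            rows.append((var, "", test_name, float(stat), float(p)))
        else:
            levels = sorted(set(train[var].dropna()) | set(test[var].dropna()), key=str)
            for lvl in levels:
                stat, p = _chi2_level(int((train[var] == lvl).sum()), len(train),
                                      int((test[var] == lvl).sum()), len(test),
                                      correction=chi2_correction)
                if np.isnan(p):  # level absent from both cohorts
                    continue
                rows.append((var, str(lvl), "chi-squared", stat, p))
    frame = pd.DataFrame(rows, columns=["variable", "level", "test", "statistic", "p"])
    frame["pass"] = frame["p"] >= alpha
    return BalanceReport(rows=frame, alpha=alpha)


def generate_balanced_splits(cohort: pd.DataFrame, n_splits: int = 50,
                             ratio: float = 0.7, alpha: float = 0.05,
                             seed: int = 0, max_attempts: int = 10_000,
                             variables: list[str] | None = None,
                             numeric_method: str = "ks") -> SplitSet:
    """Rejection-sample simple random ``ratio``:(1-ratio) partitions until
    ``n_splits`` pass every balance test at level ``alpha``.

    |train| = round(ratio * n).  Deterministic given ``seed``.  Raises
    after ``max_attempts`` candidates, naming the most-often-failing
    variable.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_train = int(round(ratio * n))
    accepted: list[tuple[np.ndarray, np.ndarray, BalanceReport]] = []
    rejections: dict[str, int] = {}
    attempts = 0
    while len(accepted) < n_splits:
        if attempts >= max_attempts:
            worst = max(rejections, key=rejections.get) if rejections else "?"
            raise RuntimeError(
                f"no balanced split found in {max_attempts} attempts; "
                f"most-often-failing variable: {worst}"
            )
        attempts += 1
        perm = rng.permutation(n)
        tr_idx, te_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        report = balance_tests(cohort.iloc[tr_idx], cohort.iloc[te_idx],
                               variables=variables, alpha=alpha,
                               numeric_method=numeric_method)
        if report.passed:
            accepted.append((tr_idx, te_idx, report))
        else:
            worst = report.worst()
            rejections[worst] = rejections.get(worst, 0) + 1
    return SplitSet(splits=accepted, ratio=ratio, alpha=alpha,
                    n_attempts=attempts, rejections=rejections)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return (float(np.median(v)), float(np.percentile(v, 25)),
            float(np.percentile(v, 75)))
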