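"""Time-dependent cumulative/dynamic AUC and the split-by-model
comparison grid.

At horizon t, cases are subjects with an observed event by t and controls
are subjects still at risk beyond t; censoring is handled by inverse
probability of censoring weighting (IPCW, Uno-type), with weights from the
Kaplan-Meier estimate of the censoring distribution.  Tied risk scores
count one half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import EncodedCohort
from .stats import SplitSet

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HORIZONS",
    "cumulative_dynamic_auc",
    "run_experiment",
    "summarize",
    "HorizonReport",
]

#: six evaluation horizons, in months
DEFAULT_HORIZONS = (6.0, 12.0, 36.0, 60.0, 84.0, 120.0)

HORIZON_TERMS = {6.0: "Near-term", 12.0: "Near-term", 36.0: "Mid-term",
                 60.0: "Mid-term", 84.0: "Long-term", 120.0: "Long-term"}


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """KM estimate G(t) of the censoring survival function (events censor
    the censoring process).  Returns a step-function evaluator."""
    order = np.argsort(time, kind="stable")
    t, c = time[order], 1 - event[order]
    uniq = np.unique(t)
    at_risk = len(t)
    surv = []
    g = 1.0
    for u in uniq:
        in_u = t == u
        d = int(c[in_u].sum())
        if at_risk > 0:
            g *= 1.0 - d / at_risk
        surv.append(g)
        at_risk -= int(in_u.sum())
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def G(x, before: bool = False):
        # before=True evaluates G(x-) (left limit)
        side = "left" if before else "right"
        idx = np.searchsorted(uniq, x, side=side) - 1
        idx = np.atleast_1d(idx)
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(x) else float(out[0])

    return G


def cumulative_dynamic_auc(risk_scores, time, event, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC at one horizon.

    Cases: event by the horizon, weighted 1/G(T-); controls: at risk past
    the horizon, weighted 1/G(horizon).  Tied scores count 1/2.  Returns
    NaN (with a warning) when there is no case or no control.
    """
    s = np.asarray(risk_scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not np.all(np.isfinite(s)):
        raise ValueError("risk scores must be finite")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        warnings.warn(f"no cases or no controls at horizon {horizon}; AUC undefined")
        return float("nan")
    G = _censoring_km(t, e)
    w_case = 1.0 / np.maximum(G(t[cases], before=True), 1e-12)
    w_ctrl = np.full(int(controls.sum()), 1.0 / max(G(horizon), 1e-12))
    sc, sk = s[cases], s[controls]
    # weighted pairwise comparison via ranking (ties = 1/2)
    gt = (sc[:, None] > sk[None, :]).astype(float)
    gt += 0.5 * (sc[:, None] == sk[None, :])
    num = float(w_case @ gt @ w_ctrl)
    den = float(w_case.sum() * w_ctrl.sum())
    return num / den


@dataclass
class HorizonReport:
    """Long-format AUC grid: one row per (model, split, horizon)."""

    grid: pd.DataFrame  # columns: model, split, horizon, auc
    horizons: tuple
    n_splits: int
    models: list[str]


def run_experiment(encoded: EncodedCohort, splits: SplitSet,
                   model_specs: dict, outcome: str = "os",
                   horizons=DEFAULT_HORIZONS,
                   encoded_full: EncodedCohort | None = None) -> HorizonReport:
    """Fit every model on each accepted split's train cohort (including
    internal selection / cross-validation), score its test cohort, and
    record the AUC at every horizon.

    ``model_specs`` maps a model name to a callable
    ``fitter(encoded_train, encoded_full_train, outcome, split_index) -> CoxFit``.
    ``encoded_full`` supplies the full one-hot design for penalized models;
    it defaults to ``encoded``.  A model failure on a split is logged and
    recorded as NaN, excluding that (model, split) from rankings.
    """
    if len(splits) < 1:
        raise ValueError("need at least one accepted split")
    encoded_full = encoded_full or encoded
    rows = []
    for s_idx, (tr, te, _) in enumerate(splits.splits):
        enc_tr = _subset(encoded, tr)
        enc_full_tr = _subset(encoded_full, tr)
        time_te, event_te = encoded.outcome(outcome)
        time_te = time_te.iloc[te].to_numpy(dtype=float)
        event_te = event_te.iloc[te].to_numpy(dtype=int)
        for name, fitter in model_specs.items():
            try:
                fit = fitter(enc_tr, enc_full_tr, outcome, s_idx)
                feats = fit.feature_names
                source = encoded_full.features if all(
                    f in encoded_full.features.columns for f in feats
                ) else encoded.features
                scores = source.iloc[te][feats].to_numpy(dtype=float) @ fit.beta
            except Exception as exc:  # noqa: BLE001 - record and move on
                log.warning("model %s failed on split %d: %s", name, s_idx, exc)
                for h in horizons:
                    rows.append((name, s_idx, float(h), float("nan")))
                continue
            for h in horizons:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    auc = cumulative_dynamic_auc(scores, time_te, event_te, h)
                rows.append((name, s_idx, float(h), auc))
    grid = pd.DataFrame(rows, columns=["model", "split", "horizon", "auc"])
    return HorizonReport(grid=grid, horizons=tuple(float(h) for h in horizons),
                         n_splits=len(splits), models=list(model_specs))


def _subset(encoded: EncodedCohort, idx) -> EncodedCohort:
    return EncodedCohort(
        features=encoded.features.iloc[idx].reset_index(drop=True),
        time=encoded.time.iloc[idx].reset_index(drop=True),
        os_event=encoded.os_event.iloc[idx].reset_index(drop=True),
        css_event=encoded.css_event.iloc[idx].reset_index(drop=True),
        mode=encoded.mode,
        references=encoded.references,
        levels=encoded.levels,
    )


def summarize(report: HorizonReport) -> pd.DataFrame:
    """Per (model, horizon): mean AUC, [25%, 75%] quantiles across splits,
    and "k/n" top-1 / top-3 ranking strings.

    Ranking ties at a horizon give every tied model the better rank, so
    top-1 counts can exceed n_splits only in the presence of exact ties
    (which are logged).  Failed (model, split) cells are excluded from
    that split's ranking.
    """
    g = report.grid
    out = []
    top1 = {(m, h): 0 for m in report.models for h in report.horizons}
    top3 = dict(top1)
    for h in report.horizons:
        for s in range(report.n_splits):
            cell = g[(g.horizon == h) & (g.split == s)].dropna(subset=["auc"])
            if cell.empty:
                continue
            aucs = cell.set_index("model")["auc"]
            if aucs.duplicated().any() and len(aucs.unique()) < len(aucs):
                log.info("AUC tie at horizon %s split %d", h, s)
            best = aucs.max()
            third = aucs.nlargest(min(3, len(aucs))).min()
            for m, a in aucs.items():
                if a == best:
                    top1[(m, h)] += 1
                if a >= third:
                    top3[(m, h)] += 1
    for m in report.models:
        for h in report.horizons:
            vals = g[(g.model == m) & (g.horizon == h)]["auc"].dropna()
            if vals.empty:
                continue
            out.append({
                "term": HORIZON_TERMS.get(h, ""),
                "horizon_months": h,
                "model": m,
                "mean_auc": vals.mean(),
                "q25": vals.quantile(0.25),
                "q75": vals.quantile(0.75),
                "top1": f"{top1[(m, h)]}/{report.n_splits}",
                "top3": f"{top3[(m, h)]}/{report.n_splits}",
            })
    return pd.DataFrame(out)
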