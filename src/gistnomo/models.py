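"""The five Cox nomogram model families.

* ``two_stage``: univariate screening at p < alpha, joint multivariate
  retention at p < alpha, final refit — the classical nomogram recipe.
* ``lasso`` / ``enet``: elastic-net-penalized Cox (gamma = 1 / 0.5) along a
  glmnet-style lambda path, lambda chosen by 5-fold cross-validated
  partial-likelihood deviance (scikit-survival's Coxnet path solver).
* ``ridge``: gamma = 0, fit by Newton iteration on the ridge-penalized
  Breslow partial likelihood over a log-spaced lambda grid with the same
  cross-validation rule (the path solver requires gamma > 0).
* ``cox_with_lasso``: unpenalized refit on the lasso model's nonzero set.

All unpenalized fits use the Breslow tie approximation, Wald confidence
intervals, and the Breslow baseline cumulative hazard; penalized fits
carry no per-feature inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._coxlib import breslow_baseline, breslow_gradient, breslow_loglik, \
    breslow_hessian, newton_cox
from .prep import EncodedCohort

__all__ = [
    "CoxFit",
    "PenaltyPath",
    "fit_cox",
    "two_stage_select_and_fit",
    "fit_penalized_cox",
    "cox_with_lasso",
    "predict_risk",
    "predict_survival",
    "GAMMA_BY_PENALTY",
]

GAMMA_BY_PENALTY = {"lasso": 1.0, "ridge": 0.0, "enet": 0.5}


@dataclass
class CoxFit:
    feature_names: list[str]
    beta: np.ndarray
    family: str  # two_stage | lasso | ridge | enet | cox_with_lasso | cox
    hr_ci_p: pd.DataFrame | None  # HR, lower, upper, p (unpenalized only)
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    selection_trace: dict = field(default_factory=dict)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def baseline_survival(self) -> np.ndarray:
        return np.exp(-self.baseline_cumhaz)

    @property
    def nonzero_features(self) -> list[str]:
        return [f for f, b in zip(self.feature_names, self.beta) if b != 0.0]


def _design(encoded: EncodedCohort, outcome: str, features: list[str] | None):
    feats = list(features) if features is not None else list(encoded.features.columns)
    X = encoded.features[feats].to_numpy(dtype=float)
    time, event = encoded.outcome(outcome)
    return feats, X, time.to_numpy(dtype=float), event.to_numpy(dtype=int)


def fit_cox(encoded: EncodedCohort, outcome: str = "os",
            features: list[str] | None = None, family: str = "cox") -> CoxFit:
    """Unpenalized Cox proportional-hazards fit (Breslow ties).

    A statsmodels PHReg fit provides starting values; the estimate is then
    polished by Newton iteration on the Breslow partial likelihood so the
    score equation is satisfied to high precision.  Wald CIs/p-values come
    from the observed information at the optimum.
    """
    feats, X, time, event = _design(encoded, outcome, features)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    beta0 = None
    try:
        from statsmodels.duration.hazard_regression import PHReg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta0 = PHReg(time, X, status=event, ties="breslow").fit(disp=False).params
    except Exception:
        beta0 = None
    try:
        beta = newton_cox(X, time, event, ridge=0.0, beta0=beta0)
    except RuntimeError as exc:
        # name the feature with the largest score residual at the last iterate
        b = beta0 if beta0 is not None else np.zeros(X.shape[1])
        g = breslow_gradient(b, X, time, event)
        raise RuntimeError(f"{exc}; worst feature: {feats[int(np.argmax(np.abs(g)))]}"
                           ) from exc

    info = -breslow_hessian(beta, X, time, event)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "HR": np.exp(beta),
        "lower95": np.exp(beta - 1.959963984540054 * se),
        "upper95": np.exp(beta + 1.959963984540054 * se),
        "p": p,
    }, index=feats)
    times, cumhaz = breslow_baseline(beta, X, time, event)
    return CoxFit(feature_names=feats, beta=beta, family=family, hr_ci_p=table,
                  baseline_times=times, baseline_cumhaz=cumhaz)


def _variable_groups(encoded: EncodedCohort) -> dict[str, list[str]]:
    """Model columns grouped by source variable (age is its own group)."""
    groups: dict[str, list[str]] = {}
    cols = list(encoded.features.columns)
    if "age_years" in cols:
        groups["age_years"] = ["age_years"]
    for var, lvls in encoded.levels.items():
        members = [f"{var}_{l}" for l in lvls if f"{var}_{l}" in cols]
        if members:
            groups[var] = members
    return groups


def two_stage_select_and_fit(encoded: EncodedCohort, outcome: str = "os",
                             alpha: float = 0.05) -> CoxFit:
    """Univariate screen -> multivariate retention -> final refit.

    Stage 1 fits one Cox model per source variable (numeric age alone;
    each categorical variable with all of its non-reference dummies) and
    advances the individual dummies with Wald p < alpha.  Stage 2 fits the
    joint model on the advanced dummies and retains those with p < alpha.
    The returned fit is re-estimated on the retained set; the full
    selection trace (univariate and multivariate p per dummy) is stored.
    """
    if encoded.mode != "reference":
        raise ValueError("two-stage selection requires reference-dropped encoding")
    uni_p: dict[str, float] = {}
    for var, members in _variable_groups(encoded).items():
        f = fit_cox(encoded, outcome, features=members)
        for m in members:
            uni_p[m] = float(f.hr_ci_p.loc[m, "p"])
    advanced = [m for m, pv in uni_p.items() if pv < alpha]
    if not advanced:
        raise RuntimeError("no feature passed the univariate screen")
    joint = fit_cox(encoded, outcome, features=advanced)
    multi_p = {m: float(joint.hr_ci_p.loc[m, "p"]) for m in advanced}
    retained = [m for m in advanced if multi_p[m] < alpha]
    if not retained:
        raise RuntimeError("no feature passed the multivariate stage")
    final = fit_cox(encoded, outcome, features=retained, family="two_stage")
    final.selection_trace = {"univariate_p": uni_p, "multivariate_p": multi_p,
                             "advanced": advanced, "retained": retained,
                             "alpha": alpha}
    return final


@dataclass
class PenaltyPath:
    alphas: np.ndarray  # lambda grid, descending
    gamma: float
    cv_deviance: np.ndarray  # mean over folds, per lambda
    chosen_alpha: float
    n_nonzero: int
    coef_path: np.ndarray | None = None  # (n_alphas, p), original scale


def _cv_deviance(X, time, event, betas_by_alpha, folds, seed,
                 refit) -> np.ndarray:
    """Mean 5-fold test-set partial-likelihood deviance per lambda.

    ``refit(X_train, t_train, e_train) -> beta matrix (n_alphas, p)``.
    """
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, betas_by_alpha.shape[0]))
    for k, (tr, te) in enumerate(kf.split(X)):
        B = refit(X[tr], time[tr], event[tr])
        for a in range(B.shape[0]):
            dev[k, a] = -2.0 * breslow_loglik(B[a], X[te], time[te], event[te])
    return dev.mean(axis=0)


def _ridge_grid(X, time, event, n_alphas: int = 30) -> np.ndarray:
    # anchor on the lasso lambda_max scale; ridge needs heavier lambdas to
    # shrink visibly, so extend two decades above it
    g = breslow_gradient(np.zeros(X.shape[1]), X, time, event)
    lam_max = np.max(np.abs(g)) / len(time)
    return np.geomspace(lam_max * 1e2, lam_max * 1e-4, n_alphas)


def fit_penalized_cox(encoded: EncodedCohort, outcome: str = "os",
                      penalty: str = "lasso", folds: int = 5, seed: int = 0,
                      n_alphas: int = 100, alphas=None, tol: float = 1e-7
                      ) -> tuple[CoxFit, PenaltyPath]:
    """Elastic-net-penalized Cox along a lambda path with cross-validated
    lambda selection (minimum mean partial-likelihood deviance).

    ``penalty`` is "lasso" (gamma=1), "enet" (gamma=0.5) or "ridge"
    (gamma=0).  Features are standardized internally; coefficients are
    returned on the original scale.
    """
    if penalty not in GAMMA_BY_PENALTY:
        raise ValueError(f"unknown penalty {penalty!r}")
    gamma = GAMMA_BY_PENALTY[penalty]
    feats, X, time, event = _design(encoded, outcome, None)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if gamma > 0:
        model = CoxnetSurvivalAnalysis(l1_ratio=gamma, n_alphas=n_alphas,
                                       alpha_min_ratio=1e-4, normalize=True,
                                       alphas=alphas, tol=tol, max_iter=10**6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        grid = np.asarray(model.alphas_)
        coefs = model.coef_.T  # (n_alphas, p), original scale

        def refit(Xt, tt, et):
            m = CoxnetSurvivalAnalysis(l1_ratio=gamma, alphas=grid, normalize=True,
                                       tol=tol, max_iter=10**6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Xt, Surv.from_arrays(event=et.astype(bool), time=tt))
            # the fold path may drop trailing alphas on non-convergence
            out = np.zeros((len(grid), Xt.shape[1]))
            fitted = {a: i for i, a in enumerate(np.asarray(m.alphas_))}
            for i, a in enumerate(grid):
                j = fitted.get(a)
                out[i] = m.coef_[:, j] if j is not None else m.coef_[:, -1]
            return out
    else:
        grid = np.asarray(alphas) if alphas is not None else _ridge_grid(X, time, event)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)

        def _ridge_path(Xt, tt, et):
            Z = (Xt - mu) / sd
            B = np.zeros((len(grid), Xt.shape[1]))
            b = np.zeros(Xt.shape[1])
            for i, lam in enumerate(grid):  # warm start down the path
                b = newton_cox(Z, tt, et, ridge=float(lam), beta0=b)
                B[i] = b / sd  # back to original scale
            return B

        coefs = _ridge_path(X, time, event)
        refit = _ridge_path

    cv = _cv_deviance(X, time, event, coefs, folds, seed, refit)
    best = int(np.argmin(cv))
    chosen = float(grid[best])
    beta = coefs[best].copy()
    nz = np.flatnonzero(beta != 0.0)
    if nz.size == 0:
        raise RuntimeError("all-zero solution at every lambda on the path")
    times, cumhaz = breslow_baseline(beta, X, time, event)
    fit = CoxFit(feature_names=feats, beta=beta, family=penalty, hr_ci_p=None,
                 baseline_times=times, baseline_cumhaz=cumhaz,
                 selection_trace={"chosen_lambda": chosen, "gamma": gamma,
                                  "n_nonzero": int(nz.size)})
    path = PenaltyPath(alphas=grid, gamma=gamma, cv_deviance=cv,
                       chosen_alpha=chosen, n_nonzero=int(nz.size),
                       coef_path=np.asarray(coefs))
    return fit, path


def _identifiable_subset(encoded: EncodedCohort, selected: list[str]) -> list[str]:
    """Reduce a full-one-hot selection to an identifiable dummy basis: if
    every level of a variable was selected, drop its reference level."""
    keep = list(selected)
    for var, lvls in encoded.levels.items():
        members = [f"{var}_{l}" for l in lvls]
        if all(m in keep for m in members):
            ref_col = f"{var}_{encoded.references[var]}"
            drop = ref_col if ref_col in members else members[0]
            keep.remove(drop)
    return keep


def cox_with_lasso(encoded: EncodedCohort, outcome: str,
                   lasso_fit: CoxFit) -> CoxFit:
    """Unpenalized Cox refit on the lasso model's nonzero feature set,
    mapped to an identifiable (reference-dropped) basis."""
    selected = lasso_fit.nonzero_features
    if not selected:
        raise ValueError("lasso fit has no nonzero features")
    basis = _identifiable_subset(encoded, selected)
    try:
        fit = fit_cox(encoded, outcome, features=basis, family="cox_with_lasso")
    except RuntimeError as exc:
        raise RuntimeError(f"selected set not fittable after basis reduction: {exc}"
                           ) from exc
    fit.selection_trace = {"lasso_nonzero": selected, "basis": basis}
    return fit


def predict_risk(fit: CoxFit, rows: pd.DataFrame) -> np.ndarray:
    """Linear predictors x . beta for encoded feature rows."""
    X = rows[fit.feature_names].to_numpy(dtype=float)
    return X @ fit.beta


def predict_survival(fit: CoxFit, rows: pd.DataFrame, t: float) -> np.ndarray:
    """S(t | x) = S0(t) ^ exp(lp), with S0 the Breslow baseline survival.

    Horizons beyond the observed event-time grid use the last grid point
    (with a warning): the baseline estimate carries no information there.
    """
    lp = predict_risk(fit, rows)
    if fit.baseline_times.size == 0:
        raise ValueError("fit has no baseline estimate")
    if t > fit.baseline_times[-1]:
        warnings.warn(f"horizon {t} beyond baseline grid end "
                      f"{fit.baseline_times[-1]}; using last grid point")
    idx = np.searchsorted(fit.baseline_times, t, side="right") - 1
    h0 = fit.baseline_cumhaz[idx] if idx >= 0 else 0.0
    return np.exp(-h0) ** np.exp(lp)
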