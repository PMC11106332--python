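"""Synthetic SEER-like gastric-GIST cohort generator.

Emulates the structure of a registry export at the granularity of the
published demographics table: one numeric age, eleven categorical
covariates with fixed level sets, survival months, and overall-survival
(OS) / cancer-specific-survival (CSS) event indicators.

Event times follow an exponential proportional-hazards law with two
competing causes (cancer death and other-cause death), plus independent
exponential censoring and an administrative follow-up cap.  Cause-specific
log-hazard coefficients are specified per dummy feature, so a Cox fit on a
large cohort is expected to recover them — that closed-form ground truth
is the point of the exponential choice.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

__all__ = [
    "CohortConfig",
    "MissingnessPlan",
    "default_category_specs",
    "default_references",
    "generate_raw_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "CATEGORICAL_VARIABLES",
]

#: categorical variables in demographic-table order
CATEGORICAL_VARIABLES = [
    "Sex",
    "Race",
    "Marital_status",
    "Tumor_location",
    "Tumor_grade",
    "Tumor_size",
    "AJCC_stage",
    "Mitotic_rate",
    "Surgery",
    "Regional_nodes_examined",
    "Chemotherapy",
]

OUTCOME_COLUMNS = ["survival_months", "os_event", "css_event"]


def _load_table1():
    ref = importlib.resources.files("gistnomo.data") / "table1_marginals.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_category_specs() -> dict[str, list[tuple[str, float]]]:
    """Per-variable (level, marginal probability) lists from the shipped
    whole-population counts; probabilities sum to 1 exactly per variable."""
    raw = _load_table1()
    specs: dict[str, list[tuple[str, float]]] = {}
    for var, counts in raw["variables"].items():
        total = sum(counts.values())
        specs[var] = [(str(lvl), c / total) for lvl, c in counts.items()]
    return specs


def default_references() -> dict[str, str]:
    """Reference level per categorical variable (the level dropped in
    reference-coded dummy encoding)."""
    return {k: str(v) for k, v in _load_table1()["references"].items()}


def default_log_hazards(cause: str = "cancer") -> dict[str, float]:
    """Default cause-specific log hazard ratios.

    The cancer-cause effects mirror the magnitudes reported for
    gastric-GIST cancer-specific survival in registry analyses (age per
    year ~1.03, male ~1.6, black race ~1.7, unmarried ~1.4, poor grade
    ~1.6, large tumors ~2.5-2.8, advanced AJCC stage ~2.2-2.5, no surgery
    ~4.9, many nodes examined ~1.6, as HRs).  The other-cause hazard rises
    with age only, approximating background mortality.
    """
    if cause == "cancer":
        return {
            "age_years": 0.03,
            "Sex_Male": 0.47,
            "Race_Black": 0.53,
            "Marital_status_Single": 0.34,
            "Tumor_grade_Poorly differentiated/undifferentiated": 0.44,
            "Tumor_size_5-10 cm": 0.90,
            "Tumor_size_>=10 cm": 1.04,
            "AJCC_stage_III": 0.90,
            "AJCC_stage_IV": 0.77,
            "Surgery_No surgery": 1.59,
            "Regional_nodes_examined_>4": 0.46,
        }
    if cause == "other":
        return {"age_years": 0.09}
    raise ValueError(f"unknown cause {cause!r}")


#: default latent correlations: strongly linked grade/mitotic-rate and
#: size/stage pairs, weaker cross-links — the association pattern real
#: registry cohorts show on a Phi heatmap
DEFAULT_COPULA_CORR = {
    ("Tumor_grade", "Mitotic_rate"): 0.6,
    ("Tumor_size", "AJCC_stage"): 0.6,
    ("Tumor_size", "Tumor_grade"): 0.25,
    ("Tumor_size", "Mitotic_rate"): 0.25,
    ("AJCC_stage", "Tumor_grade"): 0.25,
    ("AJCC_stage", "Mitotic_rate"): 0.25,
}


@dataclass
class CohortConfig:
    """Ground-truth generative model for a synthetic cohort.

    ``log_hazards_cancer`` / ``log_hazards_other`` map dummy-feature names
    (``"<variable>_<level>"`` or ``"age_years"``) to cause-specific log
    hazard ratios.  The age coefficient is per year and age enters the
    linear predictor centred at its distribution median, so the baseline
    rates refer to a median-aged reference patient.
    """

    n_patients: int = 2000
    category_specs: dict[str, list[tuple[str, float]]] = field(
        default_factory=default_category_specs
    )
    age_median: float = 64.0
    age_lower: float = 20.0
    age_upper: float = 95.0
    age_mu: float = 64.3
    age_sd: float = 14.4
    log_hazards_cancer: dict[str, float] = field(
        default_factory=lambda: default_log_hazards("cancer"))
    log_hazards_other: dict[str, float] = field(
        default_factory=lambda: default_log_hazards("other"))
    baseline_hazard_rate: float = 0.0004  # cancer deaths per month (reference patient)
    other_cause_rate: float = 0.0005  # non-cancer deaths per month
    censor_rate: float = 0.006  # loss to follow-up / administrative censoring per month
    followup_cap_months: float = 250.0
    #: Gaussian-copula rank correlations among ordered severity variables
    #: (marginals are preserved exactly); None disables dependence
    copula_corr: dict[tuple[str, str], float] | None = field(
        default_factory=lambda: dict(DEFAULT_COPULA_CORR))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for rate_name in ("baseline_hazard_rate", "other_cause_rate", "censor_rate"):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"{rate_name} must be >= 0")
        for var, spec in self.category_specs.items():
            probs = [p for _, p in spec]
            if any(p < 0 for p in probs):
                raise ValueError(f"negative probability in {var}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal probabilities for {var} sum to {sum(probs)}, not 1"
                )
        known = {"age_years"} | {
            f"{var}_{lvl}" for var, spec in self.category_specs.items() for lvl, _ in spec
        }
        for betas in (self.log_hazards_cancer, self.log_hazards_other):
            unknown = set(betas) - known
            if unknown:
                raise ValueError(f"log-hazard features not in cohort: {sorted(unknown)}")


@dataclass
class MissingnessPlan:
    """Where and how to blank categorical cells.

    mechanism "MCAR": each targeted cell blanked independently.
    mechanism "MAR": the log-odds of blanking are shifted by
    ``log(odds_ratio)`` for rows whose fully observed driver variable takes
    ``driver_level``; the overall blanked fraction still targets
    ``fractions[var]`` on average.
    """

    fractions: dict[str, float] = field(default_factory=dict)
    mechanism: str = "MCAR"
    driver: str | None = None
    driver_level: str | None = None
    odds_ratio: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for var, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"missing fraction for {var} must be in [0,1]")
        if self.mechanism == "MAR":
            if self.driver is None or self.driver_level is None:
                raise ValueError("MAR plan needs driver and driver_level")
            if self.odds_ratio <= 0:
                raise ValueError("odds_ratio must be > 0")


def _linear_predictor(frame: pd.DataFrame, betas: dict[str, float], age_median: float
                      ) -> np.ndarray:
    lp = np.zeros(len(frame))
    for feat, beta in betas.items():
        if feat == "age_years":
            lp += beta * (frame["age_years"].to_numpy() - age_median)
            continue
        # feature names use "<variable>_<level>"; variable names themselves
        # contain underscores, so match against the frame's columns
        for var in frame.columns:
            if feat.startswith(str(var) + "_"):
                lvl = feat[len(str(var)) + 1:]
                lp += beta * (frame[var].to_numpy() == lvl).astype(float)
                break
        else:
            raise ValueError(f"log-hazard feature {feat!r} matches no column")
    return lp


def generate_raw_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table: covariates, survival_months, os_event, css_event.

    Deterministic given ``config.seed``.  ``css_event <= os_event`` holds by
    construction: a CSS event is a death whose first-arriving cause is the
    cancer cause.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    a = (config.age_lower - config.age_mu) / config.age_sd
    b = (config.age_upper - config.age_mu) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mu, scale=config.age_sd,
                        size=n, random_state=rng)
    frame = pd.DataFrame({"age_years": np.round(age, 1)})

    # variables linked through the copula draw from correlated latent
    # normals; the inverse-CDF map preserves each marginal exactly
    corr_vars: list[str] = []
    if config.copula_corr:
        names = sorted({v for pair in config.copula_corr for v in pair})
        corr_vars = [v for v in names if v in config.category_specs]
    if len(corr_vars) >= 2:
        k = len(corr_vars)
        sigma = np.eye(k)
        for (a_name, b_name), rho in config.copula_corr.items():
            if a_name in corr_vars and b_name in corr_vars:
                i, j = corr_vars.index(a_name), corr_vars.index(b_name)
                sigma[i, j] = sigma[j, i] = rho
        # guard against an inconsistent user-supplied matrix
        w, v = np.linalg.eigh(sigma)
        sigma = (v * np.clip(w, 1e-6, None)) @ v.T
        z = rng.multivariate_normal(np.zeros(k), sigma, size=n,
                                    method="cholesky")
        from scipy.stats import norm

        u = norm.cdf(z)
        for i, var in enumerate(corr_vars):
            spec = config.category_specs[var]
            levels = [lvl for lvl, _ in spec]
            cum = np.cumsum([p for _, p in spec])
            idx = np.searchsorted(cum / cum[-1], u[:, i], side="left")
            frame[var] = np.array(levels, dtype=object)[np.clip(idx, 0,
                                                                len(levels) - 1)]
    else:
        corr_vars = []

    for var, spec in config.category_specs.items():
        if var in corr_vars:
            continue
        levels = [lvl for lvl, _ in spec]
        probs = np.array([p for _, p in spec])
        frame[var] = rng.choice(levels, size=n, p=probs / probs.sum())
        frame[var] = frame[var].astype(object)

    lp_cancer = _linear_predictor(frame, config.log_hazards_cancer, config.age_median)
    lp_other = _linear_predictor(frame, config.log_hazards_other, config.age_median)

    def _exp_times(rate: float, lp: np.ndarray) -> np.ndarray:
        haz = rate * np.exp(lp)
        with np.errstate(divide="ignore"):
            return np.where(haz > 0, rng.exponential(1.0, n) / np.maximum(haz, 1e-300),
                            np.inf)

    t_cancer = _exp_times(config.baseline_hazard_rate, lp_cancer)
    t_other = _exp_times(config.other_cause_rate, lp_other)
    t_censor = (rng.exponential(1.0 / config.censor_rate, n)
                if config.censor_rate > 0 else np.full(n, np.inf))

    t_death = np.minimum(t_cancer, t_other)
    t_obs = np.minimum.reduce([t_death, t_censor,
                               np.full(n, config.followup_cap_months)])
    os_event = (t_death <= np.minimum(t_censor, config.followup_cap_months)).astype(int)
    css_event = (os_event & (t_cancer < t_other)).astype(int)

    frame["survival_months"] = np.round(t_obs, 2)
    frame["os_event"] = os_event
    frame["css_event"] = css_event
    return frame


def inject_missingness(cohort: pd.DataFrame, plan: MissingnessPlan
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank categorical cells per the plan; returns (gapped copy, mask).

    The mask is a boolean frame over the targeted variables marking exactly
    the blanked cells; untouched cells of the input are never altered.
    """
    plan.validate()
    for var in plan.fractions:
        if var in ("age_years", *OUTCOME_COLUMNS):
            raise ValueError(f"missingness may target only categorical variables, not {var}")
        if var not in cohort.columns:
            raise ValueError(f"unknown variable {var}")
    rng = np.random.default_rng(plan.seed)
    out = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index, columns=list(plan.fractions))

    if plan.mechanism == "MAR":
        if cohort[plan.driver].isna().any():
            raise ValueError("MAR driver variable must be fully observed")
        in_level = (cohort[plan.driver] == plan.driver_level).to_numpy()

    for var, frac in plan.fractions.items():
        if frac == 0:
            continue
        if plan.mechanism == "MCAR":
            p = np.full(len(cohort), frac)
        else:
            # solve base probability so the expected overall fraction is frac
            share = in_level.mean()
            from scipy.optimize import brentq

            def overall(logit0):
                p0 = 1 / (1 + np.exp(-logit0))
                p1 = 1 / (1 + np.exp(-(logit0 + np.log(plan.odds_ratio))))
                return (1 - share) * p0 + share * p1 - frac

            logit0 = brentq(overall, -30, 30)
            p = np.where(in_level,
                         1 / (1 + np.exp(-(logit0 + np.log(plan.odds_ratio)))),
                         1 / (1 + np.exp(-logit0)))
        hit = rng.random(len(cohort)) < p
        mask[var] = hit
        out.loc[hit, var] = np.nan
    return out, mask


def generate_latent_class_table(n: int, variables: dict[str, list[str]] | None = None,
                                signal: float = 0.7, n_classes: int = 3,
                                seed: int = 0) -> pd.DataFrame:
    """Correlated categorical table for imputation benchmarking.

    A latent class Z (uniform over ``n_classes``) drives every variable:
    with probability ``signal`` a variable takes its class-determined
    level (a fixed random class->level map), otherwise a uniform random
    level.  ``signal`` = 0 gives independent columns, ``signal`` = 1 makes
    every variable a deterministic function of Z (hence of each other when
    the class->level maps are injective).
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must be in [0, 1]")
    if variables is None:
        variables = {
            "V1": ["a", "b", "c"],
            "V2": ["x", "y", "z"],
            "V3": ["lo", "mid", "hi"],
            "V4": ["p", "q", "r"],
        }
    rng = np.random.default_rng(seed)
    z = rng.integers(0, n_classes, size=n)
    out = {}
    for var, levels in variables.items():
        k = len(levels)
        class_map = rng.permutation(k)[np.arange(n_classes) % k]
        determined = np.array(levels, dtype=object)[class_map[z]]
        noise = rng.choice(levels, size=n)
        take = rng.random(n) < signal
        out[var] = np.where(take, determined, noise)
    return pd.DataFrame(out).astype(object)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """CSV with header; missing cells are empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path, category_specs: dict[str, list[tuple[str, float]]] | None = None
                ) -> pd.DataFrame:
    """Read a cohort CSV, validating categorical levels against the declared
    level sets (defaults to the shipped demographic-table levels)."""
    frame = pd.read_csv(path, dtype={v: object for v in CATEGORICAL_VARIABLES})
    if frame.empty:
        raise ValueError(f"{path}: empty cohort file")
    specs = category_specs if category_specs is not None else default_category_specs()
    for var, spec in specs.items():
        if var not in frame.columns:
            continue
        allowed = {lvl for lvl, _ in spec}
        col = frame[var]
        bad = col.notna() & ~col.isin(allowed)
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: unknown level {col[row]!r} in column {var!r}, row {row}"
            )
    return frame
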