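"""Cohort preparation: exclusion cascade, NCCN-style recoding, dummy
encoding, and categorical association (Phi) analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype
from scipy.stats import chi2_contingency

from .synthetic import CATEGORICAL_VARIABLES, default_references

__all__ = [
    "RecodeMap",
    "EncodedCohort",
    "EXCLUSION_CRITERIA",
    "apply_exclusions",
    "recode_variables",
    "encode_dummies",
    "decode_dummies",
    "phi_matrix",
]


# Exclusion cascade: ordered (label, column read, keep-predicate). A row is
# attributed to the FIRST criterion it fails. Criteria whose column is
# absent from the table pass vacuously (synthetic cohorts are born
# pre-coded and carry only age and survival-months among these fields).
EXCLUSION_CRITERIA = [
    ("I_site_not_stomach", "site",
     lambda s: s.astype(str).str.lower() == "stomach"),
    ("II_age_under_20", "age_years", lambda s: s >= 20),
    ("III_race_unknown", "race_known", lambda s: s.astype(bool)),
    ("IV_not_first_malignant", "first_malignant", lambda s: s.astype(bool)),
    ("V_tumor_size_unknown_or_zero", "tumor_size_mm",
     lambda s: s.notna() & (s > 0)),
    ("VI_surgery_not_performed_or_unknown", "surgery_performed",
     lambda s: s.astype(bool)),
    ("VII_cause_of_death_unknown", "cause_known", lambda s: s.astype(bool)),
    ("VIII_survival_under_3_months", "survival_months", lambda s: s >= 3),
]


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows failing the registry exclusion cascade.

    Returns the filtered cohort and per-criterion removal counts, each
    removed row attributed to the first criterion it fails.
    """
    keep = pd.Series(True, index=raw.index)
    attributed = pd.Series(False, index=raw.index)
    counts: dict[str, int] = {}
    for label, col, pred in EXCLUSION_CRITERIA:
        if col not in raw.columns:
            counts[label] = 0
            continue
        ok = pred(raw[col]).fillna(False)
        fails = ~ok & ~attributed
        counts[label] = int(fails.sum())
        attributed |= fails
        keep &= ok
    return raw.loc[keep].copy(), counts


@dataclass
class RecodeMap:
    """Numeric-to-categorical binning rules for the NCCN-style recode.

    Each entry: variable -> (bin right edges, output labels); bins follow a
    half-open (lo, hi] convention so the printed <=/>= endpoints land in
    the closed side. ``reference`` names each output variable's reference
    level for dummy encoding.
    """

    tumor_size_cm: tuple = (0.0, (2.0, 5.0, 10.0, np.inf),
                            ("<=2 cm", "2-5 cm", "5-10 cm", ">=10 cm"))
    mitotic_rate: tuple = (-np.inf, (5.0, np.inf), ("<=5/5 HPF", ">5/5 HPF"))
    nodes_examined: tuple = (-np.inf, (0.0, 4.0, np.inf), ("0", "1-4", ">4"))
    age_cut_years: float = 65.0  # KM display only; models keep age numeric
    references: dict[str, str] = field(default_factory=default_references)


def _bin(values: pd.Series, lo: float, edges, labels, varname: str) -> pd.Series:
    v = values.astype(float)
    if (v < 0).any():
        row = int(v.index[v < 0][0])
        raise ValueError(f"{varname}: negative value at row {row}")
    out = pd.Series(index=values.index, dtype=object)
    for hi, lab in zip(edges, labels):
        sel = (v > lo) & (v <= hi)
        out[sel] = lab
        lo = hi
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise ValueError(f"{varname}: value {values[row]!r} outside all bins (row {row})")
    return out


def recode_variables(raw: pd.DataFrame, rmap: RecodeMap | None = None) -> pd.DataFrame:
    """Recode numeric tumor size (cm), mitotic rate (/5 HPF) and regional
    nodes examined into their categorical bins; add the 65-year age split
    as ``age_group`` for display.  Columns absent from the input are left
    alone, so pre-coded cohorts pass through unchanged."""
    rmap = rmap or RecodeMap()
    out = raw.copy()
    if "tumor_size_cm" in out.columns:
        out["Tumor_size"] = _bin(out["tumor_size_cm"], *rmap.tumor_size_cm,
                                 "tumor_size_cm")
    if "mitotic_rate_per_5hpf" in out.columns:
        out["Mitotic_rate"] = _bin(out["mitotic_rate_per_5hpf"], *rmap.mitotic_rate,
                                   "mitotic_rate_per_5hpf")
    if "nodes_examined" in out.columns:
        out["Regional_nodes_examined"] = _bin(out["nodes_examined"],
                                              *rmap.nodes_examined, "nodes_examined")
    if "age_years" in out.columns:
        out["age_group"] = np.where(out["age_years"] < rmap.age_cut_years,
                                    f"<{rmap.age_cut_years:.0f}",
                                    f">={rmap.age_cut_years:.0f}")
    return out


@dataclass
class EncodedCohort:
    """Design matrix + outcomes for survival modelling.

    ``mode`` is "reference" (each variable's reference level dropped —
    identifiable, for unpenalized Cox) or "full" (complete one-hot, for
    penalized Cox).  ``features`` carries 0/1 dummies named
    ``<variable>_<level>`` plus numeric ``age_years``.
    """

    features: pd.DataFrame
    time: pd.Series
    os_event: pd.Series
    css_event: pd.Series
    mode: str
    references: dict[str, str]
    levels: dict[str, list[str]]

    def outcome(self, which: str) -> tuple[pd.Series, pd.Series]:
        which = which.lower()
        if which == "os":
            return self.time, self.os_event
        if which == "css":
            return self.time, self.css_event
        raise ValueError(f"unknown outcome {which!r}")


def encode_dummies(cohort: pd.DataFrame, mode: str = "reference",
                   references: dict[str, str] | None = None,
                   variables: list[str] | None = None) -> EncodedCohort:
    """One-hot encode the categorical covariates, keeping age numeric.

    Requires a complete table (run after imputation).
    """
    if mode not in ("reference", "full"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    refs = references if references is not None else default_references()
    variables = variables or [v for v in CATEGORICAL_VARIABLES if v in cohort.columns]
    cols: dict[str, np.ndarray] = {}
    levels: dict[str, list[str]] = {}
    if "age_years" in cohort.columns:
        cols["age_years"] = cohort["age_years"].to_numpy(dtype=float)
    for var in variables:
        col = cohort[var]
        if col.isna().any():
            raise ValueError(f"{var}: missing cells; encode after imputation")
        lvls = sorted(col.unique(), key=str)
        ref = refs.get(var)
        if ref in lvls:  # reference listed first for readability
            lvls = [ref] + [l for l in lvls if l != ref]
        levels[var] = [str(l) for l in lvls]
        for lvl in lvls:
            if mode == "reference" and str(lvl) == str(ref):
                continue
            cols[f"{var}_{lvl}"] = (col == lvl).to_numpy(dtype=float)
    features = pd.DataFrame(cols, index=cohort.index)
    return EncodedCohort(
        features=features,
        time=cohort["survival_months"].astype(float)
        if "survival_months" in cohort.columns else pd.Series(dtype=float),
        os_event=cohort["os_event"].astype(int)
        if "os_event" in cohort.columns else pd.Series(dtype=int),
        css_event=cohort["css_event"].astype(int)
        if "css_event" in cohort.columns else pd.Series(dtype=int),
        mode=mode,
        references={v: str(refs.get(v)) for v in variables},
        levels=levels,
    )


def decode_dummies(encoded: EncodedCohort) -> pd.DataFrame:
    """Invert :func:`encode_dummies`, recovering the categorical table."""
    out = pd.DataFrame(index=encoded.features.index)
    if "age_years" in encoded.features.columns:
        out["age_years"] = encoded.features["age_years"]
    for var, lvls in encoded.levels.items():
        vals = pd.Series(index=out.index, dtype=object)
        assigned = pd.Series(False, index=out.index)
        for lvl in lvls:
            name = f"{var}_{lvl}"
            if name in encoded.features.columns:
                hit = encoded.features[name] == 1
                vals[hit] = lvl
                assigned |= hit
        if encoded.mode == "reference":
            vals[~assigned] = encoded.references[var]
        elif (~assigned).any():
            raise ValueError(f"{var}: full one-hot row sums must be 1")
        out[var] = vals
    return out


def phi_matrix(cohort: pd.DataFrame, variables: list[str] | None = None
               ) -> pd.DataFrame:
    """Pairwise Phi association between categorical variables.

    Binary x binary pairs use the signed 2x2 formula
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); pairs involving a variable with
    more than two levels use the unsigned sqrt(chi2 / n).  Zero-variance
    variables yield NaN against everything.
    """
    variables = variables or [c for c in cohort.columns
                              if not is_numeric_dtype(cohort[c])]
    if len(variables) < 2:
        raise ValueError("need at least two categorical variables")
    k = len(variables)
    out = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variables[i], variables[j]
            tab = pd.crosstab(cohort[a], cohort[b]).to_numpy()
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                val = np.nan
            elif tab.shape == (2, 2):
                (t00, t01), (t10, t11) = tab
                denom = np.sqrt(float(t00 + t01) * (t10 + t11)
                                * (t00 + t10) * (t01 + t11))
                val = (t00 * t11 - t01 * t10) / denom if denom > 0 else np.nan
            else:
                chi2 = chi2_contingency(tab, correction=False)[0]
                val = np.sqrt(chi2 / tab.sum())
            out.iat[i, j] = out.iat[j, i] = val
    return out
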