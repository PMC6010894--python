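"""Logistic risk models for a rare incident outcome and a serum biomarker.

Unconditional logistic regression of incident HCC on the biomarker scaled to
10 ng/mL units, under three nested covariate sets (univariate; + age, sex,
smoking, drinking; + education, marriage, BMI, physical activity, family
cancer history), and the same model within pre-specified subgroups with the
stratifying variable removed from the adjustment set.  Odds ratios carry Wald
95% confidence intervals and two-sided p-values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

logger = logging.getLogger(__name__)

_Z975 = float(norm.ppf(0.975))

#: Adjustment sets for the three model labels.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "model1": (),
    "model2": ("age", "sex_male", "smoking", "drinking"),
    "model3": ("age", "sex_male", "smoking", "drinking",
               "education", "marriage", "bmi", "physical_activity",
               "family_history"),
}

#: Subgroup definitions: (label, stratifying column, {stratum: predicate}).
#: Age and BMI cutpoints place the boundary value in the upper stratum.
SUBGROUP_RULES = (
    ("sex", "sex_male", {"male": lambda d: d["sex_male"] == 1,
                         "female": lambda d: d["sex_male"] == 0}),
    ("age", "age", {"<62": lambda d: d["age"] < 62,
                    ">=62": lambda d: d["age"] >= 62}),
    ("bmi", "bmi", {"<24": lambda d: d["bmi"] < 24,
                    ">=24": lambda d: d["bmi"] >= 24}),
    ("smoking", "smoking", {"ever": lambda d: d["smoking"] == 1,
                            "never": lambda d: d["smoking"] == 0}),
    ("drinking", "drinking", {"ever": lambda d: d["drinking"] == 1,
                              "never": lambda d: d["drinking"] == 0}),
)


@dataclass
class LogisticFit:
    """One logistic fit: OR per unit of the (pre-scaled) exposure with Wald
    95% CI and two-sided p."""
    exposure_name: str
    model_label: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    converged: bool
    covariates: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {"exposure": self.exposure_name, "model": self.model_label,
                "covariates": ",".join(self.covariates) or "none",
                "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "n_used": self.n_used, "converged": self.converged}


def ensure_indicator_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a 0/1 ``sex_male`` indicator derived from the ``sex`` column."""
    df = cohort.copy()
    if "sex_male" not in df.columns and "sex" in df.columns:
        df["sex_male"] = (df["sex"] == "male").astype(int)
    return df


def fit_logistic(outcome, exposure, covariates: pd.DataFrame | None = None,
                 exposure_name: str = "exposure",
                 model_label: str = "model1") -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on a
    (pre-scaled) exposure plus optional covariates.

    The exposure coefficient is reported as an odds ratio with Wald 95% CI
    ``exp(beta +/- z_{.975} * SE)``.  Separation or non-convergence is
    flagged via ``converged=False`` (with NaN estimates when the likelihood
    is degenerate), never silently reported.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model is "
                         "unidentifiable")
    x = pd.DataFrame({exposure_name: np.asarray(exposure, dtype=float)})
    if covariates is not None and len(covariates.columns):
        x = pd.concat([x.reset_index(drop=True),
                       covariates.reset_index(drop=True).astype(float)], axis=1)
    design = sm.add_constant(x, has_constant="add")

    converged = True
    try:
        with warnings.catch_warnings():
            # separation and overflow surface through the converged flag
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-10, disp=0,
                                          warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", False))
        beta = float(res.params[exposure_name])
        se = float(res.bse[exposure_name])
        p = float(res.pvalues[exposure_name])
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
        converged, beta, se, p = False, math.nan, math.nan, math.nan
    if not math.isfinite(se):
        converged = False
    return LogisticFit(
        exposure_name=exposure_name, model_label=model_label,
        beta=beta, se=se, or_=math.exp(beta) if math.isfinite(beta) else math.nan,
        ci_low=math.exp(beta - _Z975 * se) if converged else math.nan,
        ci_high=math.exp(beta + _Z975 * se) if converged else math.nan,
        p=p, n_used=len(y), converged=converged,
        covariates=tuple(covariates.columns) if covariates is not None else ())


def _complete_case(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        logger.info("complete-case: dropped %d of %d rows", dropped, len(sub))
    return kept


def run_model_battery(cohort: pd.DataFrame,
                      exposures: dict[str, str] | None = None,
                      models: tuple[int, ...] = (1, 2, 3)) -> pd.DataFrame:
    """Fit every exposure x model combination; biomarkers are scaled to per-10
    ng/mL units before fitting.

    ``exposures`` maps a display name to a cohort column; default is the raw
    and genetically corrected AFP.  Rows with missing model variables are
    dropped per model (complete case).
    """
    if exposures is None:
        exposures = {"afp": "afp_ng_ml", "corrected_afp": "afp_corrected"}
    df = ensure_indicator_columns(cohort)
    rows = []
    for label, col in exposures.items():
        if col not in df.columns:
            raise ValueError(f"exposure column {col!r} absent from cohort")
        for m in models:
            key = f"model{m}"
            if key not in MODEL_COVARIATES:
                raise ValueError(f"unknown model label {key!r}")
            covs = list(MODEL_COVARIATES[key])
            data = _complete_case(df, ["hcc", col, *covs])
            fit = fit_logistic(data["hcc"], data[col] / 10.0,
                               data[covs] if covs else None,
                               exposure_name=f"{label}_per10",
                               model_label=key)
            fit.n_used = len(data)
            rows.append(fit.as_row())
    return pd.DataFrame(rows)


def subgroup_analysis(cohort: pd.DataFrame, exposure_col: str = "afp_corrected",
                      min_stratum_n: int = 50) -> pd.DataFrame:
    """Per-stratum logistic fits (per 10 ng/mL) across the five pre-specified
    groupings, adjusting for the full covariate set minus the stratifier.

    Strata smaller than ``min_stratum_n`` or with a single outcome class are
    reported as NA rows rather than raising.
    """
    df = ensure_indicator_columns(cohort)
    if exposure_col not in df.columns:
        raise ValueError(f"exposure column {exposure_col!r} absent from cohort")
    rows = []
    for label, strat_col, strata in SUBGROUP_RULES:
        covs = [c for c in MODEL_COVARIATES["model3"] if c != strat_col]
        for stratum, pred in strata.items():
            data = _complete_case(df, ["hcc", exposure_col, strat_col, *covs])
            data = data[pred(data)]
            base = {"grouping": label, "stratum": stratum, "n_used": len(data),
                    "n_cases": int(data["hcc"].sum()) if len(data) else 0}
            if (len(data) < min_stratum_n
                    or data["hcc"].nunique() < 2):
                rows.append({**base, "or": math.nan, "ci_low": math.nan,
                             "ci_high": math.nan, "p": math.nan,
                             "converged": False})
                continue
            fit = fit_logistic(data["hcc"], data[exposure_col] / 10.0,
                               data[covs], exposure_name=f"{exposure_col}_per10",
                               model_label=f"subgroup:{label}={stratum}")
            rows.append({**base, "or": fit.or_, "ci_low": fit.ci_low,
                         "ci_high": fit.ci_high, "p": fit.p,
                         "converged": fit.converged})
    return pd.DataFrame(rows)


def incidence_rate(n_cases: int, n_total: int) -> float:
    """Cumulative incidence per 1000 people, two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_cases <= n_total:
        raise ValueError("n_cases must be between 0 and n_total")
    return round(1000.0 * n_cases / n_total, 2)
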