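"""Disease-based validation of the biological-age clocks.

Cross-sectional on baseline records: each clock's acceleration is
standardized and (except the cardiopulmonary clock, whose accelerations are
too small) split at +/-1 into low/mid/high categories; logistic regressions
then test its association with organ-mapped diseases, adjusting for the
five lifestyle factors and the standard covariate set. A panel passes when
its continuous per-SD odds ratio exceeds 1 with a 95% CI excluding 1 for at
least one mapped disease. No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from organclock import columns as C

__all__ = [
    "DEFAULT_DISEASE_MAP",
    "ValidationSpec",
    "OddsRatioEstimate",
    "standardize_and_categorize",
    "fit_logistic",
    "select_validated_panels",
    "validate_panels",
]

log = logging.getLogger(__name__)

#: panel -> diseases it should reflect; renal has no mapped disease and is
#: therefore unvalidatable with the collected outcomes
DEFAULT_DISEASE_MAP: dict[str, list[str]] = {
    "comprehensive": ["cvd", "diabetes", "cancer"],
    "cardiopulmonary": ["cvd", "chronic_bronchitis"],
    "metabolic": ["cvd", "diabetes"],
    "liver": ["chronic_hepatitis"],
    "renal": [],
    "immune": ["rheumatoid_arthritis"],
}

#: panels whose acceleration is never categorized
NO_CATEGORY_PANELS = frozenset({"cardiopulmonary"})

DEFAULT_VALIDATION_COVARIATES = [
    "age", "sex", "ethnicity", "urbanicity", "education", "occupation",
    "marital", "energy_kcal", "depression", "anxiety", "menopausal",
    "beverage", "supplement",
]
LIFESTYLE_FLAG_COLS = [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS]


@dataclass
class ValidationSpec:
    disease_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_MAP))
    covariates: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_VALIDATION_COVARIATES))
    adjust_lifestyle: bool = True
    categorize_scale: str = "z"   # cut at +/-1 on the z scale ("raw" = years)


@dataclass
class OddsRatioEstimate:
    panel: str
    disease: str
    term: str                     # "per_sd" | "cat_low" | "cat_high"
    odds_ratio: float
    ci_low: float
    ci_high: float
    converged: bool = True


def standardize_and_categorize(
    accel: pd.Series,
    reference: pd.Series | None = None,
    scale: str = "z",
) -> tuple[pd.Series, pd.Series]:
    """Z-score accelerations against a (baseline) reference population and
    cut into low (< -1) / mid (|.| <= 1, the reference group) / high (> 1).

    ``scale='raw'`` applies the +/-1 cut in years instead of SD units.
    """
    ref = accel if reference is None else reference
    mu, sd = float(ref.mean()), float(ref.std())
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("reference population SD must be positive")
    z = (accel - mu) / sd
    basis = z if scale == "z" else accel
    category = pd.Series(
        np.select([basis < -1, basis > 1], ["low", "high"], "mid"),
        index=accel.index)
    return z, category


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design block: categoricals dummy-coded (first level dropped)."""
    blocks = []
    for cov in covariates:
        col = df[cov]
        if cov == "menopausal":
            dums = pd.get_dummies(col, prefix=cov, dtype=float)
            keep = [f"menopausal_{lv}" for lv in C.MENOPAUSAL_DUMMY_LEVELS]
            blocks.append(dums[[c for c in keep if c in dums.columns]])
        elif cov in C.CATEGORICAL_COVARIATES or col.dtype == object:
            blocks.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
        else:
            blocks.append(col.astype(float).rename(cov))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)


def fit_logistic(
    outcome: pd.Series,
    terms: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """ML logistic fit; per term exp(beta) with Wald 95% CI.

    Separation or non-convergence yields rows flagged ``converged=False``
    rather than silent NaNs.
    """
    y = outcome.astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")
    X = terms.astype(float)
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates], axis=1)
    X = sm.add_constant(X, has_constant="add")
    res, converged = None, False
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:  # singular Hessian, separation, ...
        res = None
    if res is None or not converged:
        # Newton struggles with near-separated rare outcomes; BFGS is slower
        # but far more robust on these designs
        try:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=2000, gtol=1e-6)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
            converged = False
    if res is not None:
        params, bse = res.params, res.bse
    else:
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
    rows = []
    for t in terms.columns:
        beta, se = params[t], bse[t]
        rows.append({
            "term": t, "beta": beta, "se": se,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "converged": converged and np.isfinite(se),
        })
    return pd.DataFrame(rows)


def validate_panels(
    data: pd.DataFrame,
    ba_results: pd.DataFrame,
    hli_records: pd.DataFrame,
    spec: ValidationSpec | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Run the full validation stage on baseline records.

    Returns (tidy estimate table, validated panels, unvalidatable panels).
    """
    spec = spec or ValidationSpec()
    base = data[data["wave"] == 0].set_index("person_id")
    hli0 = hli_records[hli_records["wave"] == 0].set_index("person_id")
    estimates = []
    unvalidatable = []
    for panel, diseases in spec.disease_map.items():
        if not diseases:
            unvalidatable.append(panel)
            continue
        acc = (ba_results[(ba_results["panel"] == panel) & (ba_results["wave"] == 0)]
               .set_index("person_id")["ba_accel"])
        idx = base.index.intersection(acc.index)
        z, cat = standardize_and_categorize(acc.loc[idx], scale=spec.categorize_scale)
        cov = _design(base.loc[idx], spec.covariates)
        if spec.adjust_lifestyle:
            cov = pd.concat([cov, hli0.loc[idx, LIFESTYLE_FLAG_COLS].astype(float)], axis=1)
        for disease in diseases:
            y = base.loc[idx, disease]
            terms = pd.DataFrame({"per_sd": z})
            res = fit_logistic(y, terms, cov)
            res["term"] = "per_sd"
            res.insert(0, "panel", panel)
            res.insert(1, "disease", disease)
            estimates.append(res)
            if panel not in NO_CATEGORY_PANELS:
                cat_terms = pd.DataFrame({
                    "cat_low": (cat == "low").astype(float),
                    "cat_high": (cat == "high").astype(float),
                })
                resc = fit_logistic(y, cat_terms, cov)
                resc.insert(0, "panel", panel)
                resc.insert(1, "disease", disease)
                estimates.append(resc)
    table = pd.concat(estimates, ignore_index=True)
    validated = select_validated_panels(table, spec)
    return table, validated, unvalidatable


def select_validated_panels(
    estimates: pd.DataFrame, spec: ValidationSpec | None = None
) -> list[str]:
    """Panels whose continuous per-SD OR is > 1 with a CI excluding 1 for at
    least one mapped disease."""
    spec = spec or ValidationSpec()
    cont = estimates[(estimates["term"] == "per_sd") & estimates["converged"]]
    passed = cont[(cont["odds_ratio"] > 1.0) & (cont["ci_low"] > 1.0)]
    order = list(spec.disease_map)
    found = set(passed["panel"])
    return [p for p in order if p in found]
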