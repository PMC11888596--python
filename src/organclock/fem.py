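"""Two-wave fixed-effects estimation of lifestyle-change effects.

With two waves the fixed-effects (within) estimator is identical to
first-difference OLS: the change in BA acceleration is regressed on changes
in the exposures and time-varying covariates. Time-invariant covariates and
baseline chronological age enter the differenced equation as level terms
(equivalent to covariate-by-wave interactions); the "standard FEM"
sensitivity variant drops them, leaving the pure within estimator.
Standard errors are heteroskedasticity-robust (HC1). Subgroup heterogeneity
is assessed with Cochran's Q at alpha = 0.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from organclock import columns as C
from organclock.lifestyle import (ALTERNATIVE_DEFINITIONS, FactorDefinitions,
                                  build_hli_records, categorize_change)

__all__ = [
    "FEMSpec",
    "RankDeficiencyError",
    "build_difference_frame",
    "fit_fem",
    "fit_fem_frame",
    "subgroup_q_test",
    "run_subgroup_analysis",
    "run_sensitivity_suite",
]

log = logging.getLogger(__name__)

EXPOSURE_MODES = {
    "five-factors-joint": [f"d_{f}" for f in C.LIFESTYLE_FACTORS],
    "hli-continuous": ["d_hli"],
    "hli-binary": ["d_hli_category"],
}

DEFAULT_TIME_VARYING = [c for c in C.TIME_VARYING_COVARIATES]
DEFAULT_TIME_INVARIANT = ["sex", "ethnicity", "urbanicity", "education", "baseline_age"]


class RankDeficiencyError(ValueError):
    """The differenced design is rank deficient (named terms collinear)."""


@dataclass
class FEMSpec:
    """What to regress on what, and which model variant to use."""

    outcome_panel: str = "comprehensive"
    exposure_mode: str = "five-factors-joint"
    time_varying: Sequence[str] = field(default_factory=lambda: list(DEFAULT_TIME_VARYING))
    time_invariant: Sequence[str] = field(default_factory=lambda: list(DEFAULT_TIME_INVARIANT))
    variant: str = "primary"          # primary | standard-fem | bmi-adjusted
    subgroup: str | None = None

    def __post_init__(self):
        if self.exposure_mode not in EXPOSURE_MODES:
            raise ValueError(f"unknown exposure mode {self.exposure_mode!r}")
        if self.variant not in {"primary", "standard-fem", "bmi-adjusted"}:
            raise ValueError(f"unknown variant {self.variant!r}")


def _dummies_both_waves(data: pd.DataFrame, cov: str) -> pd.DataFrame:
    """Dummy-code a categorical consistently across waves (levels pooled).

    Menopausal status keeps only peri/post indicators (reference = premenopausal
    women and men), which would otherwise be collinear with sex.
    """
    if cov == "menopausal":
        dums = pd.get_dummies(data[cov], prefix=cov, dtype=float)
        keep = [f"menopausal_{lv}" for lv in C.MENOPAUSAL_DUMMY_LEVELS]
        return dums[[c for c in keep if c in dums.columns]]
    return pd.get_dummies(data[cov], prefix=cov, drop_first=True, dtype=float)


def build_difference_frame(
    data: pd.DataFrame,
    ba_results: pd.DataFrame,
    change_records: pd.DataFrame,
    spec: FEMSpec,
) -> pd.DataFrame:
    """Assemble the per-person differenced design for one outcome panel.

    Columns: ``d_y`` (change in BA acceleration), exposure deltas from
    ``change_records``, ``d_<cov>`` for time-varying covariates (categorical
    covariates are dummy-coded before differencing), and level terms for the
    time-invariant covariates (baseline values, dummy-coded).
    """
    acc = ba_results[ba_results["panel"] == spec.outcome_panel]
    wide = acc.pivot(index="person_id", columns="wave", values="ba_accel")
    wide = wide.dropna()
    out = pd.DataFrame({"d_y": wide[1] - wide[0]})

    chg = change_records.set_index("person_id")
    exposures = EXPOSURE_MODES[spec.exposure_mode]
    out = out.join(chg[exposures], how="inner")

    tv = list(spec.time_varying)
    if spec.variant == "bmi-adjusted" and C.BMI not in tv:
        tv = tv + [C.BMI]
    dat = data.set_index(["person_id", "wave"])
    for cov in tv:
        if cov in C.CATEGORICAL_COVARIATES or data[cov].dtype == object:
            dums = _dummies_both_waves(data, cov)
            dums.index = dat.index
            for col in dums.columns:
                w = dums[col].unstack("wave")
                out[f"d_{col}"] = w[1] - w[0]
        else:
            w = dat[cov].unstack("wave").astype(float)
            out[f"d_{cov}"] = w[1] - w[0]

    if spec.variant != "standard-fem":
        base = data[data["wave"] == 0].set_index("person_id")
        for cov in spec.time_invariant:
            if cov == "baseline_age":
                out["baseline_age"] = base[C.AGE]
            elif cov in C.CATEGORICAL_COVARIATES or base[cov].dtype == object:
                dums = pd.get_dummies(base[cov], prefix=cov, drop_first=True, dtype=float)
                out = out.join(dums)
            else:
                out[cov] = base[cov].astype(float)
    n0 = len(out)
    out = out.dropna()
    if len(out) < n0:
        log.info("build_difference_frame[%s]: dropped %d persons with missing terms",
                 spec.outcome_panel, n0 - len(out))
    return out


def fit_fem_frame(
    frame: pd.DataFrame,
    exposures: Sequence[str],
    method: str = "first-difference",
) -> pd.DataFrame:
    """Fit the differenced design and return tidy exposure estimates.

    ``method='within'`` reconstructs the two-wave long form and applies the
    within (demeaning) transformation instead; for two waves the two
    estimators coincide to machine precision.

    Non-exposure columns with zero variance (time-constant terms that
    differenced to zero) are dropped with a warning; an all-zero exposure
    delta raises :class:`RankDeficiencyError` naming the term.
    """
    y = frame["d_y"].astype(float)
    X = frame.drop(columns=["d_y"]).astype(float)

    for e in exposures:
        if X[e].nunique() <= 1:
            raise RankDeficiencyError(
                f"exposure {e!r} has no within-person variation")
    const_cols = [c for c in X.columns if c not in exposures and X[c].nunique() <= 1]
    if const_cols:
        warnings.warn(f"dropping constant terms from differenced design: {const_cols}",
                      stacklevel=2)
        X = X.drop(columns=const_cols)

    if method == "within":
        # within (demeaning) transformation of the implied two-wave long form:
        # person-demeaned values are -/+ half the difference, and the demeaned
        # wave indicator (-1/2, +1/2) absorbs the period effect that plays the
        # intercept's role in the first-difference form.
        yl = pd.concat([-(y / 2), y / 2], ignore_index=True)
        Xl = pd.concat([-(X / 2), X / 2], ignore_index=True)
        wave_c = np.r_[np.full(len(X), -0.5), np.full(len(X), 0.5)]
        design = Xl.assign(_wave=wave_c)
        res = sm.OLS(yl, design).fit()
        params, bse, nobs = res.params, res.bse, len(X)
    else:
        design = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            _, R = np.linalg.qr(design.to_numpy())
            suspect = [design.columns[i] for i in range(design.shape[1])
                       if abs(R[i, i]) < 1e-8] if R.shape[0] >= design.shape[1] else list(design.columns)
            raise RankDeficiencyError(f"collinear terms in differenced design: {suspect}")
        res = sm.OLS(y, design).fit(cov_type="HC1")
        params, bse, nobs = res.params, res.bse, int(res.nobs)

    rows = []
    for e in exposures:
        beta, se = float(params[e]), float(bse[e])
        rows.append({"term": e, "beta": beta, "se": se,
                     "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se,
                     "n": nobs})
    return pd.DataFrame(rows)


def fit_fem(
    data: pd.DataFrame,
    ba_results: pd.DataFrame,
    change_records: pd.DataFrame,
    spec: FEMSpec,
    method: str = "first-difference",
) -> pd.DataFrame:
    """End-to-end FEM fit for one spec; tidy rows per exposure term."""
    frame = build_difference_frame(data, ba_results, change_records, spec)
    res = fit_fem_frame(frame, EXPOSURE_MODES[spec.exposure_mode], method=method)
    res.insert(0, "panel", spec.outcome_panel)
    res.insert(1, "exposure_mode", spec.exposure_mode)
    res["variant"] = spec.variant
    return res


def subgroup_q_test(betas: Sequence[float], ses: Sequence[float],
                    alpha: float = 0.1) -> dict:
    """Cochran's Q across stratum estimates.

    Q = sum w_i (beta_i - beta_w)^2 with w_i = 1/se_i^2 and beta_w the
    inverse-variance mean; p from chi-square with (k-1) df; heterogeneity is
    flagged at p < alpha (default 0.1).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least two strata")
    if np.any(s <= 0):
        raise ValueError("every stratum needs a positive SE")
    w = 1.0 / s**2
    b_w = float((w * b).sum() / w.sum())
    q = float((w * (b - b_w) ** 2).sum())
    df = len(b) - 1
    p = float(stats.chi2.sf(q, df))
    return {"Q": q, "df": df, "p_value": p, "pooled_beta": b_w,
            "significant": p < alpha, "alpha": alpha}


DEFAULT_SUBGROUPS: dict[str, callable] = {
    "sex": lambda base: base["sex"],
    "baseline_age": lambda base: np.where(base["age"] < 60, "<60", ">=60"),
    "ethnicity": lambda base: base["ethnicity"],
    "urbanicity": lambda base: base["urbanicity"],
}


def run_subgroup_analysis(
    data: pd.DataFrame,
    ba_results: pd.DataFrame,
    change_records: pd.DataFrame,
    spec: FEMSpec,
    subgroup: str,
    strata: Mapping[str, pd.Index] | None = None,
) -> dict:
    """Stratified FEM fits plus a per-term heterogeneity Q test.

    The stratifying variable is removed from the covariate lists of the
    stratum-specific models.
    """
    base = data[data["wave"] == 0].set_index("person_id")
    if strata is None:
        if subgroup not in DEFAULT_SUBGROUPS:
            raise ValueError(f"no default stratification for {subgroup!r}")
        lab = pd.Series(DEFAULT_SUBGROUPS[subgroup](base), index=base.index)
        strata = {str(v): lab.index[lab == v] for v in pd.unique(lab)}
    sub_spec = replace(
        spec,
        time_varying=[c for c in spec.time_varying if c != subgroup],
        time_invariant=[c for c in spec.time_invariant
                        if c != subgroup and not (subgroup == "baseline_age" and c == "baseline_age")],
        subgroup=subgroup,
    )
    fits = {}
    for name, idx in strata.items():
        d = data[data["person_id"].isin(idx)]
        fits[name] = fit_fem(d, ba_results, change_records, sub_spec)
    terms = fits[next(iter(fits))]["term"]
    q_tests = {}
    for t in terms:
        betas = [f.loc[f["term"] == t, "beta"].iloc[0] for f in fits.values()]
        ses = [f.loc[f["term"] == t, "se"].iloc[0] for f in fits.values()]
        q_tests[t] = subgroup_q_test(betas, ses)
    return {"subgroup": subgroup, "strata": fits, "q_tests": q_tests}


def run_sensitivity_suite(
    data: pd.DataFrame,
    ba_results: pd.DataFrame,
    base_spec: FEMSpec,
    primary_definitions: FactorDefinitions | None = None,
    overlays: Mapping[str, FactorDefinitions] | None = None,
) -> pd.DataFrame:
    """Primary fit plus the sensitivity variants, as one comparison table.

    Variants: one re-fit per swapped factor definition (lifestyle re-scored
    under the overlay), the standard (within-only) FEM, and the
    BMI-adjusted model.
    """
    primary_definitions = primary_definitions or FactorDefinitions()
    overlays = overlays if overlays is not None else ALTERNATIVE_DEFINITIONS

    def scored(defs):
        recs = build_hli_records(data, defs)
        return categorize_change(recs)

    primary_changes = scored(primary_definitions)
    out = []
    res = fit_fem(data, ba_results, primary_changes, base_spec)
    res["analysis"] = "primary"
    out.append(res)
    for factor, defs in overlays.items():
        res = fit_fem(data, ba_results, scored(defs), base_spec)
        res["analysis"] = f"alt-definition:{factor}"
        out.append(res)
    for variant in ("standard-fem", "bmi-adjusted"):
        res = fit_fem(data, ba_results, primary_changes, replace(base_spec, variant=variant))
        res["analysis"] = variant
        out.append(res)
    return pd.concat(out, ignore_index=True)
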