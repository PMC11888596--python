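"""Seeded two-wave synthetic cohort with known ground-truth aging effects.

The generator emulates the structure of a two-wave population cohort of
adults aged 30-79: sex-specific linear biomarker-age trends, five lifestyle
factors whose between-wave change frequencies match the study conditions
(smoking/alcohol >90% unchanged; diet and sleep changing in more than a
third of people; exercise in roughly 30%), and self-reported chronic
diseases linked to organ-specific latent aging. Every person carries a
latent acceleration per organ system:

    a_i(organ, wave) = g_i + o_i(organ) + sum_f beta_f * (1 - healthy_f(i, wave))

with shared frailty ``g_i``, organ-specific frailty ``o_i``, and additive
lifestyle effects ``beta_f`` in years. Biomarkers follow

    x_j = q_j + k_j * (CA + a_i) + eps,   eps ~ Normal(0, s_j^2)

sex-specifically. The ground truth (frailties, per-wave accelerations, the
intended healthy flags and the true effect sizes) is returned alongside the
table and is never consumed by any estimation code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from organclock import columns as C

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "simulate_change_panel",
    "write_cohort",
]

ORGANS = ["cardiopulmonary", "metabolic", "liver", "renal", "immune"]

#: marker -> organ membership (for latent-acceleration assignment)
MARKER_ORGAN = {
    "sbp": "cardiopulmonary", "pef": "cardiopulmonary",
    "ldl_ch": "metabolic", "hdl_ch": "metabolic", "hba1c": "metabolic",
    "tg": "metabolic", "whr": "metabolic",
    "ast": "liver", "ggt": "liver", "alp": "liver", "alb": "liver",
    "cr": "renal", "urea": "renal",
    "plt": "immune", "mcv": "immune",
}

# (intercept q, slope k per year, residual SD s), per sex. Values are chosen
# to give physiologically plausible means/spreads over ages 30-79; they are
# configuration, not claims about any real population.
DEFAULT_MARKER_SPECS: dict[str, dict[str, tuple[float, float, float]]] = {
    "sbp":    {"male": (105.0, 0.45, 12.0), "female": (98.0, 0.60, 12.0)},
    "whr":    {"male": (0.84, 0.0012, 0.045), "female": (0.78, 0.0016, 0.05)},
    "pef":    {"male": (660.0, -3.2, 60.0), "female": (480.0, -2.6, 50.0)},
    "ggt":    {"male": (24.0, 0.16, 14.0), "female": (16.0, 0.13, 9.0)},
    "alb":    {"male": (49.0, -0.055, 2.4), "female": (48.5, -0.05, 2.4)},
    "ldl_ch": {"male": (2.15, 0.012, 0.65), "female": (2.0, 0.016, 0.65)},
    "hdl_ch": {"male": (1.45, -0.0035, 0.28), "female": (1.6, -0.003, 0.3)},
    "tg":     {"male": (1.05, 0.009, 0.75), "female": (0.85, 0.011, 0.65)},
    "ast":    {"male": (20.0, 0.085, 6.5), "female": (18.0, 0.08, 5.5)},
    "cr":     {"male": (68.0, 0.16, 9.5), "female": (55.0, 0.13, 8.0)},
    "alp":    {"male": (58.0, 0.50, 17.0), "female": (50.0, 0.62, 17.0)},
    "urea":   {"male": (3.9, 0.032, 1.05), "female": (3.6, 0.034, 1.0)},
    "mcv":    {"male": (87.5, 0.065, 3.8), "female": (87.0, 0.07, 3.8)},
    "hba1c":  {"male": (4.75, 0.019, 0.48), "female": (4.7, 0.02, 0.48)},
    "plt":    {"male": (265.0, -0.85, 52.0), "female": (275.0, -0.8, 52.0)},
}

#: years of latent acceleration added while a factor is unhealthy; the
#: magnitudes mirror the comprehensive-clock effect profile used throughout
#: the recovery suites (protective change = minus these values)
DEFAULT_LIFESTYLE_EFFECTS = {
    "smoking": 0.13,
    "alcohol": 0.17,
    "diet": 0.15,
    "exercise": 0.16,
    "sleep": 0.02,
}

#: metabolic-clock effect profile (same convention): smoking dominates the
#: protective mixture (55% of the summed negative-direction magnitudes) and
#: unhealthy sleep carries a tiny opposite-signed effect
METABOLIC_LIFESTYLE_EFFECTS = {
    "smoking": 0.54,
    "alcohol": 0.18,
    "diet": 0.18,
    "exercise": 0.09,
    "sleep": -0.01,
}

#: baseline probability of being healthy on each factor; smoking and alcohol
#: are strongly sex-patterned in the emulated population
DEFAULT_BASELINE_HEALTHY = {
    "smoking": {"male": 0.35, "female": 0.93},
    "alcohol": {"male": 0.60, "female": 0.92},
    "diet": 0.50,
    "exercise": 0.45,
    "sleep": 0.55,
}

#: (P(unhealthy->healthy), P(healthy->unhealthy)) between waves
DEFAULT_TRANSITIONS = {
    "smoking": (0.010, 0.020),
    "alcohol": (0.040, 0.040),
    "diet": (0.370, 0.370),
    "exercise": (0.300, 0.300),
    "sleep": (0.350, 0.350),
}

#: disease -> (organ driving it, logistic intercept, slope per year of that
#: organ's acceleration). By default the driving acceleration is the
#: biomarker-implied one (the marker-composite deviation from the age norm):
#: diseases are caused by the measured physiology — glycaemia drives
#: diabetes, blood pressure drives CVD — not by an unobservable clock, and
#: this is what lets a biomarker clock validate against disease at all.
#: rheumatoid arthritis deliberately has a null link: the immune clock is
#: expected to fail disease validation.
DEFAULT_DISEASE_LINKS = {
    "cvd": ("cardiopulmonary", -1.60, 0.016),
    "diabetes": ("metabolic", -3.20, 0.060),
    "cancer": ("comprehensive", -4.80, 0.005),
    "chronic_bronchitis": ("cardiopulmonary", -3.30, 0.020),
    "chronic_hepatitis": ("liver", -3.50, 0.012),
    "rheumatoid_arthritis": ("immune", -3.50, 0.000),
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-wave cohort.

    Defaults are the study conditions emulated throughout the test suite:
    8396 people aged 30-79 at baseline, a ~2-year wave gap, and the default
    lifestyle-change frequencies above.
    """

    n_individuals: int = 8396
    seed: int = 1
    baseline_age_range: tuple[float, float] = (30.0, 76.0)
    wave_gap_mean: float = 2.0
    wave_gap_sd: float = 0.25
    wave_gap_bounds: tuple[float, float] = (1.0, 3.0)
    sex_ratio_female: float = 0.62
    frailty_sd: float = 2.5
    organ_frailty_sd: float = 1.5
    marker_specs: Mapping = field(default_factory=lambda: DEFAULT_MARKER_SPECS)
    lifestyle_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFESTYLE_EFFECTS))
    baseline_healthy: Mapping = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HEALTHY))
    transition_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS))
    disease_links: Mapping = field(default_factory=lambda: dict(DEFAULT_DISEASE_LINKS))
    disease_driver: str = "biomarker"   # "biomarker" | "latent"
    missing_rate: Mapping[str, float] | float = 0.0
    diet_component_noise: float = 0.12

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        lo, hi = self.baseline_age_range
        if not (30.0 <= lo < hi <= 79.0):
            raise ConfigurationError("baseline_age_range must lie within [30, 79]")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ConfigurationError("sex_ratio_female must be in [0, 1]")
        if self.frailty_sd < 0 or self.organ_frailty_sd < 0:
            raise ConfigurationError("frailty SDs must be nonnegative")
        if self.disease_driver not in ("biomarker", "latent"):
            raise ConfigurationError("disease_driver must be 'biomarker' or 'latent'")
        for marker, by_sex in self.marker_specs.items():
            for sex, (q, k, s) in by_sex.items():
                if s < 0:
                    raise ConfigurationError(f"noise SD for {marker}/{sex} must be >= 0")
        for factor, (p_uh, p_hu) in self.transition_probs.items():
            if not (0.0 <= p_uh <= 1.0 and 0.0 <= p_hu <= 1.0):
                raise ConfigurationError(f"transition probabilities for {factor} must be in [0, 1]")
        rates = self.missing_rate
        if isinstance(rates, (int, float)):
            rates = {"_": float(rates)}
        for m, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"missing rate for {m} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Latent state of a generated cohort; never read by estimation code."""

    person_id: np.ndarray
    shared_frailty: np.ndarray               # g_i, years
    organ_frailty: pd.DataFrame              # person x organ, years
    accel: pd.DataFrame                      # person_id, wave, organ accels + comprehensive
    healthy_flags: pd.DataFrame              # person_id, wave, intended 0/1 per factor
    lifestyle_effects: dict[str, float]
    qgc_weights_negative: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lifestyle_effects": self.lifestyle_effects,
            "qgc_weights_negative": self.qgc_weights_negative,
            "person_id": self.person_id.tolist(),
            "shared_frailty": self.shared_frailty.tolist(),
            "organ_frailty": self.organ_frailty.to_dict(orient="list"),
            "accel": self.accel.to_dict(orient="list"),
            "healthy_flags": self.healthy_flags.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


def _healthy_prob(spec, sex: np.ndarray) -> np.ndarray:
    if isinstance(spec, Mapping):
        return np.where(sex == "female", spec["female"], spec["male"])
    return np.full(sex.shape, float(spec))


def implied_negative_weights(effects: Mapping[str, float]) -> dict[str, float]:
    """Relative contribution of each protective (negative-direction) factor.

    A positive entry in ``effects`` means years added while unhealthy, so the
    change-effect of becoming healthy is ``-effects[f]``; the negative-group
    mixture weight is its share of the summed protective magnitudes.
    """
    neg = {f: abs(v) for f, v in effects.items() if v > 0}
    total = sum(neg.values())
    if total == 0:
        return {}
    return {f: v / total for f, v in neg.items()}


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a two-wave cohort table and its ground truth.

    Returns a long-format table (two rows per person, columns per
    :mod:`organclock.columns`) and the :class:`GroundTruth` that produced it.
    Identical config + seed gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    pid = np.arange(n)

    sex = np.where(rng.random(n) < config.sex_ratio_female, "female", "male")
    lo, hi = config.baseline_age_range
    age0 = rng.uniform(lo, hi, n)
    a, b = config.wave_gap_bounds
    if config.wave_gap_sd > 0:
        gap = stats.truncnorm.rvs(
            (a - config.wave_gap_mean) / config.wave_gap_sd,
            (b - config.wave_gap_mean) / config.wave_gap_sd,
            loc=config.wave_gap_mean, scale=config.wave_gap_sd,
            size=n, random_state=rng)
    else:
        gap = np.full(n, config.wave_gap_mean)
    age1 = age0 + gap

    # latent frailty
    g = rng.normal(0.0, config.frailty_sd, n)
    o = {org: rng.normal(0.0, config.organ_frailty_sd, n) for org in ORGANS}

    # intended healthy flags: Bernoulli baseline, Markov transition to wave 1
    flags0, flags1 = {}, {}
    for f in C.LIFESTYLE_FACTORS:
        p0 = _healthy_prob(config.baseline_healthy[f], sex)
        h0 = (rng.random(n) < p0).astype(int)
        p_uh, p_hu = config.transition_probs[f]
        u = rng.random(n)
        h1 = np.where(h0 == 1, (u >= p_hu).astype(int), (u < p_uh).astype(int))
        flags0[f], flags1[f] = h0, h1

    effects = dict(config.lifestyle_effects)
    burden0 = sum(effects[f] * (1 - flags0[f]) for f in C.LIFESTYLE_FACTORS)
    burden1 = sum(effects[f] * (1 - flags1[f]) for f in C.LIFESTYLE_FACTORS)

    accel = {0: {}, 1: {}}
    for org in ORGANS:
        accel[0][org] = g + o[org] + burden0
        accel[1][org] = g + o[org] + burden1
    accel[0]["comprehensive"] = g + burden0
    accel[1]["comprehensive"] = g + burden1

    # biomarkers: x = q + k*(CA + organ accel) + noise, per sex
    rows = {0: {}, 1: {}}
    ages = {0: age0, 1: age1}
    for marker in C.BIOMARKERS:
        organ = MARKER_ORGAN[marker]
        by_sex = config.marker_specs[marker]
        for w in (0, 1):
            x = np.empty(n)
            for s_name in ("male", "female"):
                q, k, s = by_sex[s_name]
                m = sex == s_name
                x[m] = q + k * (ages[w][m] + accel[w][organ][m]) + rng.normal(0, s, m.sum())
            rows[w][marker] = x

    # lifestyle raw fields consistent with the intended flags
    raw = {0: {}, 1: {}}
    for w, flags in ((0, flags0), (1, flags1)):
        # smoking: healthy = never; unhealthy split current/former, persistent
        smoke_unhealthy = np.where(rng.random(n) < 0.75, "current", "former")
        raw[w][C.SMOKING_STATUS] = np.where(flags["smoking"] == 1, "never", smoke_unhealthy)
        raw[w][C.DRINK_FREQ] = np.where(
            flags["alcohol"] == 1, rng.uniform(0.0, 0.99, n), rng.uniform(1.0, 7.0, n))
        u = rng.random(n)
        z = np.where(flags["diet"] == 1,
                     stats.norm.ppf(0.5 + 0.5 * u), stats.norm.ppf(0.5 * u))
        sigma = config.diet_component_noise
        scales = {"diet_vegetables": 5.6, "diet_legumes": 3.8, "diet_fruits": 4.8,
                  "diet_nuts": 2.5, "diet_whole_grains": 4.4, "diet_fish": 3.2,
                  "diet_red_meat": 4.1}
        for comp, log_mu in scales.items():
            sign = -1.0 if comp in C.DIET_REVERSE_COMPONENTS else 1.0
            raw[w][comp] = np.exp(log_mu + 0.4 * sign * z + rng.normal(0, sigma, n))
        ex_choice = rng.choice(C.EXERCISE_LEVELS[1:], size=n, p=[0.35, 0.35, 0.30])
        raw[w][C.EXERCISE_FREQ] = np.where(flags["exercise"] == 1, ex_choice, "never")
        bad_sleep = np.where(rng.random(n) < 0.6,
                             rng.uniform(4.5, 6.9, n), rng.uniform(8.2, 9.5, n))
        raw[w][C.SLEEP_HOURS] = np.where(
            flags["sleep"] == 1, rng.uniform(7.0, 8.0, n), bad_sleep)

    # covariates
    ethnicity = rng.choice(["majority", "minority"], n, p=[0.61, 0.39])
    urbanicity = rng.choice(["urban", "rural"], n, p=[0.36, 0.64])
    education = rng.choice(
        ["no_schooling", "primary", "middle_high", "college"], n,
        p=[0.26, 0.24, 0.39, 0.11])
    occ_levels = ["primary_industry", "secondary_industry", "tertiary_industry", "unemployed"]
    occupation0 = rng.choice(occ_levels, n, p=[0.34, 0.06, 0.40, 0.20])
    reshuffle = rng.random(n) < 0.05
    occupation1 = np.where(reshuffle, rng.choice(occ_levels, n, p=[0.34, 0.06, 0.40, 0.20]),
                           occupation0)
    marital0 = np.where(rng.random(n) < 0.89, "married", "not_married")
    marital1 = np.where(rng.random(n) < 0.02,
                        np.where(marital0 == "married", "not_married", "married"), marital0)
    bev_levels = ["never", "former", "current"]
    beverage0 = rng.choice(bev_levels, n, p=[0.93, 0.005, 0.065])
    beverage1 = np.where(rng.random(n) < 0.03, rng.choice(bev_levels, n, p=[0.93, 0.005, 0.065]),
                         beverage0)

    def menopause(ages_w):
        out = np.full(n, "not_applicable", dtype=object)
        fem = sex == "female"
        stage = np.where(ages_w < 46 + rng.normal(0, 1.5, n), "premenopausal",
                         np.where(ages_w < 51 + rng.normal(0, 1.5, n),
                                  "perimenopausal", "postmenopausal"))
        out[fem] = stage[fem]
        return out

    bmi0 = 24.3 + 0.02 * (age0 - 50.0) + rng.normal(0, 3.2, n)
    bmi1 = bmi0 + rng.normal(0.2, 0.8, n)

    cov = {
        0: {
            "ethnicity": ethnicity, "urbanicity": urbanicity, "education": education,
            "occupation": occupation0, "marital": marital0,
            "energy_kcal": np.exp(rng.normal(7.47, 0.33, n)),
            "depression": (rng.random(n) < 0.05).astype(int),
            "anxiety": (rng.random(n) < 0.055).astype(int),
            "menopausal": menopause(age0), "beverage": beverage0,
            "supplement": (rng.random(n) < 0.17).astype(int),
            C.BMI: bmi0,
        },
        1: {
            "ethnicity": ethnicity, "urbanicity": urbanicity, "education": education,
            "occupation": occupation1, "marital": marital1,
            "energy_kcal": np.exp(rng.normal(7.31, 0.34, n)),
            "depression": (rng.random(n) < 0.035).astype(int),
            "anxiety": (rng.random(n) < 0.03).astype(int),
            "menopausal": menopause(age1), "beverage": beverage1,
            "supplement": (rng.random(n) < 0.17).astype(int),
            C.BMI: bmi1,
        },
    }

    # diseases: logistic in the linked organ's baseline acceleration; chronic
    # flags carry forward with a small incidental hazard at wave 1. The
    # driving acceleration is by default the biomarker-implied one (exact
    # inverse-regression composite under the true marker model), so that
    # disease reflects measured physiology.
    if config.disease_driver == "biomarker":
        panel_of = {org: [m for m, o in MARKER_ORGAN.items() if o == org] for org in ORGANS}
        panel_of["comprehensive"] = list(C.BIOMARKERS)
        driver = {}
        for org, members in panel_of.items():
            num = np.zeros(n)
            den = np.zeros(n)
            for m in members:
                by_sex = config.marker_specs[m]
                for s_name in ("male", "female"):
                    q, k, s = by_sex[s_name]
                    s = max(s, 1e-8)
                    msk = sex == s_name
                    resid = rows[0][m][msk] - q - k * age0[msk]
                    num[msk] += resid * k / s**2
                    den[msk] += (k / s) ** 2
            driver[org] = num / den
    else:
        driver = {org: accel[0][org] for org in ORGANS + ["comprehensive"]}
    disease = {0: {}, 1: {}}
    for dz, (organ, alpha, beta) in config.disease_links.items():
        lin = alpha + beta * driver[organ]
        p = 1.0 / (1.0 + np.exp(-lin))
        d0 = (rng.random(n) < p).astype(int)
        d1 = np.maximum(d0, (rng.random(n) < 0.02).astype(int))
        disease[0][dz], disease[1][dz] = d0, d1

    frames = []
    for w in (0, 1):
        df_w = pd.DataFrame({"person_id": pid, "wave": w, C.AGE: ages[w], C.SEX: sex})
        for name, arr in {**rows[w], **raw[w], **cov[w], **disease[w]}.items():
            df_w[name] = arr
        frames.append(df_w)
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["person_id", "wave"], kind="stable").reset_index(drop=True)

    rates = config.missing_rate
    if isinstance(rates, (int, float)):
        rates = {m: float(rates) for m in C.BIOMARKERS}
    if any(r > 0 for r in rates.values()):
        df = inject_missingness(df, rates, seed=int(rng.integers(2**31 - 1)))

    accel_df = pd.concat([
        pd.DataFrame({"person_id": pid, "wave": w,
                      **{org: accel[w][org] for org in ORGANS + ["comprehensive"]}})
        for w in (0, 1)], ignore_index=True)
    flags_df = pd.concat([
        pd.DataFrame({"person_id": pid, "wave": w,
                      **{f"healthy_{f}": fl[f] for f in C.LIFESTYLE_FACTORS}})
        for w, fl in ((0, flags0), (1, flags1))], ignore_index=True)

    truth = GroundTruth(
        person_id=pid,
        shared_frailty=g,
        organ_frailty=pd.DataFrame(o),
        accel=accel_df,
        healthy_flags=flags_df,
        lifestyle_effects=effects,
        qgc_weights_negative=implied_negative_weights(effects),
    )
    return df, truth


def inject_missingness(
    data: pd.DataFrame, rates: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Set marker values missing completely at random at per-column rates."""
    for col, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"missing rate for {col} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = data.copy()
    for col, r in rates.items():
        if r <= 0 or col not in out.columns:
            continue
        mask = rng.random(len(out)) < r
        out.loc[mask, col] = np.nan
    return out


def simulate_change_panel(
    n: int,
    effects: Mapping[str, float],
    seed: int,
    change_probs: Mapping[str, float] | None = None,
    baseline_healthy: Mapping[str, float] | None = None,
    noise_sd: float = 2.0,
    n_noise_covariates: int = 2,
) -> pd.DataFrame:
    """Directly simulate a person-level differenced panel for recovery tests.

    ``effects`` are signed change-effects in years per factor: the expected
    shift in BA-acceleration change when that factor's healthy flag rises by
    one. The outcome is ``d_y = sum_f effects[f] * d_<f> + Normal(0, noise_sd)``
    plus nothing else, so the fixed-effects and mixture estimators can be
    checked against exact truth without the biomarker layer.
    """
    rng = np.random.default_rng(seed)
    change_probs = dict(change_probs or
                        {f: p_uh for f, (p_uh, _) in DEFAULT_TRANSITIONS.items()})
    baseline_healthy = dict(baseline_healthy or
                            {f: 0.5 for f in C.LIFESTYLE_FACTORS})
    out = pd.DataFrame({"person_id": np.arange(n)})
    d_y = rng.normal(0.0, noise_sd, n)
    for f in effects:
        h0 = (rng.random(n) < baseline_healthy[f]).astype(int)
        p = change_probs[f]
        u = rng.random(n)
        h1 = np.where(u < p, 1 - h0, h0)
        d = h1 - h0
        out[f"d_{f}"] = d
        d_y = d_y + effects[f] * d
    for j in range(n_noise_covariates):
        out[f"d_cov{j}"] = rng.normal(0.0, 1.0, n)
    out["d_y"] = d_y
    return out


def demo_config(n: int = 2000, seed: int = 1) -> CohortConfig:
    """High-signal demonstration configuration for end-to-end runs.

    The study-condition defaults put realistic measurement noise on the
    markers, which (as in real cohorts) leaves single-factor change effects
    of ~0.1-0.2 years far below the detection floor of a two-wave panel.
    For a qualitative end-to-end demonstration — where the point is that
    every estimated sign matches a clearly-negative simulated truth — this
    profile shrinks marker noise five-fold and uses effects of 1-2 years,
    scaling disease slopes to keep the biomarker-driver scale comparable.
    """
    specs = {
        m: {s: (q, k, sd * 0.2) for s, (q, k, sd) in by_sex.items()}
        for m, by_sex in DEFAULT_MARKER_SPECS.items()
    }
    links = {dz: (org, a, b * 5.0) for dz, (org, a, b) in DEFAULT_DISEASE_LINKS.items()}
    return CohortConfig(
        n_individuals=n,
        seed=seed,
        marker_specs=specs,
        lifestyle_effects={"smoking": 2.0, "alcohol": 1.5, "diet": 1.8,
                           "exercise": 1.6, "sleep": 1.0},
        disease_links=links,
    )


def write_cohort(df: pd.DataFrame, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the cohort as UTF-8 CSV and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "cohort.csv", index=False)
    truth.to_json(out / "ground_truth.json")
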