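"""Klemera-Doubal biological age for the comprehensive and organ panels.

Each biomarker j is regressed on chronological age within a sex stratum,
x_j = q_j + k_j * CA, with residual SD s_j. The uncorrected biological age
of a person with marker vector x is the precision-weighted average of the
per-marker inverse-regression estimates,

    BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j (k_j / s_j)^2 ,

and the noise-corrected (CA-anchored) estimator shrinks it toward CA:

    BA_EC = ( sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 )
            / ( sum_j (k_j / s_j)^2 + 1 / s_BA^2 ) ,

where s_BA^2 is the population variance of true biological age around CA,
estimated from the variance of BA_E - CA minus the model-implied estimator
dispersion. BA acceleration is BA - CA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from organclock import columns as C

__all__ = [
    "DEFAULT_PANELS",
    "KDMParams",
    "MarkerFit",
    "FittingError",
    "ScreeningError",
    "screen_biomarkers",
    "fit_kdm",
    "fit_kdm_all",
    "estimate_ba",
    "score_dataset",
    "load_panels",
]

log = logging.getLogger(__name__)

#: shipped panel definitions: 15-marker comprehensive clock + five organ systems
DEFAULT_PANELS: dict[str, list[str]] = {
    "comprehensive": list(C.BIOMARKERS),
    "cardiopulmonary": ["sbp", "pef"],
    "metabolic": ["ldl_ch", "hdl_ch", "hba1c", "tg", "whr"],
    "liver": ["ast", "ggt", "alp", "alb"],
    "renal": ["cr", "urea"],
    "immune": ["plt", "mcv"],
}

_S_FLOOR = 1e-8       # residual-SD floor for (near-)noiseless markers
_SBA2_FLOOR = 1e-2    # floor on s_BA^2, years^2


class FittingError(ValueError):
    """A marker cannot support the age regression (e.g. zero slope)."""


class ScreeningError(ValueError):
    """No biomarker survives the screening rules."""


@dataclass(frozen=True)
class MarkerFit:
    q: float   # intercept, marker units
    k: float   # slope, marker units / year
    s: float   # residual SD, marker units
    r: float   # Pearson correlation with age


@dataclass
class KDMParams:
    """Fitted sex-stratum parameters for one biomarker panel."""

    panel: str
    sex: str
    markers: dict[str, MarkerFit]
    s_ba: float                      # years
    r_char: float                    # information-weighted mean |r|
    age_range: tuple[float, float]   # training ages, years
    n_train: int = 0

    def to_dict(self) -> dict:
        return {
            "panel": self.panel, "sex": self.sex,
            "markers": {m: vars(f) for m, f in self.markers.items()},
            "s_ba": self.s_ba, "r_char": self.r_char,
            "age_range": list(self.age_range), "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KDMParams":
        return cls(
            panel=d["panel"], sex=d["sex"],
            markers={m: MarkerFit(**f) for m, f in d["markers"].items()},
            s_ba=d["s_ba"], r_char=d["r_char"],
            age_range=tuple(d["age_range"]), n_train=d.get("n_train", 0))


def screen_biomarkers(
    data: pd.DataFrame,
    candidates: Iterable[str] | None = None,
    max_missing: float = 0.30,
    min_age_correlation: float = 0.10,
) -> list[str]:
    """Keep markers with missingness < ``max_missing`` and a consistent,
    sufficiently strong age correlation in both sex strata.

    Raises :class:`ScreeningError` when nothing survives.
    """
    candidates = list(candidates) if candidates is not None else list(C.BIOMARKERS)
    kept = []
    for m in candidates:
        col = data[m]
        if col.isna().mean() >= max_missing:
            continue
        rs = []
        ok = True
        for sex, grp in data.groupby(C.SEX):
            sub = grp[[C.AGE, m]].dropna()
            if len(sub) < 3 or sub[m].std() == 0:
                ok = False
                break
            r = float(np.corrcoef(sub[C.AGE], sub[m])[0, 1])
            rs.append(r)
        if not ok or len(rs) < 2:
            continue
        if all(abs(r) >= min_age_correlation for r in rs) and len({np.sign(r) for r in rs}) == 1:
            kept.append(m)
    if not kept:
        raise ScreeningError("no biomarker passed the missingness/age-correlation screen")
    return kept


def _ba_e_components(
    data: pd.DataFrame, markers: Mapping[str, MarkerFit]
) -> tuple[np.ndarray, float]:
    num = np.zeros(len(data))
    den = 0.0
    for m, f in markers.items():
        s = max(f.s, _S_FLOOR)
        x = data[m].to_numpy(dtype=float)
        num = num + (x - f.q) * f.k / s**2
        den += (f.k / s) ** 2
    return num, den


def fit_kdm(
    training: pd.DataFrame,
    panel_markers: Iterable[str],
    sex: str,
    panel_name: str = "custom",
) -> KDMParams:
    """Fit sex-stratum KDM parameters on (baseline-wave) training records.

    Per-marker OLS of the marker on age gives (q, k, s); s_BA^2 is the
    variance of BA_E - CA in the training data minus the Klemera-Doubal
    dispersion term (1 - r_char^2)/r_char^2 * range^2 / (12 m), floored at
    a small positive constant.
    """
    markers = list(panel_markers)
    sub = training[training[C.SEX] == sex]
    sub = sub.dropna(subset=[C.AGE] + markers)
    ages = sub[C.AGE].to_numpy(dtype=float)
    if len(np.unique(ages)) < 2:
        raise FittingError("training data needs at least two distinct ages")

    fits: dict[str, MarkerFit] = {}
    for m in markers:
        x = sub[m].to_numpy(dtype=float)
        k, q = np.polyfit(ages, x, 1)
        resid = x - (q + k * ages)
        dof = max(len(x) - 2, 1)
        s = float(np.sqrt((resid**2).sum() / dof))
        sd_x = x.std()
        if sd_x == 0 or abs(k) < 1e-12:
            raise FittingError(f"marker {m!r} has no age slope in stratum {sex!r}")
        r = float(np.corrcoef(ages, x)[0, 1])
        fits[m] = MarkerFit(q=float(q), k=float(k), s=s, r=r)

    w = np.array([(f.k / max(f.s, _S_FLOOR)) ** 2 for f in fits.values()])
    r_abs = np.array([abs(f.r) for f in fits.values()])
    r_char = float((w * r_abs).sum() / w.sum())

    num, den = _ba_e_components(sub, fits)
    ba_e = num / den
    age_lo, age_hi = float(ages.min()), float(ages.max())
    m_count = len(fits)
    if r_char > 0:
        dispersion = ((1 - r_char**2) / r_char**2) * (age_hi - age_lo) ** 2 / (12 * m_count)
    else:
        dispersion = np.inf
    s_ba2 = float(np.mean((ba_e - ages) ** 2) - dispersion)
    s_ba = float(np.sqrt(max(s_ba2, _SBA2_FLOOR)))
    return KDMParams(panel=panel_name, sex=sex, markers=fits, s_ba=s_ba,
                     r_char=r_char, age_range=(age_lo, age_hi), n_train=len(sub))


def fit_kdm_all(
    training: pd.DataFrame,
    panels: Mapping[str, Iterable[str]] | None = None,
    train_wave: int | None = 0,
) -> dict[tuple[str, str], KDMParams]:
    """Fit every panel in both sex strata; keyed by (panel, sex).

    Training defaults to baseline-wave records so both waves are scored
    with one parameter set and within-person change stays interpretable.
    """
    panels = panels or DEFAULT_PANELS
    if train_wave is not None:
        training = training[training["wave"] == train_wave]
    out = {}
    for panel, markers in panels.items():
        for sex in ("male", "female"):
            out[(panel, sex)] = fit_kdm(training, markers, sex, panel_name=panel)
    return out


def estimate_ba(
    data: pd.DataFrame,
    params: KDMParams,
    use_ca_anchor: bool = True,
) -> pd.DataFrame:
    """Score records of the parameter stratum: BA and BA acceleration.

    Records with any missing panel marker are skipped (complete-case) with
    a logged count. Returns person_id, wave, panel, ba, ba_accel.
    """
    markers = list(params.markers)
    sub = data[data[C.SEX] == params.sex]
    complete = sub.dropna(subset=[C.AGE] + markers)
    n_skipped = len(sub) - len(complete)
    if n_skipped:
        log.info("estimate_ba[%s/%s]: skipped %d records with missing markers",
                 params.panel, params.sex, n_skipped)
    num, den = _ba_e_components(complete, params.markers)
    ca = complete[C.AGE].to_numpy(dtype=float)
    if use_ca_anchor:
        ba = (num + ca / params.s_ba**2) / (den + 1.0 / params.s_ba**2)
    else:
        ba = num / den
    return pd.DataFrame({
        "person_id": complete["person_id"].to_numpy(),
        "wave": complete["wave"].to_numpy(),
        "panel": params.panel,
        "ba": ba,
        "ba_accel": ba - ca,
    })


def score_dataset(
    data: pd.DataFrame,
    params_by_stratum: Mapping[tuple[str, str], KDMParams],
    use_ca_anchor: bool = True,
) -> pd.DataFrame:
    """Score all panels and sex strata into one tidy BA table."""
    parts = [estimate_ba(data, p, use_ca_anchor=use_ca_anchor)
             for p in params_by_stratum.values()]
    return (pd.concat(parts, ignore_index=True)
            .sort_values(["panel", "person_id", "wave"], kind="stable")
            .reset_index(drop=True))


def load_panels(path: str | Path) -> dict[str, list[str]]:
    """Read panel definitions (name -> marker list) from YAML."""
    with open(path) as fh:
        panels = yaml.safe_load(fh)
    return {name: list(markers) for name, markers in panels.items()}
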