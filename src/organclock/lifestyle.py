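"""Healthy Lifestyle Index scoring: five binary factors, modified aMED, HLI.

The index sums five binary healthiness indicators — never smoking,
non-regular drinking (< 1 occasion/week), diet quality at or above the
population-median modified aMED, regular leisure exercise (at least
1-2 times/week), and 7-8 hours of sleep — giving an HLI of 0-5, dichotomised
at 4-5 = healthy. The diet score is an alternate Mediterranean diet score
with the alcohol item removed: 7 components, each scored 1-5 by quintile
rank within a same-wave reference population (protective components score
high when intake is high; red/processed meat when low), total 7-35.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from organclock import columns as C

__all__ = [
    "FactorDefinitions",
    "ALTERNATIVE_DEFINITIONS",
    "score_amed",
    "classify_factors",
    "compute_hli",
    "build_hli_records",
    "categorize_change",
]

AMED_MIN, AMED_MAX = 7, 35


@dataclass(frozen=True)
class FactorDefinitions:
    """Healthiness criteria for the five factors.

    The primary definitions are the study criteria; sensitivity analyses
    swap one field at a time (see :data:`ALTERNATIVE_DEFINITIONS`).
    """

    healthy_smoking_levels: frozenset = frozenset({"never"})
    alcohol_max_freq: float = 1.0            # healthy iff freq < this, times/week
    diet_quantile: float = 0.5               # healthy iff aMED >= this population quantile
    healthy_exercise_levels: frozenset = frozenset(
        {"1-2_per_week", "3-5_per_week", "daily"})
    sleep_range: tuple[float, float] = (7.0, 8.0)   # closed interval, hours

    def replacing(self, **kw) -> "FactorDefinitions":
        return replace(self, **kw)


#: one-factor-at-a-time overlays for the sensitivity suite: other common
#: health criteria (never/former smoking; <3 drinking occasions/week; diet in
#: the top 40%; exercise at least 3 times/week; 6-9 h sleep)
ALTERNATIVE_DEFINITIONS: dict[str, FactorDefinitions] = {
    "smoking": FactorDefinitions(healthy_smoking_levels=frozenset({"never", "former"})),
    "alcohol": FactorDefinitions(alcohol_max_freq=3.0),
    "diet": FactorDefinitions(diet_quantile=0.6),
    "exercise": FactorDefinitions(
        healthy_exercise_levels=frozenset({"3-5_per_week", "daily"})),
    "sleep": FactorDefinitions(sleep_range=(6.0, 9.0)),
}


def load_definitions(path=None) -> tuple[FactorDefinitions, dict[str, FactorDefinitions]]:
    """Read (primary, alternatives) criteria from YAML; defaults to the
    shipped definitions file."""
    import yaml

    if path is None:
        from importlib.resources import files
        text = (files("organclock") / "data" / "definitions.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)

    def build(d):
        kw = dict(d)
        for key in ("healthy_smoking_levels", "healthy_exercise_levels"):
            if key in kw:
                kw[key] = frozenset(kw[key])
        if "sleep_range" in kw:
            kw["sleep_range"] = tuple(kw["sleep_range"])
        return FactorDefinitions(**kw)

    primary = build(raw.get("primary", {}))
    alternatives = {f: build(d) for f, d in raw.get("alternatives", {}).items()}
    return primary, alternatives


def _midrank_percentile(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mid-rank empirical percentile of ``values`` within ``reference``.

    Ties get the midpoint of their rank span, so a degenerate (constant)
    reference maps everything to 0.5.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    n = len(ref)
    left = np.searchsorted(ref, values, side="left")
    right = np.searchsorted(ref, values, side="right")
    return (left + right) / (2.0 * n)


def _quintile_score(p: np.ndarray) -> np.ndarray:
    """Map percentiles to quintile scores 1-5 with right-closed bins."""
    breaks = np.array([0.2, 0.4, 0.6, 0.8])
    return 1 + (p[:, None] > breaks[None, :]).sum(axis=1)


def score_amed(
    diet: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    components: Iterable[str] = tuple(C.DIET_COMPONENTS),
    reverse: Iterable[str] = tuple(C.DIET_REVERSE_COMPONENTS),
) -> pd.Series:
    """Modified aMED (alcohol item removed): 7 components x 1-5, range 7-35.

    Each component is scored by quintile of its mid-rank percentile within
    ``reference`` (default: the scored population itself). Reverse-coded
    components score high when intake is low. Rows with any missing
    component get NaN (complete-case).

    Parameters
    ----------
    diet : rows to score, one column per component.
    reference : population defining the quintiles; defaults to ``diet``.
    """
    components = list(components)
    reverse = set(reverse)
    if reference is None:
        reference = diet
    if len(reference) == 0:
        raise ValueError("reference population must be nonempty")
    total = np.zeros(len(diet))
    missing = np.zeros(len(diet), dtype=bool)
    for comp in components:
        v = diet[comp].to_numpy(dtype=float)
        ref = reference[comp].dropna().to_numpy(dtype=float)
        missing |= np.isnan(v)
        p = _midrank_percentile(np.nan_to_num(v), ref)
        if comp in reverse:
            p = 1.0 - p
        total = total + _quintile_score(p)
    out = pd.Series(total, index=diet.index, name="amed")
    out[missing] = np.nan
    return out


def classify_factors(
    records: pd.DataFrame,
    definitions: FactorDefinitions = FactorDefinitions(),
    amed: pd.Series | None = None,
    amed_threshold: float | None = None,
) -> pd.DataFrame:
    """Binary healthiness flags for the five factors.

    ``amed`` defaults to scoring the records against themselves; the diet
    threshold defaults to the given quantile of ``amed`` over the same
    records (the analysis population at the record's own wave).
    """
    smoking = records[C.SMOKING_STATUS]
    known = {"never", "former", "current"}
    bad = set(smoking.dropna().unique()) - known
    if bad:
        raise ValueError(f"unknown smoking status levels: {sorted(bad)}")
    bad_ex = set(records[C.EXERCISE_FREQ].dropna().unique()) - set(C.EXERCISE_LEVELS)
    if bad_ex:
        raise ValueError(f"unknown exercise levels: {sorted(bad_ex)}")

    if amed is None:
        amed = score_amed(records[list(C.DIET_COMPONENTS)])
    if amed_threshold is None:
        amed_threshold = float(np.nanquantile(amed.to_numpy(dtype=float),
                                              definitions.diet_quantile))
    lo, hi = definitions.sleep_range
    flags = pd.DataFrame(index=records.index)
    flags["healthy_smoking"] = smoking.isin(definitions.healthy_smoking_levels).astype(int)
    flags["healthy_alcohol"] = (
        records[C.DRINK_FREQ] < definitions.alcohol_max_freq).astype(int)
    flags["healthy_diet"] = (amed >= amed_threshold).astype(int)
    flags["healthy_exercise"] = records[C.EXERCISE_FREQ].isin(
        definitions.healthy_exercise_levels).astype(int)
    flags["healthy_sleep"] = (
        (records[C.SLEEP_HOURS] >= lo) & (records[C.SLEEP_HOURS] <= hi)).astype(int)
    return flags


def compute_hli(flags: pd.DataFrame) -> pd.DataFrame:
    """HLI = sum of the five flags (0-5); 4-5 = healthy, 0-3 = unfavorable."""
    cols = [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS]
    vals = flags[cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("healthiness flags must be 0/1")
    out = flags.copy()
    out["hli"] = vals.sum(axis=1)
    out["hli_category"] = np.where(out["hli"] >= 4, "healthy", "unfavorable")
    return out


def build_hli_records(
    data: pd.DataFrame,
    definitions: FactorDefinitions = FactorDefinitions(),
) -> pd.DataFrame:
    """Score every person x wave: flags, aMED, HLI, HLI category.

    The diet quintiles and the median threshold are computed within each
    wave's population (per-wave pooled).
    """
    pieces = []
    for wave, grp in data.groupby("wave"):
        amed = score_amed(grp[list(C.DIET_COMPONENTS)])
        flags = classify_factors(grp, definitions, amed=amed)
        rec = compute_hli(flags)
        rec.insert(0, "person_id", grp["person_id"].to_numpy())
        rec.insert(1, "wave", wave)
        rec["amed"] = amed.to_numpy()
        pieces.append(rec)
    return pd.concat(pieces, ignore_index=True)


def _direction(delta: pd.Series) -> pd.Series:
    return pd.Series(
        np.select([delta > 0, delta < 0], ["healthier", "unhealthier"], "unchanged"),
        index=delta.index)


def categorize_change(hli_records: pd.DataFrame) -> pd.DataFrame:
    """Per-person between-wave change categories.

    For each factor: healthier iff unhealthy at baseline and healthy at the
    repeat (and vice versa). For HLI (range): by score comparison. For HLI
    (category): by healthy/unfavorable transition. Also emits the signed
    deltas used as model exposures.
    """
    wide = hli_records.pivot(index="person_id", columns="wave")
    out = pd.DataFrame(index=wide.index)
    for f in C.LIFESTYLE_FACTORS:
        col = f"healthy_{f}"
        delta = wide[(col, 1)] - wide[(col, 0)]
        out[f"d_{f}"] = delta
        out[f"change_{f}"] = _direction(delta)
    d_hli = wide[("hli", 1)] - wide[("hli", 0)]
    out["d_hli"] = d_hli
    out["change_hli_range"] = _direction(d_hli)
    cat = (wide[("hli_category", 1)] == "healthy").astype(int) - \
          (wide[("hli_category", 0)] == "healthy").astype(int)
    out["d_hli_category"] = cat
    out["change_hli_category"] = _direction(cat)
    return out.reset_index()
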