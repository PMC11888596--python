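"""Klemera-Doubal estimator: screening, fitting, the BA formulas."""

import numpy as np
import pandas as pd
import pytest

from organclock import columns as C
from organclock.kdm import (DEFAULT_PANELS, FittingError, KDMParams, MarkerFit,
                            ScreeningError, estimate_ba, fit_kdm, fit_kdm_all,
                            score_dataset, screen_biomarkers)
from organclock.synthetic import CohortConfig, generate_cohort


def _frame(ages, sex="female", **markers):
    n = len(ages)
    df = pd.DataFrame({"person_id": np.arange(n), "wave": 0,
                       C.AGE: ages, C.SEX: sex})
    for name, vals in markers.items():
        df[name] = vals
    return df


def _toy_params(qs, ks, ss, s_ba, sex="female", panel="toy"):
    markers = {f"m{i}": MarkerFit(q=q, k=k, s=s, r=0.5)
               for i, (q, k, s) in enumerate(zip(qs, ks, ss))}
    return KDMParams(panel=panel, sex=sex, markers=markers, s_ba=s_ba,
                     r_char=0.5, age_range=(30, 79))


class TestScreening:
    def test_high_missingness_excluded_and_null_marker_excluded(self):
        rng = np.random.default_rng(0)
        n = 5000
        ages = rng.uniform(30, 79, n)
        good = 5 + 0.5 * ages + rng.normal(0, 5, n)
        null = rng.normal(0, 1, n)  # no age signal by construction
        gappy = good.copy()
        gappy[rng.random(n) < 0.35] = np.nan
        df = _frame(ages, sex=rng.choice(["male", "female"], n),
                    good=good, null=null, gappy=gappy)
        kept = screen_biomarkers(df, ["good", "null", "gappy"])
        assert kept == ["good"]

    def test_analytic_correlation_marker_retained(self):
        """A marker with slope k and noise s has age correlation
        k*SD(age)/sqrt(k^2 Var(age) + s^2); build one just above the 0.10
        screen threshold and confirm retention."""
        rng = np.random.default_rng(1)
        n = 5000
        ages = rng.uniform(30, 79, n)
        k, s = 0.5, 10.0
        r_expected = k * ages.std() / np.sqrt(k**2 * ages.var() + s**2)
        assert r_expected > 0.10
        x = 1 + k * ages + rng.normal(0, s, n)
        df = _frame(ages, sex=rng.choice(["male", "female"], n), m=x)
        assert screen_biomarkers(df, ["m"]) == ["m"]

    def test_empty_survivor_set_raises(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(30, 79, 500)
        df = _frame(ages, sex=rng.choice(["male", "female"], 500),
                    junk=rng.normal(0, 1, 500))
        with pytest.raises(ScreeningError):
            screen_biomarkers(df, ["junk"])


class TestFitting:
    def test_noiseless_line_recovers_exactly(self):
        ages = np.linspace(30, 79, 200)
        df = _frame(ages, m=10 + 0.2 * ages)
        params = fit_kdm(df, ["m"], "female")
        fit = params.markers["m"]
        assert fit.q == pytest.approx(10.0, abs=1e-8)
        assert fit.k == pytest.approx(0.2, abs=1e-10)
        assert fit.s < 1e-8

    def test_constant_marker_raises_naming_it(self):
        ages = np.linspace(30, 79, 100)
        df = _frame(ages, flat=np.full(100, 5.0))
        with pytest.raises(FittingError, match="flat"):
            fit_kdm(df, ["flat"], "female")

    def test_parameter_recovery_within_monte_carlo_error(self):
        """OLS on n=10000 recovers (q, k, s) within 3 sampling SEs."""
        rng = np.random.default_rng(3)
        n = 10000
        ages = rng.uniform(30, 79, n)
        q, k, s = 50.0, 0.4, 8.0
        df = _frame(ages, m=q + k * ages + rng.normal(0, s, n))
        fit = fit_kdm(df, ["m"], "female").markers["m"]
        se_k = s / (ages.std() * np.sqrt(n))
        se_q = s * np.sqrt(1 / n + ages.mean()**2 / (n * ages.var()))
        se_s = s / np.sqrt(2 * n)
        assert abs(fit.k - k) < 3 * se_k
        assert abs(fit.q - q) < 3 * se_q
        assert abs(fit.s - s) < 3 * se_s

    def test_s_ba_matches_direct_formula_evaluation(self):
        """Single marker: s_BA^2 from the fitted params equals an
        independent evaluation of the variance decomposition on the data."""
        rng = np.random.default_rng(4)
        n = 8000
        ages = rng.uniform(30, 79, n)
        q, k, s = 20.0, 0.5, 6.0
        x = q + k * ages + rng.normal(0, s, n)
        df = _frame(ages, m=x)
        params = fit_kdm(df, ["m"], "female")
        # independent evaluation from raw data
        kk, qq = np.polyfit(ages, x, 1)
        resid_sd = np.sqrt(((x - qq - kk * ages)**2).sum() / (n - 2))
        ba_e = (x - qq) / kk
        r = abs(np.corrcoef(ages, x)[0, 1])
        disp = (1 - r**2) / r**2 * (ages.max() - ages.min())**2 / 12
        expected = np.sqrt(max(np.mean((ba_e - ages)**2) - disp, 1e-2))
        assert params.s_ba == pytest.approx(expected, rel=1e-6)

    def test_sex_strata_fit_independently(self):
        rng = np.random.default_rng(5)
        n = 1000
        ages = np.tile(rng.uniform(30, 79, n), 2)
        sex = np.r_[["male"] * n, ["female"] * n]
        x = np.r_[5 + 0.3 * ages[:n], 8 + 0.5 * ages[n:]] + rng.normal(0, 2, 2 * n)
        df = _frame(ages, sex=sex, m=x)
        full = fit_kdm(df, ["m"], "male")
        # permuting rows within the female stratum leaves male params alone
        fem_rows = df[df.sex == "female"].sample(frac=1, random_state=0)
        shuffled = pd.concat([df[df.sex == "male"], fem_rows])
        assert fit_kdm(shuffled, ["m"], "male").markers["m"] == full.markers["m"]


class TestEstimator:
    def test_single_marker_on_regression_line_inverts_exactly(self):
        params = _toy_params([10], [0.2], [1.0], s_ba=5.0)
        df = _frame(np.array([50.0]), m0=np.array([10 + 0.2 * 50]))
        res = estimate_ba(df, params, use_ca_anchor=False)
        assert res["ba"].iloc[0] == pytest.approx(50.0, abs=1e-10)
        assert res["ba_accel"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_two_marker_hand_oracle(self):
        """q=(10,100), k=(0.2,-1), s=(1,5), x=(22,45), CA=50: the weighted
        inverse-regression estimates are 60 and 55 with equal weights 0.04,
        so BA_E = 57.5; the anchored estimate sits strictly between."""
        params = _toy_params([10, 100], [0.2, -1.0], [1.0, 5.0], s_ba=10.0)
        df = _frame(np.array([50.0]), m0=np.array([22.0]), m1=np.array([45.0]))
        ba_e = estimate_ba(df, params, use_ca_anchor=False)["ba"].iloc[0]
        num = (22 - 10) * 0.2 / 1 + (45 - 100) * (-1) / 25
        den = 0.2**2 + (1 / 5)**2
        assert ba_e == pytest.approx(num / den, abs=1e-10)
        assert ba_e == pytest.approx(57.5, abs=1e-10)
        ba_ec = estimate_ba(df, params, use_ca_anchor=True)["ba"].iloc[0]
        assert 50.0 < ba_ec < ba_e
        assert ba_ec == pytest.approx((num + 50 / 100) / (den + 1 / 100), abs=1e-10)

    def test_anchor_limits(self):
        df = _frame(np.array([50.0]), m0=np.array([22.0]), m1=np.array([45.0]))
        qs, ks, ss = [10, 100], [0.2, -1.0], [1.0, 5.0]
        ba_e = estimate_ba(df, _toy_params(qs, ks, ss, 10.0),
                           use_ca_anchor=False)["ba"].iloc[0]
        loose = estimate_ba(df, _toy_params(qs, ks, ss, 1e8))["ba"].iloc[0]
        tight = estimate_ba(df, _toy_params(qs, ks, ss, 1e-6))["ba"].iloc[0]
        assert loose == pytest.approx(ba_e, abs=1e-6)
        assert tight == pytest.approx(50.0, abs=1e-6)

    def test_ba_e_is_convex_combination_of_inverse_estimates(self):
        rng = np.random.default_rng(6)
        params = _toy_params([10, 100, 3], [0.2, -1.0, 0.05], [1.0, 5.0, 0.4],
                             s_ba=8.0)
        for _ in range(20):
            x = {f"m{i}": np.array([f.q + f.k * rng.uniform(20, 90)])
                 for i, f in enumerate(params.markers.values())}
            df = _frame(np.array([55.0]), **x)
            ba_e = estimate_ba(df, params, use_ca_anchor=False)["ba"].iloc[0]
            inv = [float((x[m][0] - f.q) / f.k) for m, f in params.markers.items()]
            assert min(inv) - 1e-9 <= ba_e <= max(inv) + 1e-9

    def test_monotone_in_each_marker_along_its_slope_sign(self):
        params = _toy_params([10, 100], [0.2, -1.0], [1.0, 5.0], s_ba=10.0)
        base = _frame(np.array([50.0]), m0=np.array([22.0]), m1=np.array([45.0]))
        up = base.assign(m0=base.m0 + 1)     # positive slope -> older
        down = base.assign(m1=base.m1 + 1)   # negative slope -> younger
        ba = lambda d: estimate_ba(d, params)["ba"].iloc[0]
        assert ba(up) > ba(base)
        assert ba(down) < ba(base)

    def test_records_with_missing_markers_are_skipped(self):
        params = _toy_params([10, 100], [0.2, -1.0], [1.0, 5.0], s_ba=10.0)
        df = _frame(np.array([50.0, 60.0]), m0=np.array([22.0, np.nan]),
                    m1=np.array([45.0, 40.0]))
        res = estimate_ba(df, params)
        assert len(res) == 1


class TestEndToEnd:
    def test_zero_noise_cohort_recovers_chronological_age(self):
        """With noiseless markers and no latent aging, every clock equals
        chronological age to 1e-8 years at both waves."""
        specs = {m: {s: (q, k, 0.0) for s, (q, k, sd) in by.items()}
                 for m, by in CohortConfig().marker_specs.items()}
        cfg = CohortConfig(n_individuals=400, seed=8, marker_specs=specs,
                           frailty_sd=0.0, organ_frailty_sd=0.0,
                           lifestyle_effects={f: 0.0 for f in C.LIFESTYLE_FACTORS})
        df, _ = generate_cohort(cfg)
        params = fit_kdm_all(df)
        ba = score_dataset(df, params)
        assert np.abs(ba["ba_accel"]).max() < 1e-8

    def test_default_panels_score_both_waves_for_everyone(self, study_scored):
        data, _, _, _, params, ba = study_scored
        assert set(ba["panel"]) == set(DEFAULT_PANELS)
        n = data["person_id"].nunique()
        assert len(ba) == 2 * n * len(DEFAULT_PANELS)
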