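"""Inhibition-kinetics estimators: IC50, Lineweaver-Burk, mode, Ki, reversibility."""

import numpy as np
import pandas as pd
import pytest

import bindkit as bk
from bindkit.datatypes import LineweaverFit
from bindkit.exceptions import (
    FitDegenerateError,
    IndeterminateIC50Error,
    NoInhibitionError,
    PreconditionError,
    ValidationError,
)
from bindkit.kinetics import (
    classify_mode,
    fit_competitive_global,
    fit_ki_secondary,
    fit_lineweaver,
    fit_michaelis_menten,
    logistic_inhibition,
)


def _lb_fits(mode, noise=0.0, seed=0, ki=0.46e-7):
    cfg = bk.SimulationConfig(seed=seed, noise_sd_rel=noise, ki_true=ki,
                              inhibition_mode=mode)
    ds = bk.simulate_kinetics(cfg)
    return [fit_lineweaver(ds, i) for i in ds.inhibitor_levels()], cfg


class TestIC50:
    def test_closed_loop_recovery(self, noiseless_config):
        df = bk.simulate_dose_response(noiseless_config)
        res = bk.estimate_ic50(df)
        assert res.ic50 == pytest.approx(noiseless_config.ic50_true, rel=1e-6)
        assert res.hill_slope == pytest.approx(noiseless_config.hill_slope, rel=1e-6)

    def test_exact_50pct_point_is_ic50(self):
        I = np.array([1e-6, 2e-6, 4e-6, 8e-6, 16e-6])
        pct = logistic_inhibition(I, 4e-6, 1.0)
        res = bk.estimate_ic50(pd.DataFrame({"inhibitor_M": I,
                                             "inhibition_pct": pct}))
        assert res.ic50 == pytest.approx(4e-6, rel=1e-8)

    def test_all_zero_inhibition_indeterminate(self):
        df = pd.DataFrame({"inhibitor_M": [1e-6, 2e-6, 4e-6, 8e-6],
                           "inhibition_pct": [0.0, 0.0, 0.0, 0.0]})
        with pytest.raises(IndeterminateIC50Error):
            bk.estimate_ic50(df)

    def test_never_crossing_50_indeterminate(self):
        df = pd.DataFrame({"inhibitor_M": [1e-6, 2e-6, 4e-6, 8e-6],
                           "inhibition_pct": [5.0, 10.0, 20.0, 40.0]})
        with pytest.raises(IndeterminateIC50Error):
            bk.estimate_ic50(df)

    def test_too_few_levels_rejected(self):
        df = pd.DataFrame({"inhibitor_M": [1e-6, 4e-6, 8e-6],
                           "inhibition_pct": [20.0, 55.0, 80.0]})
        with pytest.raises(PreconditionError):
            bk.estimate_ic50(df)

    def test_nonmonotone_warns(self):
        df = pd.DataFrame({"inhibitor_M": [1e-6, 2e-6, 4e-6, 8e-6, 16e-6],
                           "inhibition_pct": [30.0, 60.0, 40.0, 70.0, 90.0]})
        with pytest.warns(UserWarning):
            bk.estimate_ic50(df)


class TestLineweaverBurk:
    def test_uninhibited_recovery(self, noiseless_config):
        ds = bk.simulate_kinetics(noiseless_config)
        fit = fit_lineweaver(ds, 0.0)
        assert fit.km_app == pytest.approx(50e-6, rel=1e-9)
        assert fit.vmax_app == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_competitive_doubles_km_at_i_equals_ki(self):
        cfg = bk.SimulationConfig(seed=0, noise_sd_rel=0.0, ki_true=1e-7,
                                  inhibitor_grid=[0.0, 1e-7])
        ds = bk.simulate_kinetics(cfg)
        fit = fit_lineweaver(ds, 1e-7)
        assert fit.km_app == pytest.approx(2 * cfg.km_true, rel=1e-9)
        assert fit.vmax_app == pytest.approx(cfg.vmax_true, rel=1e-9)

    def test_two_points_rejected(self):
        df = pd.DataFrame({"substrate_M": [25e-6, 50e-6],
                           "inhibitor_M": [0.0, 0.0],
                           "velocity": [0.3, 0.5]})
        with pytest.raises(PreconditionError):
            fit_lineweaver(bk.KineticDataset(df), 0.0)

    def test_zero_velocity_excluded_with_warning(self):
        S = np.array([25e-6, 37.5e-6, 50e-6, 75e-6, 100e-6])
        v = 1.0 * S / (50e-6 + S)
        v[0] = 0.0
        df = pd.DataFrame({"substrate_M": S, "inhibitor_M": 0.0, "velocity": v})
        with pytest.warns(UserWarning):
            fit = fit_lineweaver(bk.KineticDataset(df), 0.0)
        assert fit.km_app == pytest.approx(50e-6, rel=1e-9)

    def test_matches_nonlinear_oracle_noiseless(self, noiseless_config):
        # reciprocal-transform OLS equals direct nonlinear least squares
        ds = bk.simulate_kinetics(noiseless_config)
        sub = ds.subset(0.0)
        km_nl, vmax_nl = fit_michaelis_menten(sub["substrate_M"], sub["velocity"])
        fit = fit_lineweaver(ds, 0.0)
        assert fit.km_app == pytest.approx(km_nl, rel=1e-6)
        assert fit.vmax_app == pytest.approx(vmax_nl, rel=1e-6)


class TestClassifyMode:
    @pytest.mark.parametrize("mode", ["competitive", "noncompetitive",
                                      "uncompetitive", "mixed"])
    def test_confusion_free_at_zero_noise(self, mode):
        fits, _ = _lb_fits(mode, ki=1e-7)
        assert classify_mode(fits) == mode

    def test_no_inhibition_is_none(self):
        fits, _ = _lb_fits("none")
        assert classify_mode(fits) == "none"

    def test_constant_intercept_rising_km_is_competitive(self):
        # constant 1/Vmax with rising Km_app is the competitive signature
        fits = [LineweaverFit(i, (50e-6 * (1 + i / 0.46e-7)), 1.0,
                              50e-6 * (1 + i / 0.46e-7), 1.0, 1.0)
                for i in [0.0, 0.2e-6, 0.4e-6, 0.8e-6]]
        assert classify_mode(fits) == "competitive"

    def test_needs_zero_inhibitor_level(self):
        fits = [LineweaverFit(i, 50e-6, 1.0, 50e-6, 1.0, 1.0)
                for i in [0.1e-6, 0.2e-6, 0.4e-6]]
        with pytest.raises(PreconditionError):
            classify_mode(fits)


class TestKiSecondary:
    def test_exact_line(self):
        # Km_app = {50, 100, 150} uM at [I] = {0, 1, 2} x 1e-7
        fits = [LineweaverFit(i, km / 1.0, 1.0, km, 1.0, 1.0)
                for i, km in zip([0.0, 1e-7, 2e-7], [50e-6, 100e-6, 150e-6])]
        res = fit_ki_secondary(fits)
        assert res.km == pytest.approx(50e-6, rel=1e-9)
        assert res.ki == pytest.approx(1e-7, rel=1e-9)
        assert res.secondary_slope == pytest.approx(500.0, rel=1e-9)

    def test_closed_loop_recovery(self, noiseless_config):
        res = bk.analyze_kinetics(bk.simulate_kinetics(noiseless_config))
        assert res.mode == "competitive"
        assert res.km == pytest.approx(noiseless_config.km_true, rel=1e-6)
        assert res.vmax == pytest.approx(noiseless_config.vmax_true, rel=1e-6)
        assert res.ki == pytest.approx(noiseless_config.ki_true, rel=1e-6)

    def test_constant_km_app_is_no_inhibition(self):
        fits = [LineweaverFit(i, 50e-6, 1.0, 50e-6, 1.0, 1.0)
                for i in [0.0, 1e-7, 2e-7]]
        with pytest.raises(NoInhibitionError):
            fit_ki_secondary(fits)

    def test_global_nonlinear_cross_check(self, noiseless_config):
        ds = bk.simulate_kinetics(noiseless_config)
        km, vmax, ki = fit_competitive_global(ds)
        assert km == pytest.approx(noiseless_config.km_true, rel=1e-6)
        assert vmax == pytest.approx(noiseless_config.vmax_true, rel=1e-6)
        assert ki == pytest.approx(noiseless_config.ki_true, rel=1e-6)


class TestReversibility:
    def test_parallel_lines_irreversible(self, noiseless_config):
        df = bk.simulate_reversibility(noiseless_config, truth="irreversible")
        res = bk.assess_reversibility(df)
        assert res.verdict == "irreversible"
        assert res.slope_cv <= 0.05

    def test_origin_fan_reversible(self, noiseless_config):
        df = bk.simulate_reversibility(noiseless_config, truth="reversible")
        assert bk.assess_reversibility(df).verdict == "reversible"

    def test_identical_lines_indeterminate(self):
        E = np.array([0.01, 0.02, 0.03])
        rows = [pd.DataFrame({"enzyme_UmL": E, "inhibitor_M": i,
                              "velocity": 30.0 * E}) for i in (0.0, 1e-7)]
        assert bk.assess_reversibility(pd.concat(rows)).verdict == "indeterminate"

    def test_single_inhibitor_level_rejected(self):
        E = np.array([0.01, 0.02, 0.03])
        df = pd.DataFrame({"enzyme_UmL": E, "inhibitor_M": 0.0,
                           "velocity": 30.0 * E})
        with pytest.raises(PreconditionError):
            bk.assess_reversibility(df)

    def test_noisy_verdicts_stay_correct(self):
        for seed in range(5):
            cfg = bk.SimulationConfig(seed=seed, noise_sd_rel=0.02)
            irr = bk.simulate_reversibility(cfg, truth="irreversible")
            rev = bk.simulate_reversibility(cfg, truth="reversible")
            assert bk.assess_reversibility(irr).verdict == "irreversible"
            assert bk.assess_reversibility(rev).verdict == "reversible"


class TestMonotonicityProperty:
    def test_apparent_ic50_of_competitive_inhibitor_rises_with_substrate(self):
        # at fixed [S], %inhibition = 100*(1 - v_I/v_0); the [I] reaching 50%
        # grows with [S] because substrate outcompetes the inhibitor
        from bindkit.kinetics import rate_law
        ic50s = []
        I = np.geomspace(1e-9, 1e-5, 200)
        for S in (25e-6, 50e-6, 100e-6):
            v0 = rate_law(S, 0.0, 50e-6, 1.0, 0.46e-7, mode="competitive")
            vi = rate_law(S, I, 50e-6, 1.0, 0.46e-7, mode="competitive")
            pct = 100 * (1 - vi / v0)
            ic50s.append(np.interp(50.0, pct, I))
        assert ic50s[0] < ic50s[1] < ic50s[2]


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = bk.IC50Estimator(max_iter=123)
        assert est.get_params()["max_iter"] == 123
        est.set_params(max_iter=456)
        assert est.max_iter == 456

    def test_predict_after_fit(self, noiseless_config):
        df = bk.simulate_dose_response(noiseless_config)
        est = bk.IC50Estimator().fit(df["inhibitor_M"], df["inhibition_pct"])
        assert est.predict([noiseless_config.ic50_true])[0] == pytest.approx(50.0)

    def test_inconsistent_grids_rejected(self):
        df1 = pd.DataFrame({"substrate_M": [25e-6, 50e-6, 100e-6],
                            "inhibitor_M": 0.0, "velocity": [0.3, 0.5, 0.66]})
        df2 = pd.DataFrame({"substrate_M": [30e-6, 60e-6, 90e-6],
                            "inhibitor_M": 1e-7, "velocity": [0.2, 0.33, 0.4]})
        with pytest.raises(ValidationError):
            bk.analyze_kinetics(pd.concat([df1, df2], ignore_index=True))
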