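"""Conditional quasi-Poisson estimation: closed forms, oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hwcc import design, estimator, hwi, simulate
from hwcc.estimator import ModelSpec

from conftest import make_climate, make_thresholds, random_small_panel


def dummy_glm_fit(panel, cols=("dhwi", "nhwi")):
    """Independent oracle: explicit stratum-dummy Poisson GLM."""
    keep = panel.groupby(design.STRATUM_COLS)["count"].transform("sum") > 0
    p = panel[keep]
    dummies = pd.get_dummies(
        p.groupby(design.STRATUM_COLS, sort=False).ngroup()
    ).astype(float)
    X = np.column_stack([p[list(cols)].to_numpy(dtype=float), dummies.to_numpy()])
    res = sm.GLM(p["count"].to_numpy(), X, family=sm.families.Poisson()).fit()
    return res.params[: len(cols)]


class TestConditionalFit:
    def test_single_stratum_closed_form(self):
        panel = design.add_stratum_keys(
            pd.DataFrame(
                {
                    "location_id": ["A", "A"],
                    "date": pd.to_datetime(["2019-07-01", "2019-07-08"]),
                    "count": [3, 5],
                    "dhwi": [0.0, 2.0],
                    "nhwi": [0.0, 0.0],
                    "dhw_flag": [0, 1],
                    "nhw_flag": [0, 0],
                }
            )
        )
        fit = estimator.fit_conditional_poisson(panel, exposure_cols=["dhwi"])
        assert fit.params["dhwi"] == pytest.approx(math.log(5 / 3) / 2, abs=1e-8)

    def test_constant_exposure_is_unidentifiable(self):
        panel = design.add_stratum_keys(
            pd.DataFrame(
                {
                    "location_id": ["A"] * 4,
                    "date": pd.date_range("2019-07-01", periods=4, freq="7D"),
                    "count": [3, 5, 2, 4],
                    "dhwi": [1.0] * 4,
                    "nhwi": [0.5] * 4,
                    "dhw_flag": [0] * 4,
                    "nhw_flag": [0] * 4,
                }
            )
        )
        with pytest.raises(RuntimeError, match="unidentifiable"):
            estimator.fit_conditional_poisson(panel)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_stratum_dummy_glm(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_small_panel(rng)
        fit = estimator.fit_conditional_poisson(panel)
        ref = dummy_glm_fit(panel)
        assert np.max(np.abs(fit.params.to_numpy() - ref)) < 1e-6

    def test_stratum_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        panel = random_small_panel(rng)
        fit = estimator.fit_conditional_poisson(panel)
        relabel = {f"L{i:02d}": f"Z{9 - i}" for i in range(10)}
        shuffled = panel.assign(
            location_id=panel["location_id"].map(relabel)
        ).sample(frac=1.0, random_state=0)
        fit2 = estimator.fit_conditional_poisson(shuffled)
        assert np.allclose(fit.params, fit2.params, atol=1e-9)

    def test_quasi_scaling_changes_only_uncertainty(self):
        rng = np.random.default_rng(11)
        panel = random_small_panel(rng)
        f1 = estimator.fit_conditional_poisson(panel)
        f2 = estimator.fit_conditional_poisson(
            panel, ModelSpec(dispersion_floor=25.0)
        )
        assert np.allclose(f1.params, f2.params)
        assert f2.se("dhwi") == pytest.approx(
            5.0 * np.sqrt(f1.cov_unscaled.loc["dhwi", "dhwi"])
        )

    def test_temperature_shift_invariance(self, six_day=None):
        tmax = [29.0, 31.0, 32.0, 29.0, 31.0, 29.0]
        tmin = [14.0, 14.0, 16.0, 14.0, 14.0, 14.0]
        clim = make_climate(tmax, tmin)
        shifted = clim.assign(tmax=clim["tmax"] + 7.0, tmin=clim["tmin"] + 7.0)
        ts = make_thresholds(30.0, 15.0)
        ts_shift = make_thresholds(37.0, 22.0)
        _, e1 = hwi.compute_exposure(clim, ts)
        _, e2 = hwi.compute_exposure(shifted, ts_shift)
        pd.testing.assert_frame_equal(e1, e2)


class TestDispersion:
    def test_doubling_counts_doubles_dispersion_exactly(self):
        rng = np.random.default_rng(21)
        panel = random_small_panel(rng, n_strata=20)
        f1 = estimator.fit_conditional_poisson(panel)
        doubled = panel.assign(count=2 * panel["count"])
        f2 = estimator.fit_conditional_poisson(doubled)
        assert np.allclose(f1.params, f2.params, atol=1e-8)
        assert f2.dispersion == pytest.approx(2.0 * f1.dispersion, rel=1e-10)

    def test_poisson_data_give_unit_dispersion(self, small_panel):
        fit = estimator.fit_conditional_poisson(small_panel)
        assert 0.8 < fit.dispersion < 1.2

    def test_negative_binomial_data_inflate_dispersion(self):
        cfg = simulate.make_scenario(
            "overdispersed", seed=77, n_locations=10, analysis_years=2,
            reference_years=15,
        )
        study = simulate.simulate_dataset(cfg)
        panel = design.assemble_panel(study.health, study.exposure, cause="mental")
        fit = estimator.fit_conditional_poisson(panel)
        assert fit.dispersion > 1.5

    def test_degenerate_df_raises_in_dispersion(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimator.pearson_dispersion(
                np.array([3.0, 5.0]), np.array([3.0, 5.0]), n_strata=1, n_params=1
            )


class TestPercentChange:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.0), (math.log(1.0123), 1.23), (math.log(1.0034), 0.34)],
    )
    def test_point_transform(self, beta, expected):
        e = estimator.percent_change(beta, 0.01)
        assert e.percent_change == pytest.approx(expected, abs=1e-10)

    def test_ci_ordering_and_p(self):
        e = estimator.percent_change(0.012, 0.001)
        assert e.ci95[0] < e.percent_change < e.ci95[1]
        assert e.p_value < 1e-6

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            estimator.percent_change(0.01, 0.0)


class TestSpline:
    def test_basis_anchored_at_zero(self):
        knots = np.array([0.0, 1.0, 2.5, 6.0])
        B = estimator.natural_spline_basis(np.array([0.0]), knots)
        assert np.allclose(B, 0.0)

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError, match="knot"):
            estimator.natural_spline_basis(np.zeros(3), np.array([0.0, 1.0, 1.0, 2.0]))

    def test_knots_at_p10_p50_of_heatwave_days(self, small_panel):
        fit, curves = estimator.fit_spline_model(small_panel)
        pos = small_panel.loc[small_panel["dhwi"] > 0, "dhwi"]
        expect = np.quantile(pos, [0.10, 0.50])
        assert np.allclose(fit.extras["knots_dhwi"][1:3], expect)
        assert curves["dhwi"].iloc[0].log_rr == 0.0

    def test_linear_truth_recovered_within_uncertainty(self, small_panel):
        fit_lin = estimator.fit_conditional_poisson(small_panel)
        fit_sp, curves = estimator.fit_spline_model(small_panel)
        curve = curves["nhwi"]
        inside = curve[curve["hwi"] <= small_panel["nhwi"].quantile(0.999)]
        line = fit_lin.params["nhwi"] * inside["hwi"]
        z = (inside["log_rr"] - line) / inside["se"].clip(lower=1e-12)
        assert np.abs(z.iloc[1:]).max() < 3.0


class TestLagAndBinary:
    def test_lag_zero_reproduces_main_fit(self, small_study, small_panel):
        main = estimator.fit_conditional_poisson(small_panel)
        lag0 = estimator.fit_lag_model(small_panel, small_study.exposure, 0)
        assert np.allclose(main.params, lag0.params, atol=1e-12)

    def test_lag_out_of_range(self, small_study, small_panel):
        with pytest.raises(ValueError, match="lag"):
            estimator.fit_lag_model(small_panel, small_study.exposure, 7)

    def test_lagged_rows_outside_coverage_dropped(self, small_study, small_panel):
        lagged = estimator.lag_exposure(small_panel, small_study.exposure, 3)
        cfg = small_study.config
        per_season = 3 * cfg.n_locations * cfg.analysis_years
        assert len(small_panel) - len(lagged) == per_season

    def test_effect_concentrated_at_generating_lag(self):
        study = simulate.simulate_dataset(simulate.make_scenario("lagged"))
        panel = design.assemble_panel(study.health, study.exposure, cause="mental")
        betas = {}
        for k in range(5):
            fit = estimator.fit_lag_model(panel, study.exposure, k)
            betas[k] = fit.params["nhwi"]
        assert max(betas, key=lambda k: abs(betas[k])) == 2
        assert betas[2] > 0

    def test_autocorrelated_exposure_attenuates_neighbour_lag(self):
        cfg = simulate.make_scenario(
            "paper_anchored", seed=88, n_locations=20, analysis_years=2,
            reference_years=15, beta_daytime=0.0,
            beta_nighttime=math.log(1.10),
        )
        study = simulate.simulate_dataset(cfg)
        panel = design.assemble_panel(study.health, study.exposure, cause="mental")
        b0 = estimator.fit_lag_model(panel, study.exposure, 0).params["nhwi"]
        b1 = estimator.fit_lag_model(panel, study.exposure, 1).params["nhwi"]
        assert b0 > b1 > 0.0

    def test_binary_without_heatwaves_unidentifiable(self):
        clim = make_climate([25.0] * 20, [10.0] * 20)
        ts = make_thresholds(30.0, 15.0)
        _, exp = hwi.compute_exposure(clim, ts)
        health = pd.DataFrame(
            {
                "location_id": "A",
                "date": pd.to_datetime(["2019-07-02"]),
                "cause": "mental",
                "count": [2],
            }
        )
        panel = design.assemble_panel(health, exp, cause="mental")
        with pytest.raises(RuntimeError, match="unidentifiable"):
            estimator.fit_binary_model(panel)

    def test_binary_effect_close_to_truth(self, small_panel, small_study):
        # per-degree generator: the per-event binary effect is roughly the
        # per-degree effect scaled by the mean event-day intensity
        fit = estimator.fit_binary_model(small_panel)
        b = fit.params["nhw_flag"]
        nights = small_panel[small_panel["nhw_flag"] == 1]
        implied = small_study.config.beta_nighttime * nights["nhwi"].mean()
        assert b == pytest.approx(implied, abs=3 * fit.se("nhw_flag"))
        assert b > small_study.config.beta_nighttime  # mean intensity > 1 degC
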