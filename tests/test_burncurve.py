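import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from grassflam import burncurve
from grassflam.io import LeafBurnEvents, MassLossSeries
from oracles import boltzmann_grid_fit, windowed_slope


def make_series(a1=2.0, a2=0.2, t0=30.0, dx=5.0, t_end=60.0, noise_sd=0.0,
                rng=None, state="dry"):
    t = np.arange(0.0, t_end + 0.1, 0.2)
    m = burncurve.boltzmann(t, a1, a2, t0, dx)
    if noise_sd > 0:
        m = np.maximum(m + rng.normal(0, noise_sd, t.size), 0.0)
        m[-1] = min(m[-1], m[0])
    return MassLossSeries("i1", state, t, m)


class TestLeafMetrics:
    def test_slow_ignition_delay(self):
        # slow-ignition case: a 4-second delay before first flaming
        ev = LeafBurnEvents("i1", "fresh", 0.2, 0.0, 4.0, 10.0)
        out = burncurve.leaf_metrics(ev)
        assert out.tti_s == pytest.approx(4.0)
        assert out.ft_s == pytest.approx(6.0)

    def test_zero_flaming_time_excluded(self):
        ev = LeafBurnEvents("i1", "dry", 0.2, 0.0, 1.0, 1.0)
        out = burncurve.leaf_metrics(ev)
        assert out.excluded and out.reason == "no sustained flaming"

    def test_combustion_rate_mass_over_ft(self):
        ev = LeafBurnEvents("i1", "dry", 0.2, 0.0, 1.0, 9.0)
        assert burncurve.leaf_metrics(ev).combustion_rate_g_s == pytest.approx(0.025)


class TestMoistureEffect:
    def _df(self, rows):
        base = {"excluded": False, "reason": ""}
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_paired_difference(self):
        df = self._df([
            {"species_id": "s", "individual_id": "i1", "state": "fresh",
             "tti_s": 2.0, "ft_s": 6.0, "combustion_rate_g_s": 0.03},
            {"species_id": "s", "individual_id": "i1", "state": "dry",
             "tti_s": 1.0, "ft_s": 5.0, "combustion_rate_g_s": 0.04},
        ])
        per_ind, per_sp = burncurve.moisture_effect(df)
        assert per_ind["tti_s_diff"].iloc[0] == pytest.approx(1.0)
        assert per_ind["tti_s_rel"].iloc[0] == pytest.approx(1.0)
        assert per_sp["ft_s_diff"].iloc[0] == pytest.approx(1.0)

    def test_identical_states_zero_difference(self):
        df = self._df([
            {"species_id": "s", "individual_id": "i1", "state": st,
             "tti_s": 2.0, "ft_s": 6.0, "combustion_rate_g_s": 0.03}
            for st in ("fresh", "dry")
        ])
        per_ind, _ = burncurve.moisture_effect(df)
        assert per_ind["tti_s_diff"].iloc[0] == 0.0

    def test_unpaired_individual_dropped(self):
        df = self._df([
            {"species_id": "s", "individual_id": "i1", "state": "fresh",
             "tti_s": 2.0, "ft_s": 6.0, "combustion_rate_g_s": 0.03},
            {"species_id": "s", "individual_id": "i2", "state": "dry",
             "tti_s": 1.0, "ft_s": 5.0, "combustion_rate_g_s": 0.04},
        ])
        per_ind, _ = burncurve.moisture_effect(df)
        assert len(per_ind) == 0

    def test_configured_ignition_delay_ratio_recovered(self, small_bundle):
        leaf = burncurve.leaf_metrics_table(small_bundle.leaf_events)
        _, per_sp = burncurve.moisture_effect(leaf)
        ratio = small_bundle.truth["tti_fresh_over_dry"]
        assert per_sp["tti_s_rel"].mean() == pytest.approx(ratio - 1.0, abs=0.08)


class TestFitBoltzmann:
    def test_noiseless_parameters_recovered(self):
        s = make_series()
        fit = burncurve.fit_boltzmann(s)
        assert fit.converged
        for got, true in zip((fit.A1, fit.A2, fit.t0, fit.dx), (2.0, 0.2, 30.0, 5.0)):
            assert got == pytest.approx(true, rel=1e-6)

    def test_flaming_time_is_width_parameter(self):
        s = make_series()
        out = burncurve.plant_metrics(s)
        assert out.flaming_time_s == pytest.approx(5.0, rel=1e-6)

    def test_refit_on_own_prediction_is_fixed_point(self):
        fit1 = burncurve.fit_boltzmann(make_series(a1=8.0, a2=0.5, t0=25.0, dx=3.0))
        t = np.arange(0.0, 60.0, 0.2)
        pred = MassLossSeries("i1", "dry", t, burncurve.boltzmann(t, fit1.A1, fit1.A2, fit1.t0, fit1.dx))
        fit2 = burncurve.fit_boltzmann(pred)
        assert fit2.dx == pytest.approx(fit1.dx, rel=1e-6)

    def test_noisy_fit_matches_grid_refined_oracle(self, rng):
        s = make_series(noise_sd=0.01, rng=rng)
        fit = burncurve.fit_boltzmann(s)
        a1o, a2o, t0o, dxo, rss_o = boltzmann_grid_fit(s.time, s.mass)
        # both optimizers should land on the same optimum
        assert fit.rss <= rss_o * (1 + 1e-6)
        assert fit.dx == pytest.approx(dxo, rel=1e-3)
        assert fit.t0 == pytest.approx(t0o, rel=1e-3)

    def test_lack_of_fit_flagged(self, rng):
        t = np.arange(0.0, 30.0, 0.2)
        m = np.maximum(2.0 - 0.05 * t + rng.normal(0, 0.5, t.size), 0.0)
        m[-1] = min(m[-1], m[0])
        s = MassLossSeries("i1", "dry", t, m)
        fit = burncurve.fit_boltzmann(s, r2_threshold=0.95)
        assert not fit.converged

    def test_exclusion_bookkeeping(self, small_bundle):
        out = burncurve.plant_metrics_table(small_bundle.mass_loss)
        assert len(out) == len(small_bundle.mass_loss)
        assert out["excluded"].sum() + (~out["excluded"]).sum() == len(out)


class TestMaxCombustionRate:
    def test_matches_analytic_curve_regression_oracle(self):
        s = make_series(a1=2.0, a2=0.2, t0=30.0, dx=5.0)
        fit = burncurve.fit_boltzmann(s)
        rate = burncurve.max_combustion_rate(s, fit)
        oracle = windowed_slope(s.time, s.mass, fit.t0, 3.0)
        assert rate == pytest.approx(oracle, rel=1e-9)
        # near but not equal to the tangent rate (A1-A2)/(4 dx) = 0.09
        assert rate == pytest.approx(0.09, rel=0.05)

    def test_quasi_linear_limit_recovers_decline_rate(self):
        # dx >> window: the sigmoid is locally linear with rate (A1-A2)/(4 dx)
        s = make_series(a1=10.0, a2=0.0, t0=150.0, dx=80.0, t_end=300.0)
        fit = burncurve.BoltzmannFit(10.0, 0.0, 150.0, 80.0, 0.0, 1.0, True)
        rate = burncurve.max_combustion_rate(s, fit)
        assert rate == pytest.approx(10.0 / (4 * 80.0), rel=1e-3)

    def test_constant_mass_gives_zero_slope(self):
        t = np.arange(0.0, 20.0, 0.2)
        s = MassLossSeries("i1", "dry", t, np.full(t.size, 1.5))
        fit = burncurve.BoltzmannFit(1.5, 1.5, 10.0, 1.0, 0.0, 1.0, True)
        assert burncurve.max_combustion_rate(s, fit) == pytest.approx(0.0, abs=1e-12)

    def test_mass_offset_invariance(self):
        s1 = make_series()
        s2 = MassLossSeries("i1", "dry", s1.time, s1.mass + 3.0)
        fit = burncurve.fit_boltzmann(s1)
        r1 = burncurve.max_combustion_rate(s1, fit)
        r2 = burncurve.max_combustion_rate(s2, fit)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_inflection_outside_series_errors(self):
        s = make_series(t_end=31.0)
        fit = burncurve.BoltzmannFit(2.0, 0.2, 30.0, 5.0, 0.0, 1.0, True)
        with pytest.raises(ValueError, match="outside"):
            burncurve.max_combustion_rate(s, fit)


def _plant_df(intercept_fresh, intercept_dry, slope, n=6, noise=0.0, rng=None):
    rows = []
    masses = np.linspace(1.0, 20.0, n)
    for i, m in enumerate(masses):
        for state, b0 in (("fresh", intercept_fresh), ("dry", intercept_dry)):
            eps = rng.normal(0, noise) if noise else 0.0
            rate = 10.0 ** (b0 + slope * np.log10(m) + eps)
            rows.append({
                "species_id": "s", "individual_id": f"i{i}", "state": state,
                "flaming_time_s": 5.0, "max_combustion_rate_g_s": rate,
                "mass_burned_g": m, "initial_mass_g": m * 1.1,
                "excluded": False, "reason": "",
            })
    return pd.DataFrame(rows)


class TestIntrinsicCombustibility:
    def test_exact_common_line_uses_combined(self):
        df = _plant_df(-1.0, -1.0, 0.6)
        out = burncurve.intrinsic_combustibility(df, "s")
        assert out.source == "combined"
        assert out.y_intercept == pytest.approx(-1.0, abs=1e-10)
        assert out.slope == pytest.approx(0.6, abs=1e-10)

    def test_separated_intercepts_fall_back_to_fresh(self, rng):
        df = _plant_df(-1.0, -0.7, 0.6, noise=0.01, rng=rng)
        out = burncurve.intrinsic_combustibility(df, "s")
        assert out.source == "fresh-only"
        assert out.y_intercept == pytest.approx(-1.0, abs=0.05)

    def test_decisions_match_statsmodels_f_test(self, rng):
        df = _plant_df(-1.0, -0.95, 0.6, n=8, noise=0.05, rng=rng)
        out = burncurve.intrinsic_combustibility(df, "s")
        d = pd.DataFrame({
            "y": np.log10(df["max_combustion_rate_g_s"]),
            "x": np.log10(df["mass_burned_g"]),
            "state": (df["state"] == "fresh").astype(float),
        })
        full = smf.ols("y ~ x * state", d).fit()
        cslope = smf.ols("y ~ x + state", d).fit()
        single = smf.ols("y ~ x", d).fit()
        p_slope = float(full.compare_f_test(cslope)[1])
        p_int = float(cslope.compare_f_test(single)[1])
        assert out.p_slope_equality == pytest.approx(p_slope, abs=1e-10)
        assert out.p_intercept_equality == pytest.approx(p_int, abs=1e-10)
        expect = single if p_int >= 0.05 else smf.ols("y ~ x", d[d.state == 1.0]).fit()
        assert out.y_intercept == pytest.approx(expect.params["Intercept"], abs=1e-10)

    def test_degenerate_mass_range_rejected(self):
        df = _plant_df(-1.0, -1.0, 0.6)
        df["mass_burned_g"] = 5.0
        with pytest.raises(ValueError, match="unidentifiable"):
            burncurve.intrinsic_combustibility(df, "s")


class TestWholePlantRate:
    def test_unit_biomass_returns_intercept_rate(self):
        assert burncurve.whole_plant_rate(-1.0, 0.8, 1.0) == pytest.approx(0.1)

    def test_across_species_extrapolation(self):
        # log10(rate) = -1 + 0.797 * log10(10) -> 0.627 g/s
        assert burncurve.whole_plant_rate(-1.0, 0.797, 10.0) == pytest.approx(0.627, abs=5e-4)

    def test_doubling_biomass_scales_by_power(self):
        r1 = burncurve.whole_plant_rate(-1.2, 0.75, 8.0)
        r2 = burncurve.whole_plant_rate(-1.2, 0.75, 16.0)
        assert r2 / r1 == pytest.approx(2 ** 0.75, rel=1e-12)

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            burncurve.whole_plant_rate(-1.0, 0.8, 0.0)
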