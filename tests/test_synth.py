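"""Generator behaviour: determinism, configured structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from aq_accountant.synth import (
    ConfigurationError,
    EmissionSeriesConfig,
    MetFieldConfig,
    RegulationStep,
    ResponseTerm,
    SourceSpec,
    TrueSourceSystem,
    generate_contributions,
    generate_emissions,
    generate_meteorology,
    generate_speciation,
    generate_world,
)


class TestMeteorology:
    def test_degenerate_config_is_constant(self):
        fields = {"temperature": MetFieldConfig(mean=12.0, amplitude=0.0, noise_sd=0.0)}
        met = generate_meteorology(fields, n_days=50, seed=0)
        assert (met["temperature"] == 12.0).all()

    def test_same_seed_reproduces(self):
        a = generate_meteorology(n_days=200, seed=42)
        b = generate_meteorology(n_days=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_long_run_mean_matches_config(self):
        fields = {"temperature": MetFieldConfig(mean=15.0, amplitude=10.0, noise_sd=2.0, ar_coef=0.8)}
        met = generate_meteorology(fields, n_days=3650, seed=1)
        assert abs(met["temperature"].mean() - 15.0) < 0.5

    def test_bounded_fields_stay_in_range(self):
        met = generate_meteorology(n_days=1000, seed=3)
        assert met["relative_humidity"].between(0, 100).all()
        assert (met["wind_speed"] >= 0).all()
        assert (met["precipitation"] >= 0).all()

    @pytest.mark.parametrize("bad", [{"ar_coef": 1.0}, {"ar_coef": -0.1}, {"noise_sd": -1.0}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            MetFieldConfig(mean=0.0, **bad)


class TestEmissions:
    def test_no_steps_scenarios_identical(self):
        cfg = EmissionSeriesConfig("EGU", "NOx", baseline=10.0, noise_sd=0.1)
        out = generate_emissions([cfg], n_days=100, seed=0)
        pd.testing.assert_frame_equal(out.factual, out.counterfactual)

    def test_cumulative_regulatory_reductions(self):
        """Stepwise controls reaching ~88% (NOx) and ~97% (SO2) by the final year."""
        configs = [
            EmissionSeriesConfig(
                "EGU", "NOx", baseline=800.0,
                steps=[RegulationStep("2007-01-01", 0.4), RegulationStep("2010-01-01", 0.5),
                       RegulationStep("2015-01-01", 0.6)],
            ),
            EmissionSeriesConfig(
                "EGU", "SO2", baseline=1000.0,
                steps=[RegulationStep("2007-01-01", 0.4), RegulationStep("2010-01-01", 0.5),
                       RegulationStep("2015-01-01", 0.9)],
            ),
        ]
        out = generate_emissions(configs, n_days=5479, start="2005-01-01", seed=0)
        y2019 = out.factual.index.year == 2019
        ratio = out.factual.loc[y2019].mean() / out.counterfactual.loc[y2019].mean()
        assert ratio["EGU:NOx"] == pytest.approx(0.12, abs=1e-12)
        assert ratio["EGU:SO2"] == pytest.approx(0.03, abs=1e-12)

    def test_single_midseries_step(self):
        cfg = EmissionSeriesConfig("s", "p", baseline=4.0, steps=[RegulationStep("2005-03-01", 0.5)])
        out = generate_emissions([cfg], n_days=120, seed=0)
        cut = out.factual.index >= "2005-03-01"
        assert np.allclose(out.factual.loc[cut, "s:p"], out.counterfactual.loc[cut, "s:p"] / 2)
        assert np.allclose(out.factual.loc[~cut, "s:p"], out.counterfactual.loc[~cut, "s:p"])

    def test_step_outside_range_rejected(self):
        cfg = EmissionSeriesConfig("s", "p", steps=[RegulationStep("2030-01-01", 0.5)])
        with pytest.raises(ConfigurationError):
            generate_emissions([cfg], n_days=100, seed=0)

    def test_inverted_case_counterfactual_lower(self):
        """Diesel-SCR ammonia: removing controls lowers the pollutant."""
        cfg = EmissionSeriesConfig(
            "mobile_diesel", "NH3", baseline=10.0,
            steps=[RegulationStep("2005-06-01", 0.3)], inverted=True,
        )
        out = generate_emissions([cfg], n_days=365, seed=0)
        assert (out.counterfactual["mobile_diesel:NH3"] <= out.factual["mobile_diesel:NH3"]).all()

    def test_fractional_reduction_bounds(self):
        with pytest.raises(ConfigurationError):
            RegulationStep("2005-01-01", 1.5)


class TestContributions:
    def test_constant_baseline(self, met_3y, small_emissions):
        system = TrueSourceSystem(
            sources=[SourceSpec("flat", baseline=3.0)],
            profiles=pd.DataFrame([[1.0]], index=["flat"], columns=["X"]),
        )
        g = generate_contributions(system, met_3y, small_emissions, seed=0)
        assert (g["flat"] == 3.0).all()

    def test_linear_scenario_difference(self, met_3y):
        """Slope-2 response and a unit emission gap give a constant impact of 2."""
        cfg = EmissionSeriesConfig("s", "p", baseline=5.0, steps=[RegulationStep("2005-01-02", 0.2)])
        emis = generate_emissions([cfg], n_days=1096, seed=0)
        system = TrueSourceSystem(
            sources=[SourceSpec("f", baseline=10.0,
                                responses=[ResponseTerm("s:p", "linear", {"slope": 2.0})])],
            profiles=pd.DataFrame([[1.0]], index=["f"], columns=["X"]),
        )
        gf = generate_contributions(system, met_3y, emis, "factual", seed=1)
        gc = generate_contributions(system, met_3y, emis, "counterfactual", seed=1)
        after = met_3y.index >= "2005-01-02"
        # emission gap is 0.2·5 = 1 after the step, so the impact is 2
        assert np.allclose((gc - gf).loc[after, "f"], 2.0)

    def test_seasonal_peak_month(self, met_3y):
        system = TrueSourceSystem(
            sources=[SourceSpec("w", baseline=2.0, seasonal_amplitude=1.0, seasonal_peak_day=15)],
            profiles=pd.DataFrame([[1.0]], index=["w"], columns=["X"]),
        )
        g = generate_contributions(system, met_3y, None, seed=0)
        monthly = g["w"].groupby(g.index.month).mean()
        assert monthly.idxmax() == 1

    def test_identical_scenarios_identical_truth(self, met_3y, simple_system):
        cfg = EmissionSeriesConfig("EGU", "SO2", baseline=100.0, noise_sd=0.1)
        cfg2 = EmissionSeriesConfig("mobile", "NOx", baseline=50.0)
        emis = generate_emissions([cfg, cfg2], n_days=1096, seed=2)
        gf = generate_contributions(simple_system, met_3y, emis, "factual", seed=3)
        gc = generate_contributions(simple_system, met_3y, emis, "counterfactual", seed=3)
        pd.testing.assert_frame_equal(gf, gc)

    def test_weekday_multipliers_recoverable(self, met_3y):
        mult = (1.2, 1.1, 1.0, 1.0, 1.0, 0.7, 0.6)
        system = TrueSourceSystem(
            sources=[SourceSpec("t", baseline=5.0, dow_multipliers=mult, noise_sd=0.5)],
            profiles=pd.DataFrame([[1.0]], index=["t"], columns=["X"]),
        )
        met = generate_meteorology(n_days=3650, seed=5)
        g = generate_contributions(system, met, None, seed=5)
        by_dow = g["t"].groupby(g.index.dayofweek).mean()
        rel = by_dow / g["t"].mean()
        expected = np.array(mult) / np.mean(mult)
        assert np.allclose(rel.to_numpy(), expected, rtol=0.05)

    def test_missing_variable_rejected(self, met_3y, small_emissions):
        system = TrueSourceSystem(
            sources=[SourceSpec("f", responses=[ResponseTerm("nope", "linear")])],
            profiles=pd.DataFrame([[1.0]], index=["f"], columns=["X"]),
        )
        with pytest.raises(ConfigurationError):
            generate_contributions(system, met_3y, small_emissions, seed=0)

    def test_nonnegative(self, met_3y):
        system = TrueSourceSystem(
            sources=[SourceSpec("n", baseline=0.1, noise_sd=2.0)],
            profiles=pd.DataFrame([[1.0]], index=["n"], columns=["X"]),
        )
        g = generate_contributions(system, met_3y, None, seed=0)
        assert (g["n"] >= 0).all()
        assert (g["n"] == 0).any()  # rectification actually engaged


class TestSpeciation:
    @pytest.fixture()
    def gf(self, met_3y, simple_system, small_emissions):
        g = generate_contributions(simple_system, met_3y, small_emissions, seed=4)
        return g, simple_system.profiles

    def test_noise_free_exact_product(self, gf):
        g, f = gf
        ds = generate_speciation(g, f, proportional_noise=0.0, detection_limit=0.0, seed=0)
        assert np.allclose(ds.X.to_numpy(), g.to_numpy() @ f.to_numpy())

    def test_identity_mixing(self, met_3y):
        system = TrueSourceSystem(
            sources=[SourceSpec("one", baseline=2.0, seasonal_amplitude=0.5)],
            profiles=pd.DataFrame([[1.0]], index=["one"], columns=["X"]),
        )
        g = generate_contributions(system, met_3y, None, seed=0)
        ds = generate_speciation(g, system.profiles, 0.0, 0.0, seed=0)
        assert np.allclose(ds.X["X"].to_numpy(), g["one"].to_numpy())

    def test_scaled_residuals_match_uncertainty_convention(self):
        """Mean |X - GF|/S ≈ E|N(0,1)| = 0.798 when S tracks the noise scale."""
        from aq_accountant.synth import three_factor_speciation

        ds, g, f = three_factor_speciation(n_days=1000, n_species=15, seed=9)
        true = g.to_numpy() @ f.to_numpy()
        scaled = np.abs(ds.X.to_numpy() - true) / ds.S.to_numpy()
        assert np.mean(scaled) == pytest.approx(0.8, abs=0.08)

    def test_censoring_and_uncertainty_invariants(self, gf):
        g, f = gf
        ds = generate_speciation(g, f, proportional_noise=0.3, detection_limit=0.5, seed=1)
        assert (ds.X.to_numpy() >= 0).all()
        assert (ds.S.to_numpy() > 0).all()
        assert ds.X.shape == ds.S.shape

    def test_factor_mismatch_rejected(self, gf):
        g, f = gf
        with pytest.raises(ValueError):
            generate_speciation(g.iloc[:, :1], f, seed=0)


class TestWorld:
    def test_fixed_seed_bit_identical(self):
        a = generate_world(n_days=1500, seed=7)
        b = generate_world(n_days=1500, seed=7)
        pd.testing.assert_frame_equal(a.met, b.met)
        pd.testing.assert_frame_equal(a.speciation.X, b.speciation.X)
        for sc in ("factual", "counterfactual"):
            pd.testing.assert_frame_equal(a.G_true[sc], b.G_true[sc])

    def test_counterfactual_not_below_factual_for_regulated(self):
        w = generate_world(n_days=2000, seed=8)
        assert (w.emissions.counterfactual.to_numpy() >= w.emissions.factual.to_numpy() - 1e-9).all()

    def test_write_world_round_trip(self, tmp_path):
        from aq_accountant.io import read_timeseries_csv
        from aq_accountant.synth import write_world

        w = generate_world(n_days=1500, seed=9)
        files = write_world(w, tmp_path)
        assert "met.csv" in files and "truth_F.csv" in files
        met = read_timeseries_csv(tmp_path / "met.csv")
        assert np.allclose(met.to_numpy(), w.met.to_numpy())
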