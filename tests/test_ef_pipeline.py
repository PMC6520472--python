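import math

import numpy as np
import pandas as pd
import pytest

from n2oflux.bayes_inference import McmcConfig
from n2oflux.ef_pipeline import (
    EventDesign,
    EventResult,
    aggregate_efs,
    analyze_event,
    background_cumulative,
    compare_methods,
    convert_flux_units,
    emission_factor,
    load_reported_event_results,
    pooled_posterior_pdf,
    prob_greater,
    results_to_frame,
    round_half_up,
)
from n2oflux.synthetic_data import (
    CampaignLayout,
    TruthSpec,
    daily_then_alternate_schedule,
    simulate_event,
)
from n2oflux.units import NMOL_M2_S_TO_KGN_HA_DAY as CONV


class TestUnitConversion:
    def test_zero(self):
        assert convert_flux_units(0.0) == 0.0

    def test_unit_flux(self):
        # 2 x 14.0067 g/mol x 86400 s/day x 1e-9 x 1e4 m2/ha / 1e3
        assert convert_flux_units(1.0) == pytest.approx(0.024204, abs=5e-7)

    def test_sustained_30_days(self):
        assert 0.4 * 30 * CONV == pytest.approx(0.290, abs=5e-4)


class TestBackgroundCumulative:
    def _control(self, flux):
        days = [1.0, 10.0, 20.0, 30.0]
        return pd.DataFrame({"day": days * 2,
                             "flux_nmol_m2_s": [flux] * 8,
                             "plot": ["c1"] * 4 + ["c2"] * 4})

    def test_zero_controls(self):
        assert background_cumulative(self._control(0.0)) == 0.0

    def test_constant_background(self):
        # constant 0.3 nmol m-2 s-1; hold rule loses the half day before
        # day 1 so integrate over 29.5 days
        got = background_cumulative(self._control(0.3))
        assert got == pytest.approx(0.3 * 29.5 * CONV, rel=1e-9)
        assert got == pytest.approx(0.2178, abs=0.005)

    def test_delegates_to_trapezoid(self):
        from n2oflux.linear_baseline import mean_flux_series, trapezoid_cumulative
        ctrl = self._control(0.3)
        assert background_cumulative(ctrl) == trapezoid_cumulative(
            mean_flux_series(ctrl))

    def test_no_controls_clear_error(self):
        with pytest.raises(ValueError, match="control"):
            background_cumulative(pd.DataFrame({"day": [], "flux_nmol_m2_s": []}))


class TestEmissionFactor:
    def test_table_spot_value(self):
        # cumulative 1.59, background 0.25, 70 kg N applied -> ~1.92 %
        assert emission_factor(1.59, 0.25, 70) == pytest.approx(1.92, abs=0.015)

    def test_negative_ef(self):
        assert emission_factor(0.43, 0.51, 70) == pytest.approx(-0.11, abs=0.015)

    def test_background_equals_cumulative(self):
        assert emission_factor(0.8, 0.8, 90) == 0.0

    def test_rejects_nonpositive_n_in(self):
        with pytest.raises(ValueError):
            emission_factor(1.0, 0.1, 0.0)


class TestAggregateEfs:
    def test_reported_treatment_means(self):
        df = load_reported_event_results()
        agg = aggregate_efs(df, value="bayes_ef_pct")
        assert agg["groups"]["AN"]["mean"] == pytest.approx(0.60, abs=0.01)
        assert agg["groups"]["Ur"]["mean"] == pytest.approx(0.29, abs=0.01)
        assert agg["groups"]["UI"]["mean"] == pytest.approx(0.26, abs=0.01)
        assert agg["groups"]["AN"]["sd"] == pytest.approx(0.63, abs=0.02)
        assert agg["overall_median"] == pytest.approx(0.24, abs=0.005)
        assert agg["n_total"] == 33

    def test_single_value_group(self):
        df = pd.DataFrame({"treatment": ["AN"], "bayes_ef": [0.5]})
        agg = aggregate_efs(df)
        g = agg["groups"]["AN"]
        assert g["mean"] == g["median"] == 0.5
        assert math.isnan(g["sd"])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aggregate_efs(pd.DataFrame({"treatment": [], "bayes_ef": []}))


class TestCompareMethods:
    def test_identical_vectors(self):
        x = [0.1, 0.5, 1.2, 0.8]
        out = compare_methods(x, x)
        assert out["slope"] == pytest.approx(1.0, rel=1e-12)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out["r_squared"] == pytest.approx(1.0, rel=1e-12)
        assert out["slope_through_origin"] == pytest.approx(1.0, rel=1e-12)

    def test_four_point_hand_ols(self):
        # brute-force OLS: x=[1,2,3,4], y=[2,4,5,9]
        # slope = sum((x-2.5)(y-5))/sum((x-2.5)^2) = 11/5, intercept = -0.5
        out = compare_methods([1, 2, 3, 4], [2, 4, 5, 9])
        assert out["slope"] == pytest.approx(11 / 5, rel=1e-12)
        assert out["intercept"] == pytest.approx(-0.5, abs=1e-12)
        # r^2 = (sxy)^2/(sxx*syy) = 121 / (5 * 26)
        assert out["r_squared"] == pytest.approx(121 / 130, rel=1e-12)
        assert out["slope_through_origin"] == pytest.approx(
            (2 + 8 + 15 + 36) / 30, rel=1e-12)

    def test_reported_table_regression(self):
        df = load_reported_event_results()
        out = compare_methods(df["linear_ef_pct"], df["bayes_ef_pct"])
        assert out["r_squared"] == pytest.approx(0.79, abs=0.03)
        assert out["slope_through_origin"] == pytest.approx(1.04, abs=0.08)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            compare_methods([1, 2], [1, 2])
        with pytest.raises(ValueError):
            compare_methods([1, 1, 1], [1, 2, 3])


class TestReportedTableInvariants:
    def test_row_arithmetic_within_rounding(self):
        df = load_reported_event_results()
        tol = 0.015
        lin_mb = df["linear_cumulative_kg_ha"] - df["background_kg_ha"]
        bay_mb = df["bayes_cumulative_kg_ha"] - df["background_kg_ha"]
        assert (lin_mb - df["linear_minus_background_kg_ha"]).abs().max() <= tol
        assert (bay_mb - df["bayes_minus_background_kg_ha"]).abs().max() <= tol
        assert (100 * lin_mb / df["n_in_kg_ha"]
                - df["linear_ef_pct"]).abs().max() <= tol
        assert (100 * bay_mb / df["n_in_kg_ha"]
                - df["bayes_ef_pct"]).abs().max() <= tol
        assert (df["bayes_ci_low_kg_ha"] <= df["bayes_cumulative_kg_ha"]).all()
        assert (df["bayes_cumulative_kg_ha"] <= df["bayes_ci_high_kg_ha"]).all()


@pytest.fixture(scope="module")
def event_results():
    truth = TruthSpec()
    layout = CampaignLayout(treatments=("AN", "Ur"))
    df = simulate_event(truth, daily_then_alternate_schedule(), layout,
                        seed=21, site="SYN", event=1)
    design = EventDesign(site="SYN", event=1, n_in=70.0,
                         treatments=("AN", "Ur"))
    return analyze_event(df, design,
                         mcmc=McmcConfig(n_iter=3000, n_burnin=1000, seed=9))


class TestAnalyzeEvent:
    def test_one_result_per_treatment(self, event_results):
        assert sorted(r.treatment for r in event_results) == ["AN", "Ur"]

    def test_internal_consistency(self, event_results):
        for r in event_results:
            r.validate()

    def test_results_frame_shape(self, event_results):
        df = results_to_frame(event_results)
        assert len(df) == 2
        assert "bayes_ef" in df.columns and "linear_ef" in df.columns

    def test_linear_and_bayes_efs_same_ballpark(self, event_results):
        # dense daily sampling: both methods see the same pulse
        for r in event_results:
            assert abs(r.bayes_ef - r.linear_ef) < 1.0

    def test_missing_event_error(self):
        df = simulate_event(TruthSpec(), seed=0, site="SYN", event=1)
        with pytest.raises(ValueError):
            analyze_event(df, EventDesign(site="SYN", event=9, n_in=70.0))


class TestUnitInvariance:
    def test_ef_invariant_to_unit_system(self):
        # expressing cumulative/background in other units with a
        # consistent conversion leaves EF unchanged
        c, b, n = 1.59, 0.25, 70.0
        ef1 = emission_factor(c, b, n)
        factor = 1000.0  # e.g. g N ha-1
        ef2 = emission_factor(c * factor, b * factor, n * factor)
        assert ef1 == pytest.approx(ef2, rel=1e-12)


class TestPooledPosterior:
    def test_single_event_pools_to_itself(self, rng):
        draws = rng.lognormal(-1, 0.5, 4000)
        pooled = pooled_posterior_pdf([draws])
        np.testing.assert_array_equal(pooled["draws"], draws)
        assert pooled["density"].shape == pooled["grid"].shape

    def test_identical_treatments_prob_half(self, rng):
        a = rng.lognormal(-1, 0.5, 50_000)
        b = rng.lognormal(-1, 0.5, 50_000)
        p = prob_greater(a, b, seed=1)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_separated_treatments(self, rng):
        a = rng.lognormal(math.log(1.0), 0.3, 50_000)
        b = rng.lognormal(math.log(0.2), 0.3, 50_000)
        assert prob_greater(a, b, seed=1) > 0.9

    def test_separation_from_fitted_posteriors(self):
        # two synthetic treatments with 5x different true omega: pooled
        # posterior EF draws must separate at dense sampling
        cfg = McmcConfig(n_iter=3000, n_burnin=1000, seed=4)
        layout = CampaignLayout(treatments=("X",), n_treatment_plots=8)
        draws = {}
        for name, omega in (("hi", 0.01), ("lo", 0.002)):
            truth = TruthSpec(omega=omega, background_mu=0.1)
            df = simulate_event(truth, daily_then_alternate_schedule(), layout,
                                seed=31)
            design = EventDesign(site="SYN", event=1, n_in=70.0, treatments=("X",))
            res = analyze_event(df, design, mcmc=cfg)[0]
            draws[name] = res.chains.ef
        pooled_hi = pooled_posterior_pdf([draws["hi"]])["draws"]
        pooled_lo = pooled_posterior_pdf([draws["lo"]])["draws"]
        assert prob_greater(pooled_hi, pooled_lo, seed=2) > 0.9

    def test_empty_error(self):
        with pytest.raises(ValueError):
            pooled_posterior_pdf([])


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.125) == 0.13
        assert round_half_up(-0.125) == -0.13
        assert round_half_up(1.914285) == 1.91
        np.testing.assert_allclose(round_half_up(np.array([0.005, 0.015])),
                                   [0.01, 0.02])
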