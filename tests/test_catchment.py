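import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from docseer.catchment import (
    CarbonParams,
    CatchmentConfig,
    HydroParams,
    LandCoverUnit,
    PointSource,
    Reach,
    SOC_M,
    SOC_O,
    SOIL,
    DOC,
    QUICK,
    SLOW,
    SNOW,
    compile_config,
    config_from_yaml,
    config_to_yaml,
    default_state,
    demo_catchment,
    route_network,
    run_simulation,
    spin_up,
    step_carbon,
    step_hydrology,
)
from docseer.synthetic import ForcingSeries


def single_unit_config(hydro=None, carbon=None, area=100.0, point_sources=(),
                       k_instream=0.0):
    unit = LandCoverUnit(share=1.0, hydro=hydro or HydroParams(),
                         carbon=carbon or CarbonParams())
    return CatchmentConfig(reaches=[Reach("C1", area, {"broadleaf_forest": unit},
                                          list(point_sources), None, k_instream)])


def make_forcing(temp, precip, reach_ids=("C1",), start_year=2000):
    return {
        rid: ForcingSeries(start_year, np.asarray(temp, float),
                           np.asarray(precip, float), rid)
        for rid in reach_ids
    }


class TestHydrologyStep:
    def test_subfreezing_precipitation_accumulates_as_snow(self):
        cp = compile_config(single_unit_config())
        pools = np.zeros((1, 7))
        new, fx = step_hydrology(pools, np.array(-5.0), np.array(10.0), cp)
        assert new[0, SNOW] == 10.0
        assert fx["her"][0] == 0.0
        assert fx["q_quick"][0] == 0.0 and fx["q_slow"][0] == 0.0

    def test_saturated_soil_routes_rain_to_her(self):
        """At capacity with zero PET, all rain becomes effective rainfall."""
        hp = HydroParams(c_soil=150.0)
        cp = compile_config(single_unit_config(hydro=hp))
        pools = np.zeros((1, 7))
        pools[0, SOIL] = hp.c_soil
        new, fx = step_hydrology(pools, np.array(0.0), np.array(10.0), cp)
        assert fx["pet"][0] == 0.0
        assert fx["her"][0] == pytest.approx(10.0)
        assert new[0, SOIL] == pytest.approx(hp.c_soil)

    def test_empty_system_all_fluxes_zero(self):
        cp = compile_config(single_unit_config())
        pools = np.zeros((1, 7))
        new, fx = step_hydrology(pools, np.array(15.0), np.array(0.0), cp)
        for name in ("rain", "snowmelt", "aet", "her", "q_quick", "q_slow"):
            assert fx[name][0] == 0.0
        assert np.array_equal(new[0, [SNOW, SOIL, QUICK, SLOW]], np.zeros(4))

    def test_melt_capped_by_snowpack(self):
        cp = compile_config(single_unit_config(hydro=HydroParams(ddf=5.0)))
        pools = np.zeros((1, 7))
        pools[0, SNOW] = 3.0
        new, fx = step_hydrology(pools, np.array(10.0), np.array(0.0), cp)
        assert fx["snowmelt"][0] == 3.0  # DDF demand 50 mm, pack only 3
        assert new[0, SNOW] == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            single_unit_config(hydro=HydroParams(beta_q=1.5))
        with pytest.raises(ValueError):
            single_unit_config(hydro=HydroParams(tau_q=0.5))


class TestCarbonStep:
    def _fluxes(self, her=0.0, smd=0.0):
        return {"her": np.array([her]), "smd": np.array([smd])}

    def test_production_formula_at_reference_conditions(self):
        """T = T_ref and saturated soil: production = k_p · SOC_o exactly."""
        carbon = CarbonParams()
        cp = compile_config(single_unit_config(carbon=carbon))
        pools = np.zeros((1, 7))
        pools[0, SOC_O] = 100.0
        _, fx = step_carbon(pools, self._fluxes(smd=0.0), np.array(carbon.t_ref), cp)
        assert fx["production"][0] == pytest.approx(carbon.k_p * 100.0)

    def test_q10_multiplies_production(self):
        carbon = CarbonParams()
        cp = compile_config(single_unit_config(carbon=carbon))
        pools = np.zeros((1, 7))
        pools[0, SOC_O] = 100.0
        _, ref = step_carbon(pools, self._fluxes(), np.array(carbon.t_ref), cp)
        _, hot = step_carbon(pools, self._fluxes(), np.array(carbon.t_ref + 10), cp)
        assert hot["production"][0] == pytest.approx(carbon.q10 * ref["production"][0])

    def test_empty_dissolved_pool_has_no_outflux(self):
        cp = compile_config(single_unit_config())
        pools = np.zeros((1, 7))
        pools[0, SOC_O] = 50.0
        _, fx = step_carbon(pools, self._fluxes(her=5.0), np.array(12.0), cp)
        for name in ("sorption", "mineralization", "export"):
            assert fx[name][0] == 0.0

    def test_flux_capping_prevents_negative_pool(self):
        """Export demand ≈ the whole pool: outflows scale, pool stays ≥ 0."""
        cp = compile_config(single_unit_config())
        pools = np.zeros((1, 7))
        pools[0, DOC] = 1.0
        fx_in = {"her": np.array([500.0]), "smd": np.array([150.0])}  # f_export = 1
        new, fx = step_carbon(pools, fx_in, np.array(10.0), cp)
        assert new[0, DOC] >= 0.0
        total_out = fx["sorption"][0] + fx["mineralization"][0] + fx["export"][0]
        assert total_out <= 1.0 + 1e-12

    def test_nonfinite_forcing_rejected(self):
        cp = compile_config(single_unit_config())
        with pytest.raises(ValueError):
            step_carbon(np.zeros((1, 7)), self._fluxes(), np.array(np.nan), cp)


class TestRouting:
    def test_point_source_mass_balance(self):
        """12 mg/L at 0.13 m³/s into 1 m³/s of clean water → (12·0.13)/1.13 mg/L."""
        cfg = single_unit_config(point_sources=[PointSource(12.0, 0.13)], area=100.0)
        cp = compile_config(cfg)
        depth = np.array([1.0 / (100.0 * 1000.0 / 86400.0)])  # exactly 1 m³/s local
        q, load, conc = route_network(cp, depth, np.zeros(1), np.zeros(1))
        assert q[0] == pytest.approx(1.13)
        assert conc[0] == pytest.approx((12.0 * 0.13) / 1.13)

    def test_dry_stream_concentration_flagged_missing(self):
        cp = compile_config(single_unit_config())
        q, load, conc = route_network(cp, np.zeros(1), np.zeros(1), np.zeros(1))
        assert q[0] == 0.0 and np.isnan(conc[0])

    def test_dilution_halves_concentration(self):
        cp = compile_config(single_unit_config())
        _, _, c1 = route_network(cp, np.array([1.0]), np.array([5.0]), np.zeros(1))
        _, _, c2 = route_network(cp, np.array([2.0]), np.array([5.0]), np.zeros(1))
        assert c2[0] == pytest.approx(c1[0] / 2)

    def test_upstream_load_attenuated_in_downstream_reach(self, catchment, truth10):
        out = run_simulation(catchment, truth10)
        # downstream flow includes upstream: C2 ≥ C1 everywhere
        assert np.all(out.streamflow[out.reach("C2")] >= out.streamflow[out.reach("C1")])


class TestSimulation:
    def test_zero_length_forcing(self, catchment):
        forcing = make_forcing(np.empty(0), np.empty(0), ("C1", "C2"))
        out = run_simulation(catchment, forcing)
        assert out.n_days == 0
        np.testing.assert_array_equal(out.final_state.pools,
                                      default_state(catchment).pools)

    def test_misaligned_forcing_rejected(self, catchment):
        forcing = {
            "C1": ForcingSeries(2000, np.zeros(10), np.zeros(10), "C1"),
            "C2": ForcingSeries(2000, np.zeros(12), np.zeros(12), "C2"),
        }
        with pytest.raises(ValueError):
            run_simulation(catchment, forcing)

    def test_balances_close_on_reference_run(self, reference10):
        assert reference10.water_balance_error() < 1e-6
        assert reference10.carbon_balance_error() < 1e-6

    def test_load_equals_concentration_times_flow(self, reference10):
        ri = reference10.reach("C2")
        q = reference10.streamflow[ri]
        ok = q > 0
        np.testing.assert_allclose(
            reference10.load[ri][ok],
            reference10.doc[ri][ok] * q[ok],
            rtol=1e-12,
        )

    def test_analytic_fixed_point_is_stationary(self):
        """Constant forcing at the analytic equilibrium: pools stay put.

        With constant T and sub-capacity P, the soil water equilibrium S*
        satisfies AET = P, the organic pool satisfies production = litter
        input, and the dissolved pool balances production against sorption +
        mineralization (no HER, so no export).
        """
        hp, carbon = HydroParams(), CarbonParams()
        cfg = single_unit_config(hydro=hp, carbon=carbon)
        cp = compile_config(cfg)
        T, P = 15.0, 2.0
        pet = hp.a_pet * T
        s_star = P * hp.c_soil / pet
        assert s_star < hp.c_soil
        f_temp = carbon.q10 ** ((T - carbon.t_ref) / 10)
        soc_o_star = carbon.i_litter / (carbon.k_p * f_temp * s_star / hp.c_soil)
        d_star = carbon.i_litter / (carbon.k_sorb + carbon.k_min)
        pools = np.zeros((1, 7))
        pools[0, SOIL], pools[0, SOC_O], pools[0, DOC] = s_star, soc_o_star, d_star
        from docseer.catchment import ModelState

        n = 20
        forcing = make_forcing(np.full(n, T), np.full(n, P))
        out = run_simulation(cfg, forcing, initial=ModelState(pools))
        end = out.final_state.pools
        for idx in (SOIL, SOC_O, DOC):
            assert abs(end[0, idx] - pools[0, idx]) / pools[0, idx] < n * 1e-9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegativity_and_balance_under_random_forcing(self, seed):
        """Property: random weather never drives a store or pool negative and
        never breaks mass conservation."""
        rng = np.random.default_rng(seed)
        n = 200
        temp = rng.normal(10, 8, n)
        precip = rng.gamma(0.5, 8, n) * (rng.random(n) < 0.4)
        cfg = single_unit_config()
        out = run_simulation(cfg, make_forcing(temp, precip),
                             record_trajectory=True)
        assert np.all(out.trajectory >= 0)
        assert out.water_balance_error() < 1e-6
        assert out.carbon_balance_error() < 1e-6
        assert np.all(out.streamflow >= 0)

    def test_soil_carbon_memory_exceeds_rainfall_memory(self, reference10):
        """Lag-1 autocorrelation of the organic carbon pool is far above that
        of effective rainfall: the slow pool integrates weather noise."""
        soc_o = reference10.trajectory[1:, 3, SOC_O]  # one forest unit
        her = reference10.her[reference10.reach("C2")]

        def lag1(x):
            x = x - x.mean()
            return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))

        assert lag1(soc_o) > lag1(her)
        assert lag1(soc_o) > 0.99


class TestSpinUp:
    def test_longer_spinup_reduces_drift(self, catchment, truth10):
        year = {sc: f.window(1988, 1, 365) for sc, f in truth10.items()}
        _, d1 = spin_up(catchment, year, 1)
        _, d5 = spin_up(catchment, year, 5)
        assert d5 <= d1

    def test_deterministic(self, catchment, truth10):
        year = {sc: f.window(1988, 1, 365) for sc, f in truth10.items()}
        s1, _ = spin_up(catchment, year, 2)
        s2, _ = spin_up(catchment, year, 2)
        np.testing.assert_array_equal(s1.pools, s2.pools)


class TestConfig:
    def test_shares_must_sum_to_one(self):
        unit = LandCoverUnit(0.5, HydroParams(), CarbonParams())
        with pytest.raises(ValueError):
            CatchmentConfig(reaches=[Reach("C1", 10.0, {"urban": unit})])

    def test_upstream_must_precede(self):
        unit = LandCoverUnit(1.0, HydroParams(), CarbonParams())
        with pytest.raises(ValueError):
            CatchmentConfig(
                reaches=[Reach("C1", 10.0, {"urban": unit}, upstream="C2"),
                         Reach("C2", 10.0, {"urban": unit})]
            )

    def test_yaml_roundtrip(self, catchment, tmp_path):
        path = tmp_path / "cfg.yaml"
        config_to_yaml(catchment, path)
        again = config_from_yaml(path)
        assert again.reach_ids == catchment.reach_ids
        a = compile_config(catchment)
        b = compile_config(again)
        np.testing.assert_array_equal(a.c_soil, b.c_soil)
        np.testing.assert_array_equal(a.i_litter, b.i_litter)
        np.testing.assert_array_equal(a.ps_load, b.ps_load)
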