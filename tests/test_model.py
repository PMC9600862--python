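import numpy as np
import pytest

from smassay import build_scenario, effective_lag, simulate, sweep_parameter
from smassay.features import auc_curve, lag_time
from smassay.model import ScenarioError, SpeciesParams, scenario_from_dict, scenario_to_dict

from conftest import REGISTRY


class TestBuildScenario:
    def test_ns_cf_wiring(self):
        """Cross-feeding: species 1 secretes C4, species 2 grows on it, and
        niche separation means neither grows on the other's carbon."""
        sc = build_scenario("NS+CF", "benign")
        sp1, sp2 = sc.species
        assert sp1.p[3] > 0
        assert sp2.r[3] > 0
        assert sp1.r[1] == 0 and sp2.r[0] == 0
        assert sc.medium0[3] == 0.0  # C4 absent from any fresh medium

    @pytest.mark.parametrize("label", ["EC", "NS", "NS+CF", "NS+CD"])
    def test_inhibitory_medium_carries_inhibitor(self, label):
        sc = build_scenario(label, "inhibitory")
        assert sc.medium0[2] == pytest.approx(3.5)

    def test_ec_is_pure_resource_overlap(self):
        sc = build_scenario("EC", "benign")
        sp1, sp2 = sc.species
        assert sp1.r[0] > 0 and sp2.r[0] > 0
        assert sp1.p[2] == 0 and sp1.p[3] == 0 and sp1.u[2] == 0
        assert sc.medium0[2] == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ScenarioError, match="unknown"):
            build_scenario("mutualism", "benign")

    def test_cd_needs_inhibitor(self):
        with pytest.raises(ScenarioError, match="inhibitor"):
            build_scenario("NS+CD", "benign")

    def test_negative_override_rejected(self):
        with pytest.raises(ScenarioError, match="negative"):
            build_scenario("NS", "benign", {"p[1,4]": -1.0})

    def test_overrides_applied_last(self):
        sc = build_scenario("NS+CF", "benign", {"p[1,4]": 0.123, "t_end": 5.0})
        assert sc.species[0].p[3] == pytest.approx(0.123)
        assert sc.t_end == 5.0

    def test_dict_roundtrip(self):
        sc = build_scenario("NS+CD", "inhibitory", {"l[2,2,3]": 7.0})
        back = scenario_from_dict(scenario_to_dict(sc))
        assert back.label == sc.label
        for a, b in zip(sc.species, back.species):
            for name in ("r", "K", "y", "p", "u", "l"):
                np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(back.medium0, sc.medium0)


class TestEffectiveLag:
    def test_zero_coefficients(self):
        sp = SpeciesParams(id=2)
        assert effective_lag(sp, 1, np.array([15, 10, 3.5, 0])) == 0.0

    def test_linear_in_inhibitor(self):
        """l[2,2,3] = 2 with C3 = 3.5 delays growth on C2 by 7 time units."""
        sp = SpeciesParams(id=2)
        sp.l[1, 2] = 2.0
        assert effective_lag(sp, 1, np.array([15, 10, 3.5, 0])) == pytest.approx(7.0)

    def test_monotone_in_c3(self):
        sp = SpeciesParams(id=2)
        sp.l[1, 2] = 1.3
        lags = [effective_lag(sp, 1, np.array([15, 10, c3, 0]))
                for c3 in np.linspace(0, 7, 15)]
        assert all(b >= a for a, b in zip(lags, lags[1:]))


class TestSimulate:
    def test_nothing_to_grow_on(self):
        sc = build_scenario("NS", "benign")
        sim = simulate(sc, medium=np.zeros(4), t_end=10, dt=0.1)
        np.testing.assert_allclose(sim.biomass, 0.05, rtol=1e-9)

    def test_closed_form_mass_balance(self):
        """Single substrate, K << c0, no lag: final biomass = inoculum + y*c0."""
        sc = build_scenario("NS", "benign",
                            {"K[1,1]": 1e-6, "medium0[1]": 5.0, "y[1,1]": 2.0})
        sim = simulate(sc, inoculum=np.array([0.05, 0.0]), t_end=40, dt=0.1)
        assert sim.biomass[0, -1] == pytest.approx(0.05 + 2.0 * 5.0, rel=1e-6)
        # growth on the substrate is the only sink: equality in the balance
        gained = sim.biomass[0, -1] - sim.biomass[0, 0]
        consumed = sim.compounds[0, 0] - sim.compounds[0, -1]
        assert gained <= 2.0 * consumed + 1e-6

    def test_exponential_segment_rate(self):
        """While c >> K the specific growth rate equals r (closed-form limit)."""
        sc = build_scenario("NS", "benign", {"K[1,1]": 1e-6, "medium0[1]": 1000.0})
        sim = simulate(sc, inoculum=np.array([0.05, 0.0]), t_end=6, dt=0.05)
        log_b = np.log(sim.biomass[0])
        slope = np.polyfit(sim.times, log_b, 1)[0]
        assert slope == pytest.approx(0.5, rel=1e-4)

    def test_unconsumed_compound_conserved(self):
        """A species consuming only C1 leaves C2 untouched at 10 for all t."""
        sc = build_scenario("NS", "benign")
        sim = simulate(sc, inoculum=np.array([0.05, 0.0]), t_end=30, dt=0.1)
        np.testing.assert_allclose(sim.compounds[1], 10.0, rtol=1e-9)

    @pytest.mark.parametrize("label,env", REGISTRY)
    def test_nonnegative_and_mass_balanced(self, label, env, registry_assays):
        """No trajectory goes negative and no responder gains more biomass
        than its consumed substrates can yield."""
        result = registry_assays[(label, env)]
        sc = build_scenario(label, env)
        responder = sc.species[1]
        for sim in result.conditions.values():
            assert sim.biomass.min() >= 0 and sim.compounds.min() >= 0
            gained = sim.biomass[1, -1] - sim.biomass[1, 0]
            budget = sum(
                responder.y[j] * (sim.compounds[j, 0] - sim.compounds[j, -1])
                for j in range(4) if responder.r[j] > 0
            )
            assert gained <= budget + 1e-6

    def test_grid_convergence(self):
        """Halving the output step changes the trajectory AUC by < 0.1%."""
        sc = build_scenario("NS+CF", "inhibitory")
        coarse = simulate(sc, inoculum=np.array([0.0, 0.05]), dt=1 / 6)
        fine = simulate(sc, inoculum=np.array([0.0, 0.05]), dt=1 / 12)
        a1 = auc_curve(coarse.times, coarse.biomass[1])
        a2 = auc_curve(fine.times, fine.biomass[1])
        assert abs(a1 - a2) / a2 < 1e-3

    def test_lag_monotone_in_initial_inhibitor(self):
        """Measured responder lag grows with the inoculation C3 level."""
        sc = build_scenario("NS", "inhibitory")
        lags = []
        for c3 in (0.0, 0.875, 1.75, 3.5):
            med = sc.medium0.copy()
            med[2] = c3
            sim = simulate(sc, medium=med, inoculum=np.array([0.0, 0.05]))
            lags.append(lag_time(sim.times, sim.biomass[1]))
        assert all(lag is not None for lag in lags)
        assert all(b >= a for a, b in zip(lags, lags[1:]))

    def test_bad_grid_rejected(self):
        sc = build_scenario("NS", "benign")
        with pytest.raises(ValueError):
            simulate(sc, dt=-0.1)
        with pytest.raises(ValueError):
            simulate(sc, medium=np.array([1.0, -1.0, 0.0, 0.0]))


class TestSweep:
    def test_zero_cf_production_matches_plain_ns(self, relative_auc_grid):
        sc = build_scenario("NS+CF", "benign")
        grid = sweep_parameter(sc, "p[1,4]", [0.0])
        plain = relative_auc_grid[("NS", "benign")]
        for cond in ("SM/2+NC", "SM", "SM/2+MM"):
            assert grid.iloc[0][cond] == pytest.approx(plain[cond], abs=1e-3)

    def test_strong_cf_lifts_sm2nc_above_mm(self):
        """Heavily produced cross-fed compounds are recognizable because even
        the half-diluted spent medium outgrows fresh medium."""
        sc = build_scenario("NS+CF", "benign")
        grid = sweep_parameter(sc, "p[1,4]", [0.2])
        assert grid.iloc[0]["SM/2+NC"] > 1.0

    def test_no_detox_leaves_inhibitor_at_initial_level(self):
        from smassay import harvest_sm

        sc = build_scenario("NS+CD", "inhibitory", {"u[1,3]": 0.0})
        sm = harvest_sm(sc)
        assert sm[2] == pytest.approx(3.5, rel=1e-6)

    def test_unknown_parameter(self):
        sc = build_scenario("NS+CF", "benign")
        with pytest.raises(ValueError, match="p\\[1,4\\]"):
            sweep_parameter(sc, "r[2,2]", [0.1])
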