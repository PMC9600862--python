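from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smassay import (
    GrowthCurveSet,
    auc_curve,
    compare_conditions,
    condition_features,
    detect_bump,
    final_yield,
    lag_time,
    read_plate_long,
    read_plate_wide,
    relative_auc,
    write_plate_long,
)
from smassay.synthetic_data import write_plate_wide


class TestAuc:
    def test_constant_curve(self):
        t = np.linspace(0, 7, 43)
        assert auc_curve(t, np.full(43, 0.3)) == pytest.approx(0.3 * 7)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 1 + 1e-9, 1 / 6)
        assert auc_curve(t, t) == pytest.approx(0.5, abs=1e-12)

    def test_exponential_oracle_at_plate_sampling(self):
        """Trapezoid at 10-min sampling matches the analytic integral of
        exp(0.5 t) over 72 h to within 0.1%."""
        t = np.arange(0, 72 + 1e-9, 1 / 6)
        curve = np.exp(0.5 * t)
        exact = (np.exp(0.5 * 72) - 1.0) / 0.5
        assert auc_curve(t, curve) == pytest.approx(exact, rel=1e-3)

    @given(st.integers(1, 40))
    def test_collinear_insertion_invariance(self, k):
        t = np.array([0.0, 1.0, 3.0])
        v = np.array([0.0, 2.0, 1.0])
        base = auc_curve(t, v)
        # insert a collinear point inside the first segment
        frac = k / 41
        t2 = np.insert(t, 1, frac)
        v2 = np.insert(v, 1, 2.0 * frac)
        assert auc_curve(t2, v2) == pytest.approx(base, abs=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_curve(np.array([0.0, 2.0, 1.0]), np.ones(3))


class TestRelativeAuc:
    def test_controls_map_to_unit_interval(self):
        assert relative_auc(2.0, 2.0, 9.0) == 0.0
        assert relative_auc(9.0, 2.0, 9.0) == 1.0

    @given(st.floats(0.1, 100), st.floats(0, 5), st.floats(5.1, 50), st.floats(0, 60))
    def test_affine_invariance(self, scale, nc, mm, x):
        base = relative_auc(x, nc, mm)
        scaled = relative_auc(scale * x, scale * nc, scale * mm)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_failed_positive_control(self):
        with pytest.raises(ValueError, match="positive control"):
            relative_auc(1.0, 5.0, 5.0)

    def test_crossfed_sm_exceeds_one(self, relative_auc_grid):
        assert relative_auc_grid[("NS+CF", "benign")]["SM"] > 1.0


class TestLagAndYield:
    def test_flat_curve_is_no_growth(self):
        t = np.arange(0, 24, 1 / 6)
        assert lag_time(t, np.full(t.size, 0.1)) is None

    def test_step_curve(self):
        t = np.arange(0, 24 + 1e-9, 1 / 6)
        od = np.where(t < 12, 0.1, 0.2)
        assert lag_time(t, od) == pytest.approx(12.0)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            lag_time(np.arange(5.0), np.arange(5.0), fold_threshold=1.0)

    def test_plateau_yield(self):
        t = np.linspace(0, 48, 289)
        od = 2.0 / (1 + np.exp(-0.5 * (t - 10)))
        assert final_yield(t, od) == pytest.approx(2.0, rel=1e-3)

    def test_crossfeeding_raises_yield_detox_does_not(self, registry_assays):
        """Extra carbon (CF) raises the SM yield above MM; removing an
        inhibitor (CD) does not add carbon, so the yields match."""
        ratios = {}
        for label in ("NS+CF", "NS+CD"):
            res = registry_assays[(label, "inhibitory")]
            y_sm = final_yield(res.conditions["SM"].times, res.conditions["SM"].biomass[1])
            y_mm = final_yield(res.conditions["MM"].times, res.conditions["MM"].biomass[1])
            ratios[label] = y_sm / y_mm
        assert ratios["NS+CF"] > 1.0
        assert ratios["NS+CD"] == pytest.approx(1.0, abs=0.02)


class TestDetectBump:
    def test_single_substrate_has_no_bump(self):
        t = np.linspace(0, 48, 289)
        od = 0.05 + 2.0 / (1 + np.exp(-0.5 * (t - 10)))
        assert not detect_bump(t, od)["present"]

    def test_crossfed_sm_curve_bumps(self, registry_assays):
        sim = registry_assays[("NS+CF", "inhibitory")].conditions["SM"]
        out = detect_bump(sim.times, sim.biomass[1])
        assert out["present"]
        assert 2.0 < out["time"] < 50.0

    def test_detox_sm_curve_does_not_bump(self, registry_assays):
        sim = registry_assays[("NS+CD", "inhibitory")].conditions["SM"]
        assert not detect_bump(sim.times, sim.biomass[1])["present"]

    def test_false_positive_rate_on_noisy_single_substrate(self, registry_assays):
        """< 5% spurious bumps over 200 seeded noisy single-phase curves."""
        sim = registry_assays[("NS", "inhibitory")].conditions["SM"]
        rng = np.random.default_rng(1234)
        fp = 0
        for _ in range(200):
            od = sim.biomass[1] + 0.04 + rng.normal(0, 0.005, sim.times.size)
            fp += detect_bump(sim.times, np.maximum(od, 0), blank=0.04)["present"]
        assert fp / 200 < 0.05

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            detect_bump(np.arange(10.0), np.arange(10.0))


def _exact_permutation_call(a, b, alpha=0.1):
    """Enumerate all 6-choose-3 relabelings; directional call when the
    observed mean difference is among the most extreme partitions."""
    pooled = np.concatenate([a, b])
    obs = a.mean() - b.mean()
    diffs = []
    for idx in combinations(range(6), 3):
        mask = np.zeros(6, bool)
        mask[list(idx)] = True
        diffs.append(pooled[mask].mean() - pooled[~mask].mean())
    p = np.mean(np.abs(diffs) >= abs(obs) - 1e-12)
    if p <= alpha:
        return ">" if obs > 0 else "<"
    return "≈"


class TestCompareConditions:
    def test_identical_sets_all_equivalent(self):
        reps = {c: np.array([1.0, 1.1, 0.9]) for c in
                ("NC", "MM", "SM/2+NC", "SM", "SM/2+MM")}
        pattern = compare_conditions(reps)
        assert set(pattern.symbols.values()) == {"≈"}

    def test_clear_effect_direction(self):
        reps = {
            "NC": np.array([1.0, 1.01, 0.99]),
            "MM": np.array([10.0, 10.01, 9.99]),
            "SM": np.array([10.0, 10.02, 9.98]),
            "SM/2+NC": np.array([1.0, 1.02, 0.98]),
            "SM/2+MM": np.array([10.0, 10.01, 9.99]),
        }
        pattern = compare_conditions(reps)
        assert pattern.symbol("SM", "MM") == "≈"
        assert pattern.symbol("SM", "NC") == ">"

    def test_bonferroni_is_family_times_raw(self):
        rng = np.random.default_rng(7)
        reps = {c: rng.normal(loc, 0.5, 3) for c, loc in
                [("NC", 1), ("MM", 5), ("SM", 4), ("SM/2+NC", 3), ("SM/2+MM", 5)]}
        pattern = compare_conditions(reps)
        for key, raw in pattern.p_raw.items():
            assert pattern.p_adj[key] == pytest.approx(min(1.0, raw * 6))

    def test_zero_variance_degenerate_flagged(self):
        reps = {
            "NC": np.array([1.0, 1.0, 1.0]),
            "MM": np.array([5.0, 5.0, 5.0]),
            "SM": np.array([5.0, 5.0, 5.0]),
            "SM/2+NC": np.array([2.0, 2.0, 2.0]),
            "SM/2+MM": np.array([5.0, 5.0, 5.0]),
        }
        pattern = compare_conditions(reps)
        assert pattern.symbol("SM", "MM") == "≈"      # equal zero-variance means
        assert ("SM", "NC") in pattern.degenerate      # unequal zero-variance means
        assert pattern.symbol("SM", "NC") == ">"

    def test_needs_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_conditions({"MM": np.array([1.0]), "NC": np.array([1.0, 2.0]),
                                "SM": np.array([1.0, 2.0])})

    def test_agreement_with_permutation_oracle(self):
        """Symbols agree with an exact permutation test's directional calls
        in >= 95% of seeded small fixtures (n = 3)."""
        agree = total = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            null_case = seed % 6 == 0
            means = {"NC": 1.0, "MM": 10.0,
                     "SM": 10.0 if null_case else 16.0,
                     "SM/2+NC": 4.0, "SM/2+MM": 7.0}
            reps = {c: rng.normal(m, 0.4, 3) for c, m in means.items()}
            pattern = compare_conditions(reps)
            for (cond, ref), sym in pattern.symbols.items():
                oracle = _exact_permutation_call(reps[cond], reps[ref])
                total += 1
                if sym == "≈" or oracle == "≈":
                    agree += (sym == "≈") == (oracle == "≈")
                else:
                    agree += sym == oracle
        assert agree / total >= 0.95


class TestPlateIO:
    def _curves(self):
        t = np.arange(0, 8 + 1e-9, 1 / 6)
        rng = np.random.default_rng(0)
        return {
            "MM": GrowthCurveSet("MM", t, rng.uniform(0.04, 1.0, (3, t.size)), blank=0.04),
            "NC": GrowthCurveSet("NC", t, rng.uniform(0.03, 0.06, (3, t.size)), blank=0.04),
        }

    def test_long_roundtrip_full_precision(self, tmp_path):
        curves = self._curves()
        path = tmp_path / "plate.csv"
        write_plate_long(curves, path)
        back = read_plate_long(path, blank=0.04)
        for cond, cs in curves.items():
            np.testing.assert_array_equal(back[cond].od, cs.od)
            np.testing.assert_array_equal(back[cond].times, cs.times)

    def test_wide_dialect_roundtrip(self, tmp_path):
        curves = self._curves()
        plate, well_map = tmp_path / "wide.csv", tmp_path / "map.csv"
        write_plate_wide(curves, plate, well_map)
        back = read_plate_wide(plate, well_map, blank=0.04)
        for cond, cs in curves.items():
            np.testing.assert_array_equal(back[cond].od, cs.od)

    def test_missing_well_named_in_error(self, tmp_path):
        curves = self._curves()
        plate, well_map = tmp_path / "wide.csv", tmp_path / "map.csv"
        write_plate_wide(curves, plate, well_map)
        import pandas as pd

        df = pd.read_csv(well_map)
        df.loc[0, "well"] = "H12"
        df.to_csv(well_map, index=False)
        with pytest.raises(ValueError, match="H12"):
            read_plate_wide(plate, well_map)

    def test_feature_table_shape(self, registry_assays):
        from smassay import NoiseModel, curves_from_assay

        curves = curves_from_assay(
            registry_assays[("NS+CF", "inhibitory")], NoiseModel(seed=3), n_rep=3
        )
        table = condition_features(curves)
        assert len(table) == 15
        assert set(table["condition"]) == {"NC", "MM", "SM/2+NC", "SM", "SM/2+MM"}
        sm_bumps = table.loc[table["condition"] == "SM", "bump_present"]
        assert sm_bumps.mean() > 0.5
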