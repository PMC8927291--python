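"""Thiele modulus, Biot number, and regime classification."""
import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tumorsat as ts
from tumorsat.thiele import Formula, Regime


class TestSurfaceToVolume:
    def test_default_geometry(self, physiology):
        # 2*8um / (75um)^2
        assert ts.surface_to_volume(physiology) == pytest.approx(2.84e3, rel=1e-2)

    def test_equal_radii_identity(self):
        phys = ts.TumorPhysiology(capillary_radius=10e-6, krogh_radius=10.0001e-6)
        assert ts.surface_to_volume(phys) == pytest.approx(2 / 10e-6, rel=1e-4)

    def test_doubling_outer_radius_quarters(self, physiology):
        double = replace(physiology, krogh_radius=2 * physiology.krogh_radius)
        assert ts.surface_to_volume(double) == pytest.approx(
            ts.surface_to_volume(physiology) / 4
        )


class TestBiotNumber:
    def test_default_physiology(self, physiology):
        # P back-computed from PS/V = 6e-6 /s is 2.11e-9 m/s
        assert physiology.resolved_permeability() == pytest.approx(2.11e-9, rel=1e-2)
        assert ts.biot_number(physiology) == pytest.approx(0.014, rel=0.02)

    def test_unity_construction(self):
        phys = ts.TumorPhysiology(ps_over_v=None,
                                  permeability=1e-11 * 0.24 / (2 * 8e-6))
        assert ts.biot_number(phys) == pytest.approx(1.0)

    def test_halving_diffusivity_doubles(self, physiology):
        slow = replace(physiology, diffusivity=physiology.diffusivity / 2)
        assert ts.biot_number(slow) == pytest.approx(2 * ts.biot_number(physiology))


class TestSimplifiedForm:
    def test_nivolumab_worked_example(self):
        phi2 = ts.thiele_squared_simplified(5.35e-6, 2.79e-9, 6e-6, 0.594e-6)
        assert phi2 == pytest.approx(4.2e-3, rel=0.02)

    def test_kadcyla_worked_example(self):
        phi2 = ts.thiele_squared_simplified(2.75e-5, 4.98e-7, 6e-6, 0.639e-6)
        assert phi2 == pytest.approx(3.6, rel=0.02)
        assert phi2 > 1  # penetration-limited

    def test_vanishes_at_high_plasma_concentration(self):
        assert ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 1e3) < 1e-9

    def test_zero_plasma_concentration_is_unbounded(self):
        assert math.isinf(ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 0.0))

    def test_zero_consumption_with_zero_delivery_is_zero(self):
        assert ts.thiele_squared_simplified(0.0, 0.0, 6e-6, 0.0) == 0.0

    @given(
        k_e=st.floats(min_value=1e-7, max_value=1e-3),
        ag=st.floats(min_value=1e-10, max_value=1e-5),
        psv=st.floats(min_value=1e-7, max_value=1e-4),
        ab=st.floats(min_value=1e-9, max_value=1e-4),
        factor=st.floats(min_value=1.01, max_value=100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity(self, k_e, ag, psv, ab, factor):
        base = ts.thiele_squared_simplified(k_e, ag, psv, ab)
        assert ts.thiele_squared_simplified(k_e * factor, ag, psv, ab) > base
        assert ts.thiele_squared_simplified(k_e, ag * factor, psv, ab) > base
        assert ts.thiele_squared_simplified(k_e, ag, psv, ab * factor) < base

    @given(
        k_e=st.floats(min_value=1e-7, max_value=1e-3),
        ag=st.floats(min_value=1e-10, max_value=1e-5),
        psv=st.floats(min_value=1e-7, max_value=1e-4),
        ab=st.floats(min_value=1e-9, max_value=1e-4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_dimensional_invariance(self, k_e, ag, psv, ab):
        """Converting all inputs to hours and micromolar leaves phi^2 fixed."""
        si = ts.thiele_squared_simplified(k_e, ag, psv, ab)
        other = ts.thiele_squared_simplified(
            k_e * 3600.0, ag * 1e6, psv * 3600.0, ab * 1e6
        )
        assert other == pytest.approx(si, rel=1e-9)


class TestFullForm:
    def test_exceeds_simplified_by_one_plus_biot(self, physiology):
        bi = ts.biot_number(physiology)
        full = ts.thiele_squared_full(5.35e-6, 2.79e-9, physiology, 0.594e-6)
        simp = ts.thiele_squared_simplified(5.35e-6, 2.79e-9, 6e-6, 0.594e-6)
        assert full / simp == pytest.approx(1.0 + bi, rel=1e-6)

    def test_small_biot_reduction(self, physiology):
        """Bi ~ 0.014 for default physiology: forms agree within ~1.5%."""
        full = ts.thiele_squared_full(1e-5, 1e-7, physiology, 1e-6)
        simp = ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 1e-6)
        assert abs(full - simp) / simp < 0.02

    def test_large_biot_is_classic_diffusion_limit(self):
        phys = ts.TumorPhysiology(ps_over_v=None, permeability=1e-3)
        assert ts.biot_number(phys) > 1e3
        full = ts.thiele_squared_full(1e-5, 1e-7, phys, 1e-6)
        classic = (
            1e-5 * phys.krogh_radius**2 * (1e-7 / phys.void_fraction)
            / (phys.diffusivity * 1e-6)
        )
        assert full == pytest.approx(classic, rel=2e-3)

    def test_zero_consumption(self, physiology):
        assert ts.thiele_squared_full(0.0, 1e-7, physiology, 1e-6) == 0.0


class TestLowAffinityVariant:
    def test_high_affinity_limit(self):
        la = ts.thiele_squared_low_affinity(1e-5, 1e-7, 6e-6, 1e-6, 0.0)
        simp = ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 1e-6)
        assert la == simp

    def test_kd_equal_to_plasma_concentration_halves(self):
        la = ts.thiele_squared_low_affinity(1e-5, 1e-7, 6e-6, 1e-6, 1e-6)
        simp = ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 1e-6)
        assert la == pytest.approx(simp / 2)

    def test_moderate_affinity_factor(self):
        # K_d = 270 nM against [Ab] = 0.594 uM -> factor 0.69
        la = ts.thiele_squared_low_affinity(1e-5, 1e-7, 6e-6, 0.594e-6, 270e-9)
        simp = ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 0.594e-6)
        assert la / simp == pytest.approx(0.6875, rel=1e-3)

    @given(kd=st.floats(min_value=1e-12, max_value=1e-5))
    @settings(max_examples=50, derandomize=True)
    def test_never_exceeds_high_affinity_value(self, kd):
        la = ts.thiele_squared_low_affinity(1e-5, 1e-7, 6e-6, 1e-6, kd)
        simp = ts.thiele_squared_simplified(1e-5, 1e-7, 6e-6, 1e-6)
        assert la <= simp


class TestEvaluateAgent:
    def test_avelumab_straddles_supersaturation_threshold(self, by_name):
        res = ts.evaluate_agent(by_name["Avelumab"])
        assert res.phi2_cmax < 0.1
        assert res.phi2_ctrough > 0.1
        assert res.regime is Regime.SUPERSATURATED

    def test_padcev_saturating(self, by_name):
        res = ts.evaluate_agent(by_name["Padcev"])
        assert res.phi2_cmax < 1
        assert res.regime is Regime.SATURATING

    def test_kadcyla_is_largest_adc(self, registry, by_name):
        kadcyla = ts.evaluate_agent(by_name["Kadcyla"])
        assert kadcyla.phi2_cmax > 1
        adcs = [r for r in registry if r.agent_class is ts.AgentClass.ADC]
        assert len(adcs) == 7
        values = {r.name: ts.evaluate_agent(r).phi2_cmax for r in adcs}
        assert max(values, key=values.get) == "Kadcyla"
        assert min(values, key=values.get) == "Enhertu (IHC2+)"

    def test_trough_always_at_least_cmax_value(self, registry):
        for record in registry:
            res = ts.evaluate_agent(record)
            assert res.phi2_ctrough >= res.phi2_cmax

    def test_trodelvy_trough_unbounded(self, by_name):
        res = ts.evaluate_agent(by_name["Trodelvy"])
        assert math.isinf(res.phi2_ctrough)

    def test_full_formula_option(self, by_name):
        res = ts.evaluate_agent(by_name["Kadcyla"], formula="full")
        assert res.formula_used is Formula.FULL
        simp = ts.evaluate_agent(by_name["Kadcyla"])
        assert res.phi2_cmax == pytest.approx(
            simp.phi2_cmax * (1 + res.biot), rel=1e-6
        )

    def test_missing_cmax_rejected(self, by_name):
        record = by_name["Kadcyla"]
        exposure = replace(record.exposure, c_max=None, c_trough=None)
        broken = replace(record, exposure=exposure)
        with pytest.raises(ts.InvalidParameterError):
            ts.evaluate_agent(broken)

    def test_regime_thresholds(self):
        assert ts.classify_regime(0.05) is Regime.SUPERSATURATED
        assert ts.classify_regime(0.5) is Regime.SATURATING
        assert ts.classify_regime(1.5) is Regime.PENETRATION_LIMITED
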