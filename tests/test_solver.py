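import numpy as np
import pytest

from retstim.errors import SolverDivergenceError
from retstim.fields import PointSourceField, StimulusWaveform
from retstim.mechanisms import BCMechanism, RGCMechanism
from retstim.morphology import CompartmentGraph
from retstim.solver import (Clamp, PassiveMechanism, SimConfig,
                            fit_membrane_time_constant,
                            polarization_profile, simulate)


def single_compartment():
    # cylinder chosen so tau_m = C_m/g_L = 1 µF/cm² / 0.5 mS/cm² = 2 ms
    return CompartmentGraph("BC", centers=[[0, 0, 0]], lengths=[5.0],
                            diameters=[5.0], sections=["soma"], edges=[])


class TestAnalyticRelaxation:
    def test_leak_relaxation_matches_closed_form(self):
        g = single_compartment()
        mech = PassiveMechanism(g, g_l_ms_cm2=0.5, e_l_mv=-60.0)
        cfg = SimConfig(total_ms=10.0, settle_ms=0.0)
        tr = simulate(g, mech, config=cfg, v_init=-50.0)
        tau = 2.0
        expected = -60.0 + 10.0 * np.exp(-tr.t_ms / tau)
        err = np.abs(tr.v_mv[:, 0] - expected) / np.abs(expected)
        assert err.max() < 1e-3  # 0.1 % of the membrane potential

    def test_dt_halving_changes_solution_under_half_percent(self, bc_cell):
        wf = StimulusWaveform(shape="pulse", amplitude_ua=2.0,
                              pulse_duration_ms=2.0, total_duration_ms=2.0)
        vals = []
        for dt in (0.025, 0.0125):
            cfg = SimConfig(dt_ms=dt, total_ms=2.0,
                            record_indices=bc_cell.terminals)
            tr = simulate(bc_cell.graph, bc_cell.mechanism, bc_cell.field,
                          wf, cfg)
            vals.append(tr.v_mv[-1].mean())
        rest = -60.0
        assert abs(vals[1] - vals[0]) / abs(vals[0] - rest) < 0.005


class TestRestingStability:
    def test_bc_rest_drift_below_hundredth_mv(self, bc_cell):
        cfg = SimConfig(total_ms=1000.0, settle_ms=50.0, record_stride=40)
        tr = simulate(bc_cell.graph, bc_cell.mechanism, config=cfg)
        assert np.abs(tr.v_mv - tr.v_mv[0]).max() < 0.01

    def test_rgc_rest_drift_below_hundredth_mv(self, rgc_graph):
        mech = RGCMechanism(rgc_graph)
        cfg = SimConfig(total_ms=200.0, settle_ms=50.0, record_stride=40,
                        record_indices=np.arange(0, rgc_graph.n_compartments,
                                                 10))
        tr = simulate(rgc_graph, mech, config=cfg)
        assert np.abs(tr.v_mv - tr.v_mv[0]).max() < 0.01

    def test_zero_gradient_uniform_field_equals_unstimulated(self, bc_cell):
        from retstim.fields import UniformField
        field = UniformField(direction=np.array([0.0, 0.0, 1.0]),
                             gradient_mv_um=0.0)
        wf = StimulusWaveform(shape="pulse", amplitude_ua=1.0,
                              pulse_duration_ms=5.0, total_duration_ms=10.0)
        cfg = SimConfig(total_ms=10.0)
        tr_stim = simulate(bc_cell.graph, bc_cell.mechanism, field, wf, cfg)
        tr_rest = simulate(bc_cell.graph, bc_cell.mechanism, config=cfg)
        assert tr_stim.v_mv == pytest.approx(tr_rest.v_mv, abs=1e-12)


class TestKirchhoff:
    def test_axial_currents_balance_membrane_currents(self, bc_graph):
        """Physics residual recomputed from the trace: into every
        compartment, axial + field-coupling currents equal the
        capacitive plus ionic currents (passive membrane)."""
        mech = PassiveMechanism(bc_graph)
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        wf = StimulusWaveform(shape="pulse", amplitude_ua=1.0,
                              pulse_duration_ms=2.0, total_duration_ms=2.0)
        dt = 0.025
        cfg = SimConfig(dt_ms=dt, total_ms=2.0, settle_ms=0.0)
        tr = simulate(bc_graph, mech, ps, wf, cfg)
        ve = ps.potential_at(1.0, bc_graph.centers)
        g_edge = bc_graph.edge_conductances_us()
        c = bc_graph.capacitances_nf
        g_l = 0.5 * bc_graph.areas_cm2 * 1e3
        k = 40  # check an interior step, during the pulse
        v_old, v_new = tr.v_mv[k - 1], tr.v_mv[k]
        axial = np.zeros(bc_graph.n_compartments)
        for (i, j), g in zip(bc_graph.edges, g_edge):
            flow = g * ((v_new[j] + ve[j]) - (v_new[i] + ve[i]))
            axial[i] += flow
            axial[j] -= flow
        residual = axial - (c * (v_new - v_old) / dt
                            + g_l * (v_new - (-60.0)))
        scale = np.abs(axial).max()
        assert np.abs(residual).max() / scale < 1e-9


class TestSpikePropagation:
    def test_upstroke_times_increase_along_axon(self, rgc_graph):
        mech = RGCMechanism(rgc_graph)
        ps = PointSourceField([rgc_graph.soma_position[0],
                               rgc_graph.soma_position[1], 10.0])
        wf = StimulusWaveform(shape="pulse", amplitude_ua=30.0,
                              pulse_duration_ms=1.0, total_duration_ms=6.0)
        cfg = SimConfig(total_ms=6.0, record_indices=np.array([0]),
                        v_bounds_mv=(-4000, 4000))
        tr = simulate(rgc_graph, mech, ps, wf, cfg)
        soma = int(rgc_graph.section_indices("soma")[0])
        dist = rgc_graph.path_distances_from(soma)
        axon = rgc_graph.section_indices("axon")
        order = axon[np.argsort(dist[axon])]
        times = tr.first_crossing_ms[order]
        assert np.isfinite(times).all()
        diffs = np.diff(times)
        # monotone arrival along the axon, allowing single-step (dt)
        # quantization ties/inversions near the initiation zone
        assert np.all(diffs >= -tr.dt_ms - 1e-9)
        assert times[-1] > times[0] + 1.0


class TestGuardsAndClamp:
    def test_divergence_guard_names_compartment(self, bc_cell):
        wf = StimulusWaveform(shape="pulse", amplitude_ua=50.0,
                              pulse_duration_ms=5.0, total_duration_ms=5.0)
        cfg = SimConfig(total_ms=5.0, v_bounds_mv=(-200.0, 300.0))
        with pytest.raises(SolverDivergenceError) as err:
            simulate(bc_cell.graph, bc_cell.mechanism, bc_cell.field, wf, cfg)
        assert err.value.compartment is not None
        assert err.value.time_ms is not None

    def test_voltage_clamp_holds_command(self, bc_graph):
        mech = BCMechanism(bc_graph)
        term = bc_graph.section_indices("terminal")
        clamp = Clamp(indices=term, v_mv=-10.0)
        cfg = SimConfig(total_ms=20.0, record_indices=term)
        tr = simulate(bc_graph, mech, config=cfg, clamp=clamp)
        assert tr.v_mv[-1] == pytest.approx(-10.0, abs=1e-3)


class TestPolarization:
    def test_zero_current_zero_polarization(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        pol = polarization_profile(bc_graph, ps, 0.0)
        assert np.abs(pol).max() == 0.0

    def test_sign_flip_is_exact(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        pol_p = polarization_profile(bc_graph, ps, 1.0)
        pol_m = polarization_profile(bc_graph, ps, -1.0)
        assert pol_m == pytest.approx(-pol_p, rel=1e-12)

    def test_anodic_source_polarization_pattern(self, bc_graph):
        """Anode below the cell: dendrites/soma hyperpolarize, terminals
        depolarize."""
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        pol = polarization_profile(bc_graph, ps, 1.0)
        assert pol[bc_graph.section_indices("dendrite")].mean() < 0
        assert pol[bc_graph.section_indices("soma")].mean() < 0
        assert pol[bc_graph.section_indices("terminal")].mean() > 0

    def test_linear_in_current(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        p1 = polarization_profile(bc_graph, ps, 1.0)
        p3 = polarization_profile(bc_graph, ps, 3.0)
        assert p3 == pytest.approx(3 * p1, rel=1e-9)


class TestCharging:
    def test_terminal_charging_time_constant_sub_ms(self, bc_cell):
        wf = StimulusWaveform(shape="pulse", amplitude_ua=4.0,
                              pulse_duration_ms=4.0, total_duration_ms=8.0,
                              delay_ms=1.0)
        cfg = SimConfig(total_ms=8.0, record_indices=bc_cell.terminals,
                        v_bounds_mv=(-4000, 4000))
        tr = simulate(bc_cell.graph, bc_cell.mechanism, bc_cell.field, wf,
                      cfg)
        tau, dv = fit_membrane_time_constant(tr.t_ms, tr.v_mv.mean(axis=1),
                                             1.0, 1.0)
        assert 0.05 < tau < 0.5
        assert dv > 0
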