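import numpy as np
import pytest

from retstim.errors import ConfigError, SingularityError
from retstim.fields import (PointSourceField, StimulusWaveform, UniformField,
                            matched_uniform_field, superpose)


@pytest.fixture()
def source():
    return PointSourceField(position_um=np.zeros(3))


class TestPointSource:
    def test_closed_form_value(self, source):
        # I = 1 µA, ρ = 1000 Ω·cm, r = 15 µm -> 10·1000/(4π·15) mV
        v = source.potential_at(1.0, [[15.0, 0.0, 0.0]])
        assert v[0] == pytest.approx(53.0516, abs=1e-3)

    def test_zero_current(self, source):
        pts = np.random.default_rng(0).normal(size=(5, 3)) * 30 + 50
        assert np.all(source.potential_at(0.0, pts) == 0.0)

    def test_inverse_distance_law(self, source):
        v1 = source.potential_at(2.0, [[10.0, 0, 0]])
        v2 = source.potential_at(2.0, [[20.0, 0, 0]])
        assert v1[0] == pytest.approx(2 * v2[0], rel=1e-12)

    def test_equipotential_sphere(self, source):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        v = source.potential_at(3.0, dirs * 25.0)
        assert np.ptp(v) < 1e-12 * abs(v[0])

    def test_singularity_guard(self, source):
        with pytest.raises(SingularityError):
            source.potential_at(1.0, [[0.1, 0.0, 0.0]])

    @pytest.mark.parametrize("amp", [0.5, 2.0, 7.5])
    def test_linearity_in_current(self, source, amp):
        pts = [[12.0, 3.0, -4.0], [40.0, 0.0, 10.0]]
        base = source.potential_at(1.0, pts)
        assert source.potential_at(amp, pts) == pytest.approx(amp * base,
                                                              rel=1e-12)


class TestSuperposition:
    def test_colocated_sources_add(self, source):
        pts = [[10.0, 5.0, 0.0]]
        two = superpose([source, PointSourceField(np.zeros(3))], [1.5, 1.5],
                        pts)
        one = source.potential_at(3.0, pts)
        assert two == pytest.approx(one, rel=1e-12)

    def test_empty_list_gives_zeros(self):
        assert np.all(superpose([], [], [[1.0, 2.0, 3.0]]) == 0.0)

    def test_grid_matches_single_source_loop(self):
        rng = np.random.default_rng(2)
        sources = [PointSourceField(rng.normal(size=3) * 20)
                   for _ in range(6)]
        currents = rng.uniform(0.5, 3.0, size=6)
        pts = rng.normal(size=(10, 3)) * 50 + 200
        total = superpose(sources, currents, pts)
        brute = sum(s.potential_at(i, pts)
                    for s, i in zip(sources, currents))
        assert total == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch(self, source):
        with pytest.raises(ConfigError):
            superpose([source], [1.0, 2.0], [[10, 0, 0]])


class TestMatchedUniformField:
    def test_voltage_drop_matches_point_source(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        uni = matched_uniform_field(ps, 1.0, bc_graph)
        z_min, z_max = bc_graph.z_extent
        xy = bc_graph.soma_position[:2]
        pts = np.array([[xy[0], xy[1], z_min], [xy[0], xy[1], z_max]])
        drop_uni = np.diff(uni.potential_at(1.0, pts))[0]
        drop_pt = np.diff(ps.potential_at(1.0, pts))[0]
        assert drop_uni == pytest.approx(drop_pt, abs=1e-9)

    def test_gradient_linear_in_current(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        g1 = matched_uniform_field(ps, 1.0, bc_graph).gradient_mv_um
        g2 = matched_uniform_field(ps, 2.0, bc_graph).gradient_mv_um
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_anode_below_gives_decreasing_potential_with_z(self, bc_graph):
        ps = PointSourceField(bc_graph.soma_position + [0, 0, -15.0])
        uni = matched_uniform_field(ps, 1.0, bc_graph)
        assert uni.gradient_mv_um > 0  # potential falls toward the vitreous

    def test_unit_direction_enforced(self):
        with pytest.raises(ConfigError):
            UniformField(direction=np.array([0, 0, 2.0]), gradient_mv_um=1.0)


class TestWaveform:
    def test_single_pulse_shape(self):
        wf = StimulusWaveform(shape="pulse", amplitude_ua=4.0,
                              pulse_duration_ms=4.0, total_duration_ms=10.0,
                              delay_ms=1.0)
        t = np.arange(0, 10.0, 0.025)
        i = wf.current_ua(t)
        assert i[t < 1.0].max() == 0.0
        assert i[(t >= 1.0) & (t < 5.0)].min() == 4.0
        assert i[t >= 5.0].max() == 0.0

    def test_train_pulse_count(self):
        wf = StimulusWaveform(shape="pulse_train", amplitude_ua=1.0,
                              pulse_duration_ms=4.0, frequency_hz=10.0,
                              total_duration_ms=1000.0)
        assert len(wf.pulse_onsets()) == 10

    def test_train_period_must_fit_pulse(self):
        with pytest.raises(ConfigError):
            StimulusWaveform(shape="pulse_train", pulse_duration_ms=25.0,
                             frequency_hz=50.0)

    def test_schedule_onsets_strictly_increasing(self):
        with pytest.raises(ConfigError):
            StimulusWaveform(shape="schedule", onsets_ms=[0.0, 10.0, 10.0])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ConfigError):
            StimulusWaveform(amplitude_ua=-1.0)

    def test_export_two_columns(self, tmp_path):
        wf = StimulusWaveform(shape="pulse", amplitude_ua=2.0,
                              pulse_duration_ms=1.0, total_duration_ms=5.0)
        path = tmp_path / "wave.tsv"
        wf.export_tsv(path, dt_ms=0.5)
        data = np.loadtxt(path, skiprows=1)
        assert data.shape[1] == 2
        assert data[:, 1].max() == 2.0
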