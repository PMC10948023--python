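import pytest

from retstim.morphology import build_stylized_bc, build_stylized_rgc


@pytest.fixture(scope="session")
def bc_graph():
    return build_stylized_bc()


@pytest.fixture(scope="session")
def rgc_graph():
    return build_stylized_rgc()


@pytest.fixture(scope="session")
def bc_cell():
    from retstim.protocols import bc_setup
    return bc_setup()


@pytest.fixture()
def toy_cable_path(tmp_path):
    from retstim.fixtures import TOY_CABLE_SWC
    p = tmp_path / "toy_cable.swc"
    p.write_text(TOY_CABLE_SWC)
    return p


@pytest.fixture(scope="session")
def clamp_ca_trace():
    """Terminal calcium under the calibration clamp (−60 → −10 mV, 2 s)."""
    from retstim.mechanisms import voltage_clamp_ca_trace
    t, ca, i_ca = voltage_clamp_ca_trace(total_ms=2000.0)
    return t, ca, i_ca
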