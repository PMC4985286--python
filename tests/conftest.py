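import pytest

from mwcgate import (CurrentTrace, RecordingConfig, propagate_piecewise,
                     reference_fixture, relaxation_protocol, to_current)


@pytest.fixture(scope="session")
def fixture_params():
    """Reference gating + ligand parameter set (ground truth everywhere)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def gate(fixture_params):
    return fixture_params[0]


@pytest.fixture(scope="session")
def menthol(fixture_params):
    return fixture_params[1]


@pytest.fixture(scope="session")
def aitc(fixture_params):
    return fixture_params[2]


@pytest.fixture(scope="session")
def rec():
    return RecordingConfig(Gmax_nS=10.0)


def relax_trace(gate, ligand, L, dt=1e-4, Gmax_nS=10.0):
    """Noiseless relaxation sweep as a CurrentTrace (hold/+120/-80)."""
    sim = propagate_piecewise(gate, ligand, L, relaxation_protocol(), dt=dt)
    return CurrentTrace(
        time_s=sim.time, voltage_mV=sim.voltage * 1e3,
        current_pA=to_current(sim, RecordingConfig(Gmax_nS=Gmax_nS)),
        po=sim.po, meta={"conc_M": repr(L)},
    )


@pytest.fixture(scope="session")
def menthol_relax_traces(gate, menthol):
    """Noiseless menthol relaxation set: control + 10/30/100 uM."""
    return [relax_trace(gate, menthol, L) for L in (0.0, 1e-5, 3e-5, 1e-4)]


@pytest.fixture(scope="session")
def aitc_relax_traces(gate, aitc):
    """Noiseless AITC relaxation set: control + 1/3/10 mM."""
    return [relax_trace(gate, aitc, L) for L in (0.0, 1e-3, 3e-3, 1e-2)]
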