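import pytest

import sbftiming as sbf


@pytest.fixture(scope="session")
def ml_type2():
    return sbf.MLParams.type2(i0=0.2)


@pytest.fixture(scope="session")
def ml_type2_trace(ml_type2):
    """A long oscillatory Type 2 run reused by period/convergence tests."""
    return sbf.integrate_ml(ml_type2, t_end=400.0, dt=0.02)


@pytest.fixture(scope="session")
def small_ml_bank():
    """Calibrated 24-neuron Type 2 bank spanning 5.5-11.5 Hz (shared: slow)."""
    return sbf.calibrate_bank(sbf.OscillatorBankSpec(5.5, 11.5, 24))


@pytest.fixture()
def band_spec():
    return sbf.OscillatorBankSpec(5.5, 11.5, 1000)
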