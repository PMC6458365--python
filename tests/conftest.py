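import numpy as np
import pytest

from cytovisc import AcquisitionSettings, RenderSpec, TraceSpec, simulate_trace


@pytest.fixture
def acq_10kpa():
    """Canonical acquisition: -10 kPa suction, 5 µm pipette, 0.5 µm/px, 800 fps."""
    return AcquisitionSettings(
        suction_pressure=1e4, pipette_radius=5.0, pixel_size=0.5, frame_rate=800.0
    )


@pytest.fixture
def acq_5kpa(acq_10kpa):
    from dataclasses import replace

    return replace(acq_10kpa, suction_pressure=5e3)


@pytest.fixture
def noiseless_trace(acq_10kpa):
    """One clean trace: µc = 41.67 Pa·s, Rc = 10 µm -> rate ~400 µm/s."""
    spec = TraceSpec(
        true_viscosity=41.67, cell_radius=10.0, elastic_jump=2.0,
        elastic_duration=0.005, noise_sd=0.0,
    )
    return simulate_trace(spec, acq_10kpa, cell_id="clean")


@pytest.fixture
def render_spec():
    return RenderSpec()


@pytest.fixture
def render_spec_noiseless():
    return RenderSpec(photon_noise_sd=0.0)
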