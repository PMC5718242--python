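import numpy as np
import pytest

from iortsim.geometry import DiscPose, GeometryModel
from iortsim.source import BeamSourceModel
from iortsim.transport import TransportSettings, run_simulation


@pytest.fixture(scope="session")
def fast_settings():
    return TransportSettings(max_step=0.5)


@pytest.fixture(scope="session")
def small_run(fast_settings):
    """One cached small run (no disc) shared by smoke-level assertions."""
    geo = GeometryModel(reference_disc=DiscPose(depth=24.5))
    grid, stats = run_simulation(
        source=BeamSourceModel(8.1, sigma_energy=1.1),
        geometry=geo,
        settings=fast_settings,
        n_histories=8000,
        n_batches=4,
        voxel_size=1.0,
        seed=123,
    )
    return grid, stats, geo


@pytest.fixture
def rng():
    return np.random.default_rng(42)
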