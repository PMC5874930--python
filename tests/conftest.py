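import numpy as np
import pytest

from arcqa import (
    ArrayConfig,
    BeamGeometry,
    GridSpec,
    MediumConfig,
    PlanSpec,
    build_geometry,
)


@pytest.fixture(scope="session")
def geometry():
    """Default 1386-diode helical array."""
    return build_geometry(ArrayConfig())


@pytest.fixture(scope="session")
def toy_geometry():
    """A 100-diode array on a small cylinder for brute-force comparisons."""
    return build_geometry(ArrayConfig(
        n_diodes=100, detector_radius=3.0, phantom_outer_radius=4.0,
        phantom_length=8.0, helix_turns=5,
    ))


@pytest.fixture(scope="session")
def toy_medium():
    return MediumConfig(outer_radius=4.0, length=8.0)


@pytest.fixture(scope="session")
def grid_spec():
    return GridSpec.covering_phantom(spacing=0.7)


@pytest.fixture(scope="session")
def single_beam_plan():
    return PlanSpec("single", [BeamGeometry(head_id=1, gantry_angle=77.0,
                                            beam_on_time=3.0)])


@pytest.fixture(scope="session")
def three_beam_plan():
    return PlanSpec("triple", [
        BeamGeometry.from_head1_angle(k, 40.0, beam_on_time=3.0)
        for k in (1, 2, 3)
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
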