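import numpy as np
import pytest

from pufov import (
    AlignmentParams,
    ParticipantProfile,
    build_layout,
    default_occlusion_mask,
    generate_grid,
    layout_with_coverage,
    schedule_events,
)


@pytest.fixture(scope="session")
def layout():
    """Reference simulator layout (3.05 x 1.89 m screens, 151 deg, 3.75 m)."""
    return build_layout()


@pytest.fixture(scope="session")
def layout149():
    """Layout whose horizontal coverage is exactly 149 degrees."""
    return layout_with_coverage(149.0)


@pytest.fixture(scope="session")
def grid():
    """Feature grid with the default chassis occlusion mask."""
    return generate_grid(0, default_occlusion_mask())


@pytest.fixture(scope="session")
def grid_all_visible():
    return generate_grid(0)


@pytest.fixture(scope="session")
def events(grid):
    """One full 5-minute schedule: 140 events per change type."""
    return schedule_events(grid, 300.0, 140, seed=1)


@pytest.fixture(scope="session")
def short_events(grid):
    """A short 60 s schedule with 15 events per type, for fast session tests."""
    return schedule_events(grid, 60.0, 15, seed=2)


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile()


@pytest.fixture(scope="session")
def noiseless_profile():
    return ParticipantProfile().noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def align_params():
    return AlignmentParams()
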