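import numpy as np
import pytest

from cardioscreen.imaging import MovieStack, build_mmode, trace_diameters
from cardioscreen.synth import SimulationSpec, simulate_movie, true_diameter_trace


@pytest.fixture(scope="session")
def clean_spec():
    """Acquisition-shaped (501 frames, 50 fps) noise- and jitter-free heart."""
    return SimulationSpec(noise_scale=0.0, rate_jitter_cv=0.0)


@pytest.fixture(scope="session")
def clean_movie(clean_spec):
    return simulate_movie(clean_spec)


@pytest.fixture(scope="session")
def clean_truth(clean_spec):
    return true_diameter_trace(clean_spec)


@pytest.fixture(scope="session")
def fast_spec():
    """Short, small movie for cheap per-test rendering."""
    return SimulationSpec(
        n_frames=201, image_height=24, noise_scale=0.0, rate_jitter_cv=0.0
    )


@pytest.fixture
def constant_movie():
    """A movie whose frames are all identical (static bright-band profile)."""
    profile = np.full(80, 10.0)
    profile[20:30] = 200.0
    profile[50:60] = 200.0
    frames = np.broadcast_to(profile, (40, 16, 80)).copy()
    return MovieStack(frames=frames, frame_rate=50.0, pixel_size=1.0)
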